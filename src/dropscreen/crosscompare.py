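"""Comparative analyses: paralog buffering, dependency counts, copy-number
bias, set overlaps, hypergeometric enrichment, and the RNAi re-analysis.

The paralog-buffering question: when a fly fitness gene duplicated along
the vertebrate lineage, single-gene knockouts of either human duplicate
can be masked by the surviving copy, so human screens under-detect these
genes. The comparison maps each fly gene to its most essential expressed
human ortholog and contrasts cumulative essentiality curves between
paralog and singleton strata.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import hypergeom_sf

__all__ = [
    "validate_orthology",
    "map_most_essential_ortholog",
    "paralog_flags",
    "cumulative_essentiality",
    "dependency_counts",
    "copy_number_bias",
    "hypergeometric_enrichment",
    "overlap_stats",
    "rnai_offtarget_filter",
]

CONFIDENCE_LEVELS = ("high", "moderate", "low")
ACCEPTED_CONFIDENCE = ("high", "moderate")


def validate_orthology(orthology: pd.DataFrame) -> None:
    bad = set(orthology["confidence"]) - set(CONFIDENCE_LEVELS)
    if bad:
        raise ValueError(f"invalid confidence labels: {sorted(bad)}")
    if orthology.duplicated(["fly_gene", "human_gene"]).any():
        raise ValueError("duplicate (fly_gene, human_gene) pairs")


def _accepted(orthology: pd.DataFrame) -> pd.DataFrame:
    return orthology[orthology["confidence"].isin(ACCEPTED_CONFIDENCE)]


def paralog_flags(orthology: pd.DataFrame) -> pd.Series:
    """fly gene -> True when it has >1 high/moderate-confidence ortholog."""
    validate_orthology(orthology)
    n = _accepted(orthology).groupby("fly_gene")["human_gene"].nunique()
    return (n > 1).rename("has_paralog")


def map_most_essential_ortholog(
    fly_gene: str,
    orthology: pd.DataFrame,
    fitness: pd.Series,
    expressed: pd.Series | None = None,
) -> str | None:
    """The fly gene's most essential expressed human ortholog, or None.

    Orthologs are restricted to high/moderate confidence; genes not
    expressed in the human line are excluded (a silent paralog cannot
    show a knockout phenotype, nor be scored meaningfully). A unique
    ortholog is returned as-is, provided it is expressed and scored.
    """
    validate_orthology(orthology)
    cands = _accepted(orthology)
    cands = cands.loc[cands["fly_gene"] == fly_gene, "human_gene"].unique()
    best, best_score = None, -np.inf
    for h in sorted(cands):
        if expressed is not None and not bool(expressed.get(h, False)):
            continue
        score = fitness.get(h, None)
        if score is None or pd.isna(score):
            continue
        if score > best_score:
            best, best_score = h, float(score)
    return best


def most_essential_orthologs(
    orthology: pd.DataFrame,
    fitness: pd.Series,
    expressed: pd.Series | None = None,
) -> pd.Series:
    """Vectorized :func:`map_most_essential_ortholog` over every fly gene.

    Returns fly gene -> chosen human gene; fly genes with no expressed,
    scored high/moderate-confidence ortholog are absent from the result.
    """
    validate_orthology(orthology)
    df = _accepted(orthology)[["fly_gene", "human_gene"]].copy()
    df["score"] = df["human_gene"].map(fitness)
    df = df.dropna(subset=["score"])
    if expressed is not None:
        df = df[df["human_gene"].map(expressed).fillna(False).astype(bool)]
    if df.empty:
        return pd.Series(dtype=object)
    # ties on score resolve to the lexicographically first human gene,
    # matching the single-gene function's deterministic scan order
    df = df.sort_values(["fly_gene", "score", "human_gene"],
                        ascending=[True, False, True], kind="mergesort")
    best = df.groupby("fly_gene", sort=True).first()
    return best["human_gene"]


def cumulative_essentiality(ordered_genes: Sequence[str], scores: pd.Series) -> pd.Series:
    """curve[k] = mean score of the first k genes of the ordered list."""
    missing = [g for g in ordered_genes if g not in scores.index or pd.isna(scores[g])]
    if missing:
        raise KeyError(f"genes missing a score: {missing[:10]} ({len(missing)} total)")
    vals = scores.reindex(ordered_genes).to_numpy(dtype=float)
    k = np.arange(1, len(vals) + 1)
    return pd.Series(np.cumsum(vals) / k, index=k, name="cumulative_mean")


def dependency_counts(
    genes: Iterable[str],
    ceres: pd.DataFrame,
    cutoff: float = -0.8,
) -> tuple[pd.Series, list[str]]:
    """Per-gene number of cell lines with a fitness call (score < cutoff).

    Returns (counts for genes present in the matrix, list of missing
    genes) — a gene absent from the panel is reported missing, not zero.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    genes = list(genes)
    present = [g for g in genes if g in ceres.index]
    missing = [g for g in genes if g not in ceres.index]
    counts = (ceres.loc[present] < cutoff).sum(axis=1).astype(int)
    counts.name = "n_dependent_lines"
    return counts, missing


def copy_number_bias(
    scores: pd.DataFrame,
    copy_number: pd.Series,
    extreme_cn: int = 8,
) -> pd.DataFrame:
    """Depletion summary per copy-number bin, with ratios to the 1-2 bin.

    Bins: 1-2 copies (normal), 3..extreme_cn-1 (moderately amplified),
    >= extreme_cn (extreme). Depletion magnitude is mean |min(Z, 0)|;
    the hit-style rate is the fraction of genes with Z < -1.645. The
    ``ratio`` column divides each bin's mean depletion by the normal
    bin's; function-independent cutting bias shows up as ratio > 1 in
    the extreme bin only.
    """
    cn = copy_number.reindex(scores.index)
    if (cn.dropna() < 1).any():
        raise ValueError("copy numbers must be >= 1")
    z = scores["z"]
    depletion = np.abs(np.minimum(z, 0.0))
    labels = pd.cut(cn, bins=[0, 2, extreme_cn - 0.5, np.inf],
                    labels=["1-2", f"3-{extreme_cn - 1}", f">={extreme_cn}"])
    df = pd.DataFrame({"bin": labels, "depletion": depletion, "z": z})
    out = df.groupby("bin", observed=False).agg(
        n_genes=("z", "size"),
        mean_depletion=("depletion", "mean"),
        depleted_rate=("z", lambda v: float((v < -1.645).mean()) if len(v) else np.nan),
    )
    base = out.loc["1-2", "mean_depletion"]
    out["ratio"] = out["mean_depletion"] / base if base > 0 else np.nan
    return out


def hypergeometric_enrichment(
    hits: set[str],
    term_sets: Mapping[str, set[str]],
    universe: set[str],
    adjust: bool = False,
) -> pd.DataFrame:
    """Exact upper-tail enrichment p per term.

    p = P(X >= overlap) for X hypergeometric with population |universe|,
    successes |term ∩ universe|, draws |hits|. Term sets are intersected
    with the universe first; hits must be a subset of the universe.
    P-values are reported raw; ``adjust=True`` adds a Benjamini-Hochberg
    column for multi-term reports.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = set(hits) - set(universe)
    if stray:
        raise ValueError(f"hits outside the universe: {sorted(stray)[:5]}")
    rows = []
    for term in sorted(term_sets):
        members = set(term_sets[term]) & set(universe)
        overlap = len(members & set(hits))
        p = hypergeom_sf(overlap, len(universe), len(members), len(hits))
        rows.append({"term": term, "term_size": len(members),
                     "overlap": overlap, "p_value": p})
    out = pd.DataFrame(rows).set_index("term")
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def overlap_stats(a: set[str], b: set[str], universe: set[str]) -> dict:
    """|A∩B|, fraction of A, and the exact enrichment tail p."""
    for name, s in (("A", a), ("B", b)):
        stray = set(s) - set(universe)
        if stray:
            raise ValueError(f"set {name} not within universe: {sorted(stray)[:5]}")
    inter = len(set(a) & set(b))
    frac = inter / len(a) if a else np.nan
    p = hypergeom_sf(inter, len(universe), len(b), len(a))
    return {"overlap": inter, "fraction_of_a": frac, "p_value": p}


def rnai_offtarget_filter(
    targets: Mapping[str, Sequence[str]],
    raw_scores: pd.Series,
) -> tuple[pd.Series, pd.Series]:
    """Discard multi-target RNAi amplicons and re-standardize.

    Amplicons with more than one unique target are removed; the
    screen-wide Z is then recomputed over retained amplicons as
    (score - mean) / sd, and each gene receives the most extreme
    (largest-|Z|) of its retained amplicons.

    Returns (per-amplicon Z over retained amplicons, per-gene Z).
    """
    for amp in raw_scores.index:
        if amp not in targets or len(targets[amp]) == 0:
            raise ValueError(f"amplicon {amp!r} has no target list")
    retained = [a for a in raw_scores.index if len(set(targets[a])) == 1]
    if not retained:
        raise ValueError("no single-target amplicons retained")
    vals = raw_scores.reindex(retained).astype(float)
    sd = vals.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        sd = 1.0
    z = ((vals - vals.mean()) / sd).rename("z")
    gene_of = pd.Series({a: next(iter(set(targets[a]))) for a in retained})
    per_gene = z.groupby(gene_of).agg(lambda v: v.iloc[int(np.argmax(np.abs(v.to_numpy())))])
    per_gene.name = "z_extreme"
    return z, per_gene
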