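"""Expression-anchored empirical FDR and screen-quality metrics.

A true fitness gene must be expressed, so a phenotypic assertion for an
unexpressed gene (RPKM below a threshold, by default 1) is certainly an
error. Ranking genes from most- to least-depleted and counting such
errors cumulatively gives a rank-wise empirical false-discovery rate
without any parametric model:

    main_text:          fdr(r) = #(unexpressed among top r) / r
    legend_normalized:  fdr(r) = #(unexpressed among top r) / #(unexpressed total)

The raw empirical curve is reported as-is (no pi0 correction, no
monotonization) — a running-minimum smoothing is available for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FdrCurve",
    "rankwise_fdr",
    "call_hits",
    "roc_vs_fdr",
    "tpr_at_fdr",
    "expression_bias_profile",
]

VARIANTS = ("main_text", "legend_normalized")


@dataclass
class FdrCurve:
    """Rank-ordered genes (most depleted first) with the empirical FDR.

    table: DataFrame with columns rank, gene_id, z, rpkm, unexpressed, fdr.
    """

    table: pd.DataFrame
    rpkm_threshold: float
    variant: str

    def monotone(self) -> pd.Series:
        """Running-minimum-from-the-strongest-rank smoothing (display only)."""
        rev = self.table["fdr"].to_numpy()[::-1]
        return pd.Series(np.minimum.accumulate(rev)[::-1],
                         index=self.table.index, name="fdr_monotone")


def rankwise_fdr(
    scores: pd.DataFrame,
    expression: pd.Series,
    rpkm_threshold: float = 1.0,
    variant: str = "main_text",
) -> FdrCurve:
    """Compute the rank-wise expression-anchored FDR curve.

    ``scores`` is the gene-score frame (index gene_id, columns including
    z); genes are ordered by ascending Z with ties broken by gene id.
    Every scored gene must have an expression value.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if len(scores) == 0:
        raise ValueError("empty score list")
    missing = [g for g in scores.index if g not in expression.index
               or pd.isna(expression[g])]
    if missing:
        raise KeyError(f"genes missing from expression table: {missing[:10]}"
                       f" ({len(missing)} total)")

    tbl = scores.reset_index().rename(columns={scores.index.name or "index": "gene_id"})
    tbl = tbl.sort_values(["z", "gene_id"], kind="mergesort").reset_index(drop=True)
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    tbl["rpkm"] = tbl["gene_id"].map(expression)
    tbl["unexpressed"] = tbl["rpkm"] < rpkm_threshold
    errors = tbl["unexpressed"].cumsum()
    if variant == "main_text":
        tbl["fdr"] = errors / tbl["rank"]
    else:
        total = int(tbl["unexpressed"].sum())
        tbl["fdr"] = errors / total if total > 0 else 0.0
    cols = ["rank", "gene_id", "z", "rpkm", "unexpressed", "fdr"]
    extra = [c for c in tbl.columns if c not in cols]
    return FdrCurve(table=tbl[cols + extra], rpkm_threshold=rpkm_threshold,
                    variant=variant)


def _cut_rank(curve: FdrCurve, alpha: float) -> int:
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    ok = curve.table["fdr"] <= alpha
    return int(curve.table["rank"][ok].max()) if ok.any() else 0


def call_hits(curve: FdrCurve, alpha: float = 0.05) -> list[str]:
    """Genes at ranks 1..r*, r* the largest rank with fdr(r) <= alpha."""
    r_star = _cut_rank(curve, alpha)
    return curve.table["gene_id"].iloc[:r_star].tolist()


def roc_vs_fdr(curve: FdrCurve, positives: set[str]) -> pd.DataFrame:
    """(fdr(r), TPR(r)) at every rank, for a gold-standard positive set."""
    pos = set(positives) & set(curve.table["gene_id"])
    if not pos:
        raise ValueError("positive set is empty (or disjoint from scored genes)")
    is_pos = curve.table["gene_id"].isin(pos)
    tpr = is_pos.cumsum() / len(pos)
    return pd.DataFrame({"rank": curve.table["rank"], "fdr": curve.table["fdr"],
                         "tpr": tpr.to_numpy()})


def tpr_at_fdr(curve: FdrCurve, positives: set[str], alpha: float = 0.05) -> float:
    """Fraction of the positive set recovered among hits at estimated alpha."""
    pos = set(positives) & set(curve.table["gene_id"])
    if not pos:
        raise ValueError("positive set is empty (or disjoint from scored genes)")
    hits = set(call_hits(curve, alpha))
    return len(pos & hits) / len(pos)


def expression_bias_profile(
    hits: set[str],
    expression: pd.Series,
    rpkm_threshold: float = 1.0,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Hit fraction per expression-quantile bin among expressed genes.

    Bins are deciles (by default) of log RPKM over genes at or above the
    expression threshold; a flat profile means hit calling is unbiased
    with respect to expression level. A chi-square p-value for
    uniformity of hits across bins is attached.
    """
    expr = expression[expression >= rpkm_threshold]
    logx = np.log10(expr.astype(float))
    bins = pd.qcut(logx.rank(method="first"), q=n_bins, labels=False)
    df = pd.DataFrame({"gene_id": expr.index, "bin": bins.to_numpy()})
    df["hit"] = df["gene_id"].isin(set(hits))
    out = df.groupby("bin", as_index=True).agg(
        n_genes=("hit", "size"), n_hits=("hit", "sum"))
    out["hit_fraction"] = out["n_hits"] / out["n_genes"]
    total_hits = out["n_hits"].sum()
    if total_hits > 0:
        expected = total_hits * out["n_genes"] / out["n_genes"].sum()
        chi2 = float(((out["n_hits"] - expected) ** 2 / expected).sum())
        out.attrs["chi2_p"] = float(stats.chi2.sf(chi2, df=len(out) - 1))
    else:
        out.attrs["chi2_p"] = 1.0
    return out
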