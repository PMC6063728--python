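"""Gene-level fitness scores from guide log2 fold-changes.

A gene's effect is the maximum-likelihood estimate of a common shift
under a Normal model (a precision-weighted mean of its guides; the
plain mean when guide variances are equal). The effect is standardized
against a permutation null built by resampling size-matched guide sets
from the screen's negative-control guides, so the Z-score asks: how
extreme is this gene's mean fold-change compared with random sets of
the same number of control guides?
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fit_gene_effect",
    "zscore_permutation",
    "differential_score",
    "replicate_correlation",
    "group_by_gene",
]

SIGMA_FLOOR = 1e-9  # guards a degenerate (constant) control null
MIN_CONTROLS = 20
MIN_ITER = 100


def fit_gene_effect(lfcs, variances=None) -> float:
    """MLE of a common gene effect under a Normal model.

    With per-guide variances, the precision-weighted mean; with equal
    (or omitted) variances this reduces to the arithmetic mean.
    """
    x = np.asarray(lfcs, dtype=float)
    if x.size == 0:
        raise ValueError("fit_gene_effect requires at least one guide")
    if variances is None:
        return float(x.mean())
    v = np.asarray(variances, dtype=float)
    if v.shape != x.shape or (v <= 0).any():
        raise ValueError("variances must be positive and match the guide values")
    w = 1.0 / v
    return float((w * x).sum() / w.sum())


def group_by_gene(lfc: pd.Series, gene_of: pd.Series) -> dict[str, np.ndarray]:
    """Split a per-guide series into per-gene arrays (targeting guides only)."""
    genes = gene_of.reindex(lfc.index)
    out: dict[str, np.ndarray] = {}
    for gene, vals in lfc.groupby(genes.dropna()):
        out[str(gene)] = vals.to_numpy(dtype=float)
    return out


def _null_moments(
    controls: np.ndarray,
    sizes: set[int],
    n_iter: int,
    rng: np.random.Generator,
) -> dict[int, tuple[float, float]]:
    """mu, sigma of means of size-matched control sets, per set size.

    Sets are drawn without replacement within each iteration, mirroring
    how a real gene's guides are distinct sequences.
    """
    out = {}
    for n in sorted(sizes):
        n_eff = min(n, len(controls))
        idx = np.argsort(rng.random((n_iter, len(controls))), axis=1)[:, :n_eff]
        means = controls[idx].mean(axis=1)
        mu = float(means.mean())
        sigma = float(means.std(ddof=1))
        out[n] = (mu, max(sigma, SIGMA_FLOOR))
    return out


def zscore_permutation(
    lfc: pd.Series,
    gene_of: pd.Series,
    controls: pd.Series | np.ndarray,
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Standardize gene effects against a control-guide resampling null.

    For each gene with n guides, Z = (beta_hat - mu_null(n)) / sigma_null(n)
    where the null moments come from ``n_iter`` resampled size-n sets of
    negative-control guide log2 fold-changes. Returns a frame indexed by
    gene with columns beta, z, n_guides, rank (rank 1 = most depleted;
    ties broken by gene id) and a flag for genes with < 2 usable guides.
    """
    ctl = np.asarray(controls, dtype=float)
    ctl = ctl[~np.isnan(ctl)]
    if len(ctl) < MIN_CONTROLS:
        raise ValueError(f"need >= {MIN_CONTROLS} control guides, got {len(ctl)}")
    if n_iter < MIN_ITER:
        raise ValueError(f"n_iter must be >= {MIN_ITER}, got {n_iter}")

    per_gene = group_by_gene(lfc, gene_of)
    if not per_gene:
        raise ValueError("no targeting guides to score")
    rng = np.random.default_rng(seed)
    moments = _null_moments(ctl, {len(v) for v in per_gene.values()}, n_iter, rng)

    rows = []
    for gene in sorted(per_gene):
        vals = per_gene[gene]
        beta = fit_gene_effect(vals)
        mu, sigma = moments[len(vals)]
        rows.append({"gene_id": gene, "beta": beta, "z": (beta - mu) / sigma,
                     "n_guides": len(vals), "few_guides": len(vals) < 2})
    # rows are built in gene-id order, so a stable sort on z breaks ties
    # deterministically by gene id
    scores = pd.DataFrame(rows).set_index("gene_id")
    scores = scores.sort_values("z", kind="mergesort")
    scores["rank"] = np.arange(1, len(scores) + 1)
    return scores


def differential_score(
    drug_lfc: pd.Series,
    none_lfc: pd.Series,
    gene_of: pd.Series,
    control_ids: pd.Index | list[str],
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Context-specific (drug vs no-treatment) gene Z-scores.

    Per-guide differential delta = log2FC_drug - log2FC_none, aggregated
    and standardized exactly as the basal score; positive Z = resistance
    (knockout buffers against the drug), negative Z = synergy.
    """
    if not drug_lfc.index.equals(none_lfc.index):
        shared = drug_lfc.index.intersection(none_lfc.index)
        if len(shared) != len(drug_lfc) or len(shared) != len(none_lfc):
            raise ValueError("drug and no-treatment arms cover different guides")
        none_lfc = none_lfc.reindex(drug_lfc.index)
    delta = drug_lfc - none_lfc
    ctl_ids = pd.Index(control_ids).intersection(delta.index)
    return zscore_permutation(delta, gene_of, delta.reindex(ctl_ids),
                              n_iter=n_iter, seed=seed)


def replicate_correlation(scores_a: pd.Series, scores_b: pd.Series) -> float:
    """Pearson r between two replicate gene-score vectors."""
    shared = scores_a.index.intersection(scores_b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    r, _ = stats.pearsonr(scores_a.reindex(shared), scores_b.reindex(shared))
    return float(r)
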