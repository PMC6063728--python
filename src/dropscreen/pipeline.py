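"""End-to-end orchestration: simulate -> filter -> fold-change -> score -> FDR.

``run_pipeline`` drives the whole analysis from a single config and
writes every stage output plus a machine-readable manifest (parameters,
seed, output hashes) so a rerun from the same config is byte-identical.
The in-memory helpers (`score_screen`, `differential_screen`) are the
same stages without the file plumbing, for library use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import fdrcal, genescore, readcount, simdata

__all__ = ["RunConfig", "run_pipeline", "score_screen", "differential_screen"]


@dataclass
class RunConfig:
    """Parameters of a full run; everything that affects output lives here."""

    outdir: str = "dropscreen_run"
    mode: str = "basal"                 # basal | differential
    seed: int = 0
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    percentile: float = 10.0
    normalization: str = "total"
    pseudocount: float = 0.5
    n_iter: int = 1000
    alpha: float = 0.05
    rpkm_threshold: float = 1.0
    variant: str = "main_text"
    benefit_threshold: float = 1.0      # context-nonspecific guide removal (differential)

    def validate(self) -> None:
        if self.mode not in ("basal", "differential"):
            raise ValueError(f"mode must be 'basal' or 'differential', got {self.mode!r}")
        if self.mode == "differential" and self.sim.drug_spec is None:
            raise ValueError("differential mode requires a drug arm "
                             "(sim.drug_spec is not set)")
        self.sim.validate()


def score_screen(
    table: readcount.CountTable,
    guides: pd.DataFrame,
    condition: str = "none",
    percentile: float = 10.0,
    normalization: str = "total",
    pseudocount: float = 0.5,
    n_iter: int = 1000,
    seed: int = 0,
):
    """Counts -> filtered, normalized, replicate-averaged LFCs -> Z-scores.

    Returns (scores frame, per-guide mean log2FC, removal log).
    """
    filtered, removed = readcount.filter_low_initial(table, guides, percentile)
    norm = readcount.normalize(filtered.counts, normalization)
    t0 = filtered.t0_sample
    lfcs = [readcount.log2_fold_change(norm, t0, s, pseudocount)
            for s in filtered.final_samples(condition)]
    lfc = readcount.average_replicates(lfcs)
    gene_of = guides.set_index("guide_id")["gene_id"]
    ctl_ids = guides.loc[guides["control_class"] != "targeting", "guide_id"]
    controls = lfc.reindex(pd.Index(ctl_ids)).dropna()
    scores = genescore.zscore_permutation(lfc, gene_of, controls,
                                          n_iter=n_iter, seed=seed)
    return scores, lfc, removed


def differential_screen(
    table: readcount.CountTable,
    guides: pd.DataFrame,
    drug: str,
    benefit_threshold: float = 1.0,
    percentile: float = 10.0,
    normalization: str = "total",
    pseudocount: float = 0.5,
    n_iter: int = 1000,
    seed: int = 0,
):
    """Drug arm vs no-treatment arm -> signed differential Z-scores.

    Context-nonspecific guides (survival benefit under normal growth)
    are removed before scoring. Returns (scores, delta per guide,
    removed guide index).
    """
    filtered, _ = readcount.filter_low_initial(table, guides, percentile)
    norm = readcount.normalize(filtered.counts, normalization)
    t0 = filtered.t0_sample
    arm = {}
    for cond in ("none", drug):
        lfcs = [readcount.log2_fold_change(norm, t0, s, pseudocount)
                for s in filtered.final_samples(cond)]
        if not lfcs:
            raise ValueError(f"no final samples for condition {cond!r}")
        arm[cond] = readcount.average_replicates(lfcs)
    kept, removed = readcount.remove_context_nonspecific(
        arm["none"], arm[drug], benefit_threshold)
    gene_of = guides.set_index("guide_id")["gene_id"]
    ctl_ids = pd.Index(guides.loc[guides["control_class"] != "targeting", "guide_id"])
    scores = genescore.differential_score(
        arm[drug].reindex(kept), arm["none"].reindex(kept), gene_of,
        ctl_ids.intersection(kept), n_iter=n_iter, seed=seed)
    delta = (arm[drug] - arm["none"]).reindex(kept)
    return scores, delta, removed


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"] = simdata.config_to_dict(config.sim)
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write outputs plus a manifest under outdir.

    Outputs: guides.tsv, counts.tsv, removed_guides.tsv, scores.tsv,
    fdr.tsv (rank, gene, z, fdr, hit flag), hits.txt, manifest.json.
    Reruns with an identical config reproduce byte-identical files.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": [], "outputs": {}}

    stage = "simulate"
    try:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        guides, truth = simdata.simulate_library(sim)
        conditions = ("none",) if config.mode == "basal" else ("none", sim.drug_spec.name)
        table = simdata.simulate_screen(guides, truth, sim, conditions=conditions)
        companions = simdata.simulate_companions(truth, sim)
        simdata.write_guides_tsv(guides, out / "guides.tsv")
        table.to_tsv(out / "counts.tsv", guides)
        companions.expression.rename("rpkm").to_csv(out / "expression.tsv", sep="\t")
        truth.to_json(out / "truth.json")
        manifest["stages"].append(stage)

        stage = "score"
        if config.mode == "basal":
            scores, lfc, removed = score_screen(
                table, guides, percentile=config.percentile,
                normalization=config.normalization, pseudocount=config.pseudocount,
                n_iter=config.n_iter, seed=config.seed)
        else:
            scores, lfc, removed_idx = differential_screen(
                table, guides, drug=sim.drug_spec.name,
                benefit_threshold=config.benefit_threshold,
                percentile=config.percentile, normalization=config.normalization,
                pseudocount=config.pseudocount, n_iter=config.n_iter,
                seed=config.seed)
            removed = pd.DataFrame({"guide_id": list(removed_idx)})
        removed.to_csv(out / "removed_guides.tsv", sep="\t", index=False)
        scores.to_csv(out / "scores.tsv", sep="\t")
        manifest["stages"].append(stage)

        stage = "fdr"
        curve = fdrcal.rankwise_fdr(scores, companions.expression,
                                    rpkm_threshold=config.rpkm_threshold,
                                    variant=config.variant)
        hits = fdrcal.call_hits(curve, config.alpha)
        tbl = curve.table.copy()
        tbl["hit"] = tbl["gene_id"].isin(set(hits))
        tbl.to_csv(out / "fdr.tsv", sep="\t", index=False)
        (out / "hits.txt").write_text("\n".join(hits) + ("\n" if hits else ""))
        manifest["stages"].append(stage)
        manifest["n_hits"] = len(hits)
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    for p in sorted(out.glob("*")):
        if p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
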