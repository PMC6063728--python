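"""Seeded generator of synthetic pooled CRISPR dropout screens.

The generator emulates the statistical structure of a genome-scale
knockout fitness screen in cultured insect cells: a plasmid pool of
barcoded sgRNA expression cassettes is integrated once per cell, cells
carrying an edited fitness gene double more slowly, the pool is
bottlenecked at every passage, and guide abundance is read out by
amplicon sequencing at t = 0 (plasmid) and after ~45 days of passaging.

The generative model is deliberately simple so limiting cases have
closed forms:

* editing happens once, at integration, with per-guide probability
  ``e_i`` driven by a nucleotide position weight matrix over the 20-nt
  protospacer plus the first PAM base;
* per doubling, an unedited cell multiplies by 2 and an edited cell by
  ``2**(1 + beta_g - damage_g)`` where ``beta_g <= 0`` is the fitness
  effect and ``damage_g`` a copy-number cutting penalty;
* every passage the population is resampled multinomially to
  ``cells_per_guide * n_guides`` cells;
* sequencing is a multinomial draw over final abundances.

An expected-value mode replaces every sampling step by its expectation,
which makes closed-form oracle tests exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .readcount import AmpliconSpec, CountTable

__all__ = [
    "SimConfig",
    "ParalogSpec",
    "CnSpec",
    "DrugSpec",
    "SimTruth",
    "Companions",
    "ConfigError",
    "simulate_library",
    "simulate_screen",
    "simulate_companions",
    "simulate_reads",
    "guide_21mers",
]

BASES = "ACGT"
PWM_POSITIONS = 21  # 20 protospacer positions (5'->3') + first PAM base


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class ParalogSpec:
    """Emulated fly-to-human orthology with duplicate (paralog) families.

    frac_conserved: fraction of fly genes with at least one human ortholog.
    frac_paralog: fraction of conserved genes whose ortholog duplicated in
        the vertebrate lineage (a two-member human family).
    buffered: if True, duplicate families of a fly fitness gene each show
        weak single-knockout scores (functional redundancy buffering).
    frac_low_confidence_extra: fraction of conserved genes that also get a
        spurious low-confidence ortholog, to exercise confidence filters.
    """

    frac_conserved: float = 0.8
    frac_paralog: float = 0.35
    buffered: bool = True
    frac_low_confidence_extra: float = 0.05


@dataclass
class CnSpec:
    """Copy-number classes and the cutting penalty for amplified loci.

    fractions: copy number -> fraction of genes in that class.
    delta: per-extra-copy fitness penalty applied to edited cells.
    damage_min_copies: the penalty only applies at or above this copy
        number (amplification bias is only seen at extreme amplification).
    """

    fractions: Mapping[int, float] = field(default_factory=lambda: {2: 0.90, 4: 0.07, 8: 0.03})
    delta: float = 0.0
    damage_min_copies: int = 8


@dataclass
class DrugSpec:
    """Context-specific effects for a drug arm.

    Resistance genes acquire a positive fitness shift under drug only
    (knockout buffers against the drug); synergy genes a negative shift
    (synthetic lethality). Cells integrate the library for
    ``pretreatment_days`` before the drug window starts. Shifts are per
    doubling and compound over the treatment window, so the defaults
    produce guide enrichments of a few log2 units — the magnitude seen
    in positive-selection arms — rather than letting resistance guides
    swallow the sequencing library.
    """

    name: str = "drug"
    n_resistance: int = 10
    n_synergy: int = 10
    resistance_shift: float = 0.25
    synergy_shift: float = -0.5
    pretreatment_days: float = 15.0
    treatment_days: float = 30.0


@dataclass
class SimConfig:
    """Study conditions for a simulated screen.

    Defaults are the screen-scale parameters of the emulated protocol:
    5-day passages for 45 days at ~1 doubling/day, >=1500 cells per sgRNA
    carried per passage, 6 guides per gene, and a sequencing depth of a
    few hundred reads per guide.
    """

    n_genes: int = 1000
    frac_essential: float = 0.10
    beta_range: tuple[float, float] = (-1.0, -0.2)
    guides_per_gene: int = 6
    n_intergenic_controls: int = 250
    n_nontargeting_controls: int = 250
    pwm: np.ndarray | None = None          # 21 x 4 (ACGT); zeros => e ~ logistic(noise)
    efficiency_noise_sd: float = 1.0
    doublings_per_day: float = 1.0
    passage_interval_days: float = 5.0
    total_days: float = 45.0
    cells_per_guide: int = 1500
    read_depth_per_guide: float = 500.0
    t0_abundance_cv: float = 0.3           # lognormal dispersion of the plasmid pool
    # optional extra lognormal jitter on the integrated (cellular) pool
    # relative to the sequenced plasmid pool: a coarse stand-in for the
    # multi-guide transfection transient before all but one cassette is
    # lost. Off by default.
    t0_premix_noise_sd: float = 0.0
    frac_unexpressed: float = 0.25         # of non-essential genes, RPKM < 1
    paralog_spec: ParalogSpec = field(default_factory=ParalogSpec)
    cn_spec: CnSpec = field(default_factory=CnSpec)
    drug_spec: DrugSpec | None = None
    n_cell_lines: int = 436                # pseudo cell-line panel width
    n_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_essential", "frac_unexpressed"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "guides_per_gene", "cells_per_guide", "n_replicates"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("n_intergenic_controls", "n_nontargeting_controls"):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (self.beta_range[0] <= self.beta_range[1] <= 0.0):
            raise ConfigError(f"beta_range must satisfy lo <= hi <= 0, got {self.beta_range}")
        for name in ("doublings_per_day", "passage_interval_days", "total_days",
                     "read_depth_per_guide"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.pwm is not None:
            p = np.asarray(self.pwm, dtype=float)
            if p.shape != (PWM_POSITIONS, 4):
                raise ConfigError(f"pwm must have shape (21, 4), got {p.shape}")
        if self.efficiency_noise_sd < 0:
            raise ConfigError("efficiency_noise_sd must be >= 0")
        if self.t0_abundance_cv < 0:
            raise ConfigError("t0_abundance_cv must be >= 0")
        if self.t0_premix_noise_sd < 0:
            raise ConfigError("t0_premix_noise_sd must be >= 0")
        total = sum(self.cn_spec.fractions.values())
        if not np.isclose(total, 1.0):
            raise ConfigError(f"cn_spec.fractions must sum to 1, got {total}")
        if any(int(c) < 1 for c in self.cn_spec.fractions):
            raise ConfigError("cn_spec copy numbers must be >= 1")

    @property
    def pwm_array(self) -> np.ndarray:
        if self.pwm is None:
            return np.zeros((PWM_POSITIONS, 4))
        return np.asarray(self.pwm, dtype=float)


@dataclass
class SimTruth:
    """Ground truth of a simulated screen.

    beta: per-gene fitness effect (per-doubling growth exponent deficit).
    efficiency: per-guide editing probability in [0, 1].
    rpkm: per-gene expression; truly non-essential genes include an
        unexpressed (RPKM < 1) stratum, essential genes are expressed.
    copy_number: per-gene locus copy number (>= 1).
    plasmid_abundance: per-guide relative abundance in the plasmid pool.
    drug_effects: condition -> per-gene fitness shift applied during the
        drug treatment window.
    orthology: filled by :func:`simulate_companions`.
    """

    beta: pd.Series
    efficiency: pd.Series
    rpkm: pd.Series
    copy_number: pd.Series
    plasmid_abundance: pd.Series
    drug_effects: dict[str, pd.Series] = field(default_factory=dict)
    orthology: pd.DataFrame | None = None

    @property
    def essential_genes(self) -> pd.Index:
        return self.beta.index[self.beta < 0]

    def to_json(self, path) -> None:
        payload = {
            "beta": self.beta.to_dict(),
            "efficiency": self.efficiency.to_dict(),
            "rpkm": self.rpkm.to_dict(),
            "copy_number": {k: int(v) for k, v in self.copy_number.items()},
            "plasmid_abundance": self.plasmid_abundance.to_dict(),
            "drug_effects": {k: v.to_dict() for k, v in self.drug_effects.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class Companions:
    """Companion tables keyed consistently with the simulated library."""

    expression: pd.Series                  # fly gene -> RPKM
    orthology: pd.DataFrame                # fly_gene, human_gene, confidence, buffered
    human_fitness: pd.Series               # human gene -> negative Bayes factor
    human_expressed: pd.Series             # human gene -> bool
    ceres: pd.DataFrame                    # human gene x pseudo cell line
    copy_number: pd.Series                 # fly gene -> copies
    term_sets: dict[str, set[str]]         # term -> fly gene set


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *stream])


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    idx = rng.integers(0, 4, size=(n, length))
    lut = np.array(list(BASES))
    return ["".join(row) for row in lut[idx]]


def guide_21mers(guides: pd.DataFrame) -> pd.Series:
    """Protospacer plus the first PAM base, the 21-position convention."""
    return (guides["protospacer"] + guides["pam"].str[0]).set_axis(guides["guide_id"])


def pwm_scores(seqs: Sequence[str], pwm: np.ndarray) -> np.ndarray:
    """Sum of matrix weights over each sequence (ACGT column order)."""
    return _pwm_scores(seqs, np.asarray(pwm, dtype=float))


def _pwm_scores(seqs: Sequence[str], pwm: np.ndarray) -> np.ndarray:
    base_idx = {b: j for j, b in enumerate(BASES)}
    arr = np.array([[base_idx[b] for b in s] for s in seqs])
    return pwm[np.arange(pwm.shape[0])[None, :], arr].sum(axis=1)


def simulate_library(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a guide library and its ground truth.

    Returns a guide table (guide_id, protospacer, pam, gene_id,
    sublibrary, control_class) with ``guides_per_gene`` random guides per
    gene plus intergenic and non-targeting controls, and the matching
    :class:`SimTruth`. Guide efficiency is
    ``logistic(sum_p pwm[p, base_p] + eps)`` with Gaussian ``eps``.
    """
    config.validate()
    rng = _rng(config, 0)

    genes = [f"g{i:05d}" for i in range(1, config.n_genes + 1)]
    n_ess = int(round(config.frac_essential * config.n_genes))
    ess_idx = rng.choice(config.n_genes, size=n_ess, replace=False)
    beta = np.zeros(config.n_genes)
    lo, hi = config.beta_range
    beta[ess_idx] = rng.uniform(lo, hi, size=n_ess)
    beta_s = pd.Series(beta, index=genes, name="beta")

    # expression: essential genes are always expressed; a configured
    # fraction of neutral genes is unexpressed (RPKM < 1)
    rpkm = 1.0 + rng.lognormal(mean=3.0, sigma=1.5, size=config.n_genes)
    neutral = np.where(beta == 0.0)[0]
    n_unexpr = int(round(config.frac_unexpressed * len(neutral)))
    unexpr = rng.choice(neutral, size=n_unexpr, replace=False)
    rpkm[unexpr] = rng.uniform(0.0, 0.999, size=n_unexpr)
    rpkm_s = pd.Series(rpkm, index=genes, name="rpkm")

    # copy-number classes
    cn_vals = np.array(sorted(config.cn_spec.fractions), dtype=int)
    cn_probs = np.array([config.cn_spec.fractions[int(c)] for c in cn_vals], dtype=float)
    cn = rng.choice(cn_vals, size=config.n_genes, p=cn_probs / cn_probs.sum())
    cn_s = pd.Series(cn, index=genes, name="copy_number")

    # gene-targeted guides, split over three sublibrary groups
    records: list[dict] = []
    for i, g in enumerate(genes):
        group = f"group{(i % 3) + 1}"
        for j in range(config.guides_per_gene):
            records.append({
                "guide_id": f"{g}_sg{j + 1}",
                "gene_id": g,
                "sublibrary": group,
                "control_class": "targeting",
            })
    for k in range(config.n_intergenic_controls):
        records.append({"guide_id": f"ctrl_ig_{k + 1:04d}", "gene_id": None,
                        "sublibrary": "common", "control_class": "intergenic"})
    for k in range(config.n_nontargeting_controls):
        records.append({"guide_id": f"ctrl_nt_{k + 1:04d}", "gene_id": None,
                        "sublibrary": "common", "control_class": "non_targeting"})
    guides = pd.DataFrame.from_records(records)

    n_guides = len(guides)
    guides["protospacer"] = _random_seqs(rng, n_guides, 20)
    pam_first = rng.integers(0, 4, size=n_guides)
    guides["pam"] = [BASES[i] + "GG" for i in pam_first]
    guides = guides[["guide_id", "protospacer", "pam", "gene_id",
                     "sublibrary", "control_class"]]

    seq21 = (guides["protospacer"] + guides["pam"].str[0]).tolist()
    score = _pwm_scores(seq21, config.pwm_array)
    eps = (rng.normal(0.0, config.efficiency_noise_sd, size=n_guides)
           if config.efficiency_noise_sd > 0 else np.zeros(n_guides))
    eff = pd.Series(expit(score + eps), index=guides["guide_id"], name="efficiency")

    # plasmid pool dispersion: lognormal relative abundance with the
    # configured coefficient of variation
    if config.t0_abundance_cv > 0:
        sigma = np.sqrt(np.log1p(config.t0_abundance_cv ** 2))
        ab = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=n_guides)
    else:
        ab = np.ones(n_guides)
    ab_s = pd.Series(ab / ab.sum(), index=guides["guide_id"], name="plasmid_abundance")

    drug_effects: dict[str, pd.Series] = {}
    if config.drug_spec is not None:
        ds = config.drug_spec
        neutral_genes = [genes[i] for i in neutral]
        picked = rng.choice(len(neutral_genes), size=ds.n_resistance + ds.n_synergy,
                            replace=False)
        shift = pd.Series(0.0, index=genes)
        shift.iloc[:] = 0.0
        res = [neutral_genes[i] for i in picked[:ds.n_resistance]]
        syn = [neutral_genes[i] for i in picked[ds.n_resistance:]]
        shift[res] = ds.resistance_shift
        shift[syn] = ds.synergy_shift
        drug_effects[ds.name] = shift

    truth = SimTruth(beta=beta_s, efficiency=eff, rpkm=rpkm_s, copy_number=cn_s,
                     plasmid_abundance=ab_s, drug_effects=drug_effects)
    return guides, truth


def _damage(truth: SimTruth, config: SimConfig, genes: pd.Series) -> np.ndarray:
    cn = genes.map(truth.copy_number).fillna(2).to_numpy()
    spec = config.cn_spec
    dmg = spec.delta * np.maximum(0.0, cn - 2.0)
    dmg[cn < spec.damage_min_copies] = 0.0
    return dmg


def simulate_screen(
    guides: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
    mode: str = "stochastic",
    conditions: Sequence[str] = ("none",),
) -> CountTable:
    """Run the growth/bottleneck/sequencing model and return counts.

    Samples: one ``t0`` column drawn from the plasmid pool, plus one
    final column per (condition, replicate). In ``expected`` mode every
    sampling step is replaced by its expectation and the returned table
    holds real values.
    """
    if mode not in ("stochastic", "expected"):
        raise ValueError(f"mode must be 'stochastic' or 'expected', got {mode!r}")
    config.validate()
    missing = set(guides["guide_id"]) - set(truth.efficiency.index)
    if missing:
        raise ValueError(f"truth does not cover guides: {sorted(missing)[:5]}")
    for cond in conditions:
        if cond != "none" and (config.drug_spec is None or cond != config.drug_spec.name):
            raise ValueError(f"unknown condition {cond!r}")

    gid = guides["guide_id"]
    n_guides = len(gid)
    e = truth.efficiency.reindex(gid).to_numpy()
    beta = guides["gene_id"].map(truth.beta).fillna(0.0).to_numpy()
    dmg = _damage(truth, config, guides["gene_id"])
    ab = truth.plasmid_abundance.reindex(gid).to_numpy()
    p0 = ab / ab.sum()

    depth_total = int(round(config.read_depth_per_guide * n_guides))
    if depth_total <= 0:
        raise ValueError("sequencing depth must be positive")
    n_cells = int(config.cells_per_guide) * n_guides
    if n_cells <= 0:
        raise ValueError("cell population must be positive")

    rng_t0 = _rng(config, 2)
    if mode == "stochastic":
        t0 = rng_t0.multinomial(depth_total, p0).astype(float)
    else:
        t0 = depth_total * p0

    drugged = any(c != "none" for c in conditions)
    columns: dict[str, np.ndarray] = {"t0": t0}
    meta: list[dict] = [{"sample": "t0", "timepoint": 0.0, "replicate": 0,
                         "condition": "none"}]

    for ci, cond in enumerate(conditions):
        if drugged:
            ds = config.drug_spec
            phases = [(ds.pretreatment_days, np.zeros(n_guides))]
            shift = (guides["gene_id"].map(truth.drug_effects[cond]).fillna(0.0).to_numpy()
                     if cond != "none" else np.zeros(n_guides))
            phases.append((ds.treatment_days, shift))
        else:
            phases = [(config.total_days, np.zeros(n_guides))]
        total_days = sum(d for d, _ in phases)

        for rep in range(1, config.n_replicates + 1):
            rng = _rng(config, 3, ci, rep)
            p_cells = p0
            if config.t0_premix_noise_sd > 0 and mode == "stochastic":
                jitter = rng.lognormal(0.0, config.t0_premix_noise_sd, size=n_guides)
                p_cells = p0 * jitter
                p_cells = p_cells / p_cells.sum()
            if mode == "stochastic":
                cells = rng.multinomial(n_cells, p_cells).astype(np.float64)
                edited = rng.binomial(cells.astype(np.int64), e).astype(np.float64)
            else:
                cells = n_cells * p0
                edited = cells * e
            unedited = cells - edited

            t = 0.0
            phase_iter = iter(phases)
            phase_days, phase_shift = next(phase_iter)
            phase_end = phase_days
            while t < total_days - 1e-9:
                chunk_end = min(t + config.passage_interval_days, total_days)
                while t < chunk_end - 1e-9:
                    seg_end = min(chunk_end, phase_end)
                    d = (seg_end - t) * config.doublings_per_day
                    unedited = unedited * 2.0 ** d
                    edited = edited * 2.0 ** (d * (1.0 + beta - dmg + phase_shift))
                    t = seg_end
                    if t >= phase_end - 1e-9:
                        nxt = next(phase_iter, None)
                        if nxt is not None:
                            phase_days, phase_shift = nxt
                            phase_end = t + phase_days
                if t < total_days - 1e-9:  # passage bottleneck, not after harvest
                    w = np.concatenate([unedited, edited])
                    tot = w.sum()
                    if mode == "stochastic":
                        new = rng.multinomial(n_cells, w / tot).astype(np.float64)
                        unedited, edited = new[:n_guides], new[n_guides:]
                    else:
                        unedited = unedited * (n_cells / tot)
                        edited = edited * (n_cells / tot)

            w = unedited + edited
            p = w / w.sum()
            reads = (rng.multinomial(depth_total, p).astype(float)
                     if mode == "stochastic" else depth_total * p)
            name = f"{cond}_d{int(round(total_days))}_r{rep}"
            columns[name] = reads
            meta.append({"sample": name, "timepoint": total_days,
                         "replicate": rep, "condition": cond})

    counts = pd.DataFrame(columns, index=pd.Index(gid, name="guide_id"))
    if mode == "stochastic":
        counts = counts.astype(np.int64)
    samples = pd.DataFrame(meta).set_index("sample")
    return CountTable(counts=counts, samples=samples)


def simulate_companions(truth: SimTruth, config: SimConfig) -> Companions:
    """Emulate the external tables the comparative analyses consume.

    Orthology follows the paralog spec: conserved fly genes map to one
    human ortholog, or to a two-member human duplicate family. When
    buffering is on, each duplicate of a fly fitness gene receives weak
    single-knockout scores (redundancy hides the phenotype), while
    singleton orthologs inherit strong scores. A pseudo cell-line panel
    (CERES-style) mirrors the same structure per line.
    """
    config.validate()
    rng = _rng(config, 4)
    ps = config.paralog_spec
    genes = list(truth.beta.index)

    rows: list[dict] = []
    conf_choices = np.array(["high", "moderate"])
    for g in genes:
        if rng.random() >= ps.frac_conserved:
            continue
        paralog = rng.random() < ps.frac_paralog
        if paralog:
            fam = [f"HS_{g}_A", f"HS_{g}_B"]
        else:
            fam = [f"HS_{g}"]
        for h in fam:
            rows.append({"fly_gene": g, "human_gene": h,
                         "confidence": str(rng.choice(conf_choices)),
                         "buffered": bool(paralog and ps.buffered)})
        if rng.random() < ps.frac_low_confidence_extra:
            rows.append({"fly_gene": g, "human_gene": f"HS_{g}_lowC",
                         "confidence": "low", "buffered": False})
    orthology = pd.DataFrame(rows, columns=["fly_gene", "human_gene",
                                            "confidence", "buffered"])
    truth.orthology = orthology

    human_genes = orthology["human_gene"].unique().tolist()
    fitness = pd.Series(rng.normal(0.0, 2.0, size=len(human_genes)),
                        index=human_genes, name="neg_bayes_factor")
    ceres = pd.DataFrame(
        rng.normal(0.0, 0.25, size=(len(human_genes), config.n_cell_lines)),
        index=human_genes,
        columns=[f"line{j + 1:03d}" for j in range(config.n_cell_lines)],
    )
    beta = truth.beta
    for _, row in orthology.iterrows():
        if row["confidence"] == "low":
            continue
        b = beta[row["fly_gene"]]
        if b < 0 and not row["buffered"]:
            # singleton ortholog of a fly fitness gene: strong dependency
            fitness[row["human_gene"]] = 20.0 * abs(b) + rng.normal(0.0, 3.0)
            ceres.loc[row["human_gene"]] = rng.normal(-1.5, 0.3, size=config.n_cell_lines)
        elif b < 0 and row["buffered"]:
            # duplicate family member: phenotype masked by its paralog
            fitness[row["human_gene"]] = rng.normal(0.0, 2.0)
            ceres.loc[row["human_gene"]] = rng.normal(-0.05, 0.25, size=config.n_cell_lines)
    expressed = pd.Series(rng.random(len(human_genes)) < 0.9,
                          index=human_genes, name="expressed")

    ess = sorted(truth.essential_genes)
    neutral = sorted(set(genes) - set(ess))
    term_sets: dict[str, set[str]] = {}
    cuts = [(0, 40, "ribosome_like"), (40, 70, "proteasome_like"),
            (70, 100, "spliceosome_like")]
    for lo, hi, name in cuts:
        if len(ess) > lo:
            term_sets[name] = set(ess[lo:min(hi, len(ess))])
    if neutral:
        k = min(20, len(neutral))
        pick = rng.choice(len(neutral), size=k, replace=False)
        term_sets["peroxisome_like"] = {neutral[i] for i in pick}

    return Companions(expression=truth.rpkm.copy(), orthology=orthology,
                      human_fitness=fitness, human_expressed=expressed,
                      ceres=ceres, copy_number=truth.copy_number.copy(),
                      term_sets=term_sets)


TRACR_PREFIX = "GTTTAAGAGCTATGCTG"  # constant scaffold start after the protospacer


def simulate_reads(
    counts: pd.Series,
    guides: pd.DataFrame,
    spec: AmpliconSpec,
    barcode: str,
    rng: np.random.Generator,
) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) amplicon reads for one sequencing sample.

    Each read is stagger (1-9 random nt) + 6-nt in-line barcode + anneal
    sequence + 20-nt protospacer + scaffold prefix, the layout the
    demultiplexer expects.
    """
    proto = guides.set_index("guide_id")["protospacer"]
    k = 0
    lut = np.array(list(BASES))
    lo, hi = spec.stagger_range
    for guide_id, n in counts.items():
        for _ in range(int(n)):
            stag = "".join(lut[rng.integers(0, 4, size=rng.integers(lo, hi + 1))])
            seq = stag + barcode + spec.anneal + proto[guide_id] + TRACR_PREFIX
            k += 1
            yield f"read{k:07d}_{guide_id}", seq


def write_guides_tsv(guides: pd.DataFrame, path) -> None:
    guides.to_csv(path, sep="\t", index=False)


def read_guides_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.loc[df["gene_id"].isna(), "gene_id"] = None
    return df


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    if config.pwm is not None:
        d["pwm"] = np.asarray(config.pwm, dtype=float).tolist()
    d["cn_spec"]["fractions"] = {int(k): float(v)
                                 for k, v in config.cn_spec.fractions.items()}
    return d
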