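"""sgRNA candidate enumeration, ranking, and the nucleotide position matrix.

Candidates are all NGG-adjacent 20-mers (both strands) whose predicted
cut site — between protospacer positions 17 and 18, i.e. 3 bp from the
PAM — falls in the first half of the coding sequence. Ranking favours
guides whose 12-nt PAM-proximal seed is unique genome-wide and with few
predicted off-target sites.

The position matrix summarizes, for screened guides of strong hit
genes, which nucleobases at each of 21 positions (20 protospacer
positions 5'->3' plus the first PAM base) separate strongly depleted
("good") from unchanging ("bad") designs, as signed log10 hypergeometric
tail probabilities: positive = enriched among good guides, negative =
enriched among bad guides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import json
import numpy as np
import pandas as pd

from ._stats import hypergeom_sf, hypergeom_cdf

__all__ = [
    "CandidateGuide",
    "PositionMatrix",
    "enumerate_candidates",
    "rank_and_select",
    "classify_good_bad",
    "position_matrix",
    "seed_match_counts",
]

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")
SEED_LENGTH = 12
CUT_OFFSET = 17      # cut between protospacer positions 17/18 (1-based)
MATRIX_POSITIONS = 21


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class CandidateGuide:
    gene_id: str
    protospacer: str
    pam: str
    strand: str            # '+' or '-' relative to the CDS text
    cut_site: int          # 0-based boundary coordinate in the CDS
    seed: str              # 12 nt of the protospacer proximal to the PAM


def _iter_cds(cds) -> Iterable[tuple[str, str]]:
    if isinstance(cds, Mapping):
        yield from cds.items()
        return
    from Bio import SeqIO
    for rec in SeqIO.parse(str(cds), "fasta"):
        yield rec.id, str(rec.seq).upper()


def enumerate_candidates(cds) -> pd.DataFrame:
    """All first-half NGG candidates on both strands of each CDS.

    ``cds`` is a mapping gene_id -> sequence, or a FASTA path. Sequences
    must be plain ACGT (ambiguity codes rejected). On the minus strand
    the PAM appears as CCN in the CDS text and the emitted protospacer
    is the reverse complement of the downstream 20-mer.
    """
    rows = []
    for gene, seq in _iter_cds(cds):
        seq = seq.upper()
        bad = set(seq) - set(BASES)
        if bad:
            raise ValueError(f"{gene}: non-ACGT characters {sorted(bad)}")
        if len(seq) < 23:
            raise ValueError(f"{gene}: CDS shorter than 23 nt")
        half = len(seq) / 2.0
        # forward strand: protospacer at [i, i+20), PAM at [i+20, i+23)
        for i in range(0, len(seq) - 22):
            if seq[i + 21:i + 23] == "GG":
                cut = i + CUT_OFFSET
                if cut < half:
                    proto = seq[i:i + 20]
                    rows.append((gene, proto, seq[i + 20:i + 23], "+",
                                 cut, proto[-SEED_LENGTH:]))
        # minus strand: PAM is CCN in the text at [j, j+3), protospacer
        # is revcomp of [j+3, j+23); cut boundary lands at j+6
        for j in range(0, len(seq) - 22):
            if seq[j:j + 2] == "CC":
                cut = j + 6
                if cut < half:
                    proto = revcomp(seq[j + 3:j + 23])
                    rows.append((gene, proto, revcomp(seq[j:j + 3]), "-",
                                 cut, proto[-SEED_LENGTH:]))
    return pd.DataFrame(rows, columns=["gene_id", "protospacer", "pam",
                                       "strand", "cut_site", "seed"])


def seed_match_counts(seeds: Sequence[str], genome) -> pd.Series:
    """Occurrences of each 12-nt seed in the genome, both strands.

    ``genome`` is a mapping name -> sequence or a FASTA path. A seed
    matches wherever it, or its reverse complement, occurs in the
    genome text (overlapping occurrences counted).
    """
    index: dict[str, int] = {}
    for _, seq in _iter_cds(genome):
        s = seq.upper()
        for i in range(len(s) - SEED_LENGTH + 1):
            kmer = s[i:i + SEED_LENGTH]
            index[kmer] = index.get(kmer, 0) + 1
    out = [index.get(seed, 0) + index.get(revcomp(seed), 0) for seed in seeds]
    return pd.Series(out, index=pd.Index(seeds, name="seed"), name="seed_matches")


def rank_and_select(
    candidates: pd.DataFrame,
    genome=None,
    filters: Sequence[Callable[[pd.Series], bool]] = (),
    k: int = 8,
    off_targets: pd.Series | None = None,
) -> pd.DataFrame:
    """Filter, rank and pick the top k guides per gene.

    Filters are boolean predicates over candidate rows (efficiency and
    frame-shift criteria are plug-ins; the default passes everything).
    Survivors are sorted by (seed-match count ascending, off-target
    count ascending, cut-site position ascending) and the top k emitted;
    genes with fewer than k survivors emit all of them and are flagged
    ``short`` in the output.
    """
    if not (1 <= k <= 20):
        raise ValueError(f"k must be in [1, 20], got {k}")
    df = candidates.copy()
    for f in filters:
        df = df[df.apply(f, axis=1)]
    if genome is not None:
        uniq = seed_match_counts(df["seed"].unique().tolist(), genome)
        df["seed_matches"] = df["seed"].map(uniq)
    elif "seed_matches" not in df.columns:
        df["seed_matches"] = 0
    if off_targets is not None:
        df["off_targets"] = df["protospacer"].map(off_targets).fillna(0).astype(int)
    elif "off_targets" not in df.columns:
        df["off_targets"] = 0

    df = df.sort_values(["gene_id", "seed_matches", "off_targets", "cut_site",
                         "protospacer"], kind="mergesort")
    out = df.groupby("gene_id", group_keys=False).head(k).copy()
    sizes = out.groupby("gene_id")["protospacer"].transform("size")
    out["short"] = sizes < k
    out["design_rank"] = out.groupby("gene_id").cumcount() + 1
    return out.reset_index(drop=True)


def classify_good_bad(
    lfc: pd.Series,
    ranked_hit_genes: Sequence[str],
    gene_of: pd.Series,
    top_n: int = 500,
    good_cut: float = -1.0,
    bad_band: float = 0.25,
) -> tuple[pd.Index, pd.Index]:
    """Split guides of top hit genes into strongly depleted vs unchanging.

    ``ranked_hit_genes`` is the hit list at a strict FDR (strongest
    first); only guides of the first ``top_n`` of these genes are
    considered. Good = log2FC <= good_cut; bad = |log2FC| <= bad_band.
    """
    if good_cut > -bad_band:
        raise ValueError(f"thresholds overlap: good_cut {good_cut} > -bad_band {-bad_band}")
    genes = set(list(ranked_hit_genes)[:top_n])
    mask = gene_of.reindex(lfc.index).isin(genes)
    sub = lfc[mask.fillna(False)]
    good = sub.index[sub <= good_cut]
    bad = sub.index[sub.abs() <= bad_band]
    return good, bad


@dataclass
class PositionMatrix:
    """Signed log10 hypergeometric scores, 21 positions x ACGT.

    scores[p, b] > 0 means base b at position p is enriched among good
    (strongly depleted) guides; < 0 enriched among bad ones; 0 when the
    two tails tie exactly (identical compositions).
    """

    scores: pd.DataFrame
    good_counts: pd.DataFrame
    bad_counts: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {"scores": self.scores.to_dict(orient="index"),
                   "good_counts": self.good_counts.to_dict(orient="index"),
                   "bad_counts": self.bad_counts.to_dict(orient="index")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _base_counts(seqs: Sequence[str]) -> pd.DataFrame:
    arr = np.array([list(s) for s in seqs])
    out = pd.DataFrame(0, index=range(1, MATRIX_POSITIONS + 1), columns=list(BASES))
    for j, b in enumerate(BASES):
        out[b] = (arr == b).sum(axis=0)
    return out


def position_matrix(good_seqs: Sequence[str], bad_seqs: Sequence[str]) -> PositionMatrix:
    """Exact hypergeometric position scores from good vs bad guide sets.

    For position p and base b: population = good + bad guides, successes
    = guides carrying b at p, draws = the good set, observed x = count
    of b at p among good. With p_enr = P(X >= x) and p_dep = P(X <= x),
    score = -log10(p_enr) if enrichment is the smaller tail, log10(p_dep)
    if depletion is, and 0 at an exact tie. Tails are exact sums.
    """
    good = [s.upper() for s in good_seqs]
    bad = [s.upper() for s in bad_seqs]
    if not good or not bad:
        raise ValueError("good and bad guide sets must both be non-empty "
                         f"(got {len(good)} good, {len(bad)} bad)")
    for s in good + bad:
        if len(s) != MATRIX_POSITIONS:
            raise ValueError(f"sequences must be {MATRIX_POSITIONS} nt "
                             f"(protospacer + first PAM base); got {len(s)}")
    gc = _base_counts(good)
    bc = _base_counts(bad)
    n_good, n_bad = len(good), len(bad)
    pop = n_good + n_bad
    scores = pd.DataFrame(0.0, index=gc.index, columns=gc.columns)
    for p in gc.index:
        for b in gc.columns:
            x = int(gc.loc[p, b])
            successes = x + int(bc.loc[p, b])
            p_enr = hypergeom_sf(x, pop, successes, n_good)
            p_dep = hypergeom_cdf(x, pop, successes, n_good)
            if p_enr < p_dep:
                scores.loc[p, b] = -np.log10(p_enr)
            elif p_dep < p_enr:
                scores.loc[p, b] = np.log10(p_dep)
            # exact tie -> 0 by convention
    return PositionMatrix(scores=scores, good_counts=gc, bad_counts=bc)
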