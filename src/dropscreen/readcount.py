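"""From raw amplicon reads or count tables to per-guide log2 fold-changes.

Count tables use the conventional readcount layout (one row per sgRNA
with its target gene, one column per sequencing sample) so tables from
standard screen pipelines can be loaded directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GuideRecord",
    "CountTable",
    "AmpliconSpec",
    "demultiplex",
    "filter_low_initial",
    "normalize",
    "log2_fold_change",
    "remove_context_nonspecific",
    "average_replicates",
]

_CONTROL_CLASSES = ("targeting", "intergenic", "non_targeting")


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA of the library."""

    guide_id: str
    protospacer: str
    gene_id: str | None
    sublibrary: str
    control_class: str = "targeting"

    def __post_init__(self) -> None:
        if set(self.protospacer) - set("ACGT"):
            raise ValueError(f"{self.guide_id}: protospacer must be ACGT only")
        if self.control_class not in _CONTROL_CLASSES:
            raise ValueError(f"{self.guide_id}: bad control_class {self.control_class!r}")
        if (self.control_class == "targeting") == (self.gene_id is None):
            raise ValueError(
                f"{self.guide_id}: gene_id must be set iff control_class is 'targeting'")


@dataclass
class CountTable:
    """Guide x sample count matrix with per-sample metadata.

    counts: DataFrame indexed by guide_id, one column per sample.
    samples: DataFrame indexed by sample name with columns
        ``timepoint`` (days), ``replicate`` and ``condition``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def validate(self) -> None:
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("negative counts")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample names")
        if not set(self.counts.columns) <= set(self.samples.index):
            raise ValueError("samples metadata missing for some columns")

    @property
    def t0_sample(self) -> str:
        t0 = self.samples.index[self.samples["timepoint"] == 0]
        if len(t0) == 0:
            raise ValueError("no t0 (timepoint 0) sample present")
        return str(t0[0])

    def final_samples(self, condition: str | None = None) -> list[str]:
        m = self.samples["timepoint"] > 0
        if condition is not None:
            m &= self.samples["condition"] == condition
        return [s for s in self.samples.index[m] if s in self.counts.columns]

    def subset(self, guide_ids: Iterable[str]) -> "CountTable":
        keep = self.counts.index.intersection(pd.Index(guide_ids))
        return CountTable(counts=self.counts.loc[keep], samples=self.samples.copy())

    def to_tsv(self, path, guides: pd.DataFrame | None = None) -> None:
        """Write the standard readcount layout: sgRNA, gene, samples."""
        out = self.counts.copy()
        if guides is not None:
            gene = guides.set_index("guide_id")["gene_id"]
            out.insert(0, "gene", out.index.map(gene).fillna("NA"))
        else:
            out.insert(0, "gene", "NA")
        out.index.name = "sgRNA"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, samples: pd.DataFrame | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.drop(columns=[c for c in ("gene",) if c in df.columns])
        df.index.name = "guide_id"
        if samples is None:
            samples = infer_sample_metadata(df.columns)
        return cls(counts=df, samples=samples)


def infer_sample_metadata(names: Iterable[str]) -> pd.DataFrame:
    """Best-effort metadata from sample names like ``none_d45_r2``."""
    rows = []
    for s in names:
        parts = str(s).split("_")
        tp, rep, cond = 0.0, 0, "none"
        if s != "t0" and len(parts) >= 3:
            cond = parts[0]
            try:
                tp = float(parts[1].lstrip("d"))
                rep = int(parts[2].lstrip("r"))
            except ValueError:
                tp, rep = 1.0, 1
        elif s != "t0":
            tp, rep = 1.0, 1
        rows.append({"sample": s, "timepoint": tp, "replicate": rep, "condition": cond})
    return pd.DataFrame(rows).set_index("sample")


@dataclass
class AmpliconSpec:
    """Structure of the sequencing amplicon around the guide.

    Reads look like: random stagger (1-9 nt), a 6-nt in-line barcode
    identifying the sample/sublibrary, a fixed annealing sequence, then
    the 20-nt protospacer.
    """

    barcodes: Mapping[str, str]                 # barcode -> sample name
    anneal: str = "GTTTTCCTCAATACTTCGTTCG"
    stagger_range: tuple[int, int] = (1, 9)
    barcode_length: int = 6
    guide_length: int = 20
    barcode_mismatch: int = 0                   # 0 = exact, 1 allowed for barcodes only

    def __post_init__(self) -> None:
        if not self.anneal:
            raise ValueError("anneal sequence must be non-empty")
        bcs = list(self.barcodes)
        if len(set(bcs)) != len(bcs):
            raise ValueError("barcodes must be unique")
        if any(len(b) != self.barcode_length for b in bcs):
            raise ValueError(f"all barcodes must have length {self.barcode_length}")
        if self.barcode_mismatch not in (0, 1):
            raise ValueError("barcode_mismatch must be 0 or 1")


def _match_barcode(bc: str, spec: AmpliconSpec) -> str | None:
    if bc in spec.barcodes:
        return bc
    if spec.barcode_mismatch == 1:
        hits = [b for b in spec.barcodes
                if sum(x != y for x, y in zip(b, bc)) <= 1]
        if len(hits) == 1:
            return hits[0]
    return None


def _iter_reads(reads) -> Iterable[tuple[str, str]]:
    if isinstance(reads, (str, os.PathLike)):
        for rec in SeqIO.parse(str(reads), "fastq"):
            yield rec.id, str(rec.seq)
        return
    for item in reads:
        if isinstance(item, tuple):
            yield item[0], str(item[1])
        else:  # SeqRecord
            yield item.id, str(item.seq)


def demultiplex(
    reads,
    spec: AmpliconSpec,
    library: pd.DataFrame,
) -> tuple[CountTable, int]:
    """Assign reads to (sample, guide) cells by structured matching.

    The annealing sequence is located in each read (first exact
    occurrence); the 6 nt before it are the in-line barcode and the
    20 nt after it the guide, matched exactly against the library
    protospacers. Reads failing any step are counted unassigned, so
    assigned + unassigned always equals the number of reads.

    ``reads`` may be a FASTQ path, an iterable of SeqRecords, or an
    iterable of (id, sequence) pairs.
    """
    proto = library["protospacer"]
    if proto.duplicated().any():
        dups = sorted(proto[proto.duplicated()].unique())
        raise ValueError(f"duplicate protospacers in library: {dups[:5]}")
    guide_of = dict(zip(proto, library["guide_id"]))

    samples = list(dict.fromkeys(spec.barcodes.values()))
    counts = pd.DataFrame(
        0, index=pd.Index(library["guide_id"], name="guide_id"),
        columns=samples, dtype=np.int64)
    unassigned = 0
    anneal = spec.anneal.upper()
    blen, glen = spec.barcode_length, spec.guide_length

    for _, seq in _iter_reads(reads):
        seq = seq.upper()
        pos = seq.find(anneal)
        if pos < blen or len(seq) < pos + len(anneal) + glen:
            unassigned += 1
            continue
        bc = _match_barcode(seq[pos - blen:pos], spec)
        guide = guide_of.get(seq[pos + len(anneal):pos + len(anneal) + glen])
        if bc is None or guide is None:
            unassigned += 1
            continue
        counts.loc[guide, spec.barcodes[bc]] += 1

    meta = infer_sample_metadata(samples)
    return CountTable(counts=counts, samples=meta), unassigned


def filter_low_initial(
    table: CountTable,
    guides: pd.DataFrame,
    percentile: float = 10.0,
    t0: str | None = None,
) -> tuple[CountTable, pd.DataFrame]:
    """Strip guides below the given percentile of initial readcounts.

    Within each sublibrary, guides whose t0 count is strictly below the
    linear-interpolation sample percentile of that sublibrary's t0
    counts are removed from every sample. Returns the filtered table and
    a log of removed guides (guide_id, sublibrary, t0 count, cutoff).
    """
    if not (0.0 <= percentile <= 100.0):
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    t0 = t0 or table.t0_sample
    sub = guides.set_index("guide_id")["sublibrary"]
    t0_counts = table.counts[t0]
    removed_rows = []
    keep: list[str] = []
    for lib, ids in t0_counts.groupby(sub.reindex(t0_counts.index)).groups.items():
        vals = t0_counts.loc[ids]
        cutoff = float(np.percentile(vals.to_numpy(), percentile))
        below = vals.index[vals < cutoff]
        keep.extend(vals.index.difference(below))
        for g in below:
            removed_rows.append({"guide_id": g, "sublibrary": lib,
                                 "t0_count": vals[g], "cutoff": cutoff})
    removed = pd.DataFrame(removed_rows,
                           columns=["guide_id", "sublibrary", "t0_count", "cutoff"])
    kept = table.counts.index.intersection(pd.Index(keep))
    out = CountTable(counts=table.counts.loc[kept], samples=table.samples.copy())
    return out, removed


def normalize(counts: pd.DataFrame, method: str = "total") -> pd.DataFrame:
    """Column normalization of a raw count matrix.

    ``total``: scale each column to the mean column sum.
    ``median_ratio``: size factors as the median across guides (with
    all-positive counts) of the ratio to the per-guide geometric mean.
    """
    if isinstance(counts, CountTable):
        counts = counts.counts
    arr = counts.astype(float)
    sums = arr.sum(axis=0)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise ValueError(f"all-zero sample columns: {bad}")
    if method == "total":
        return arr * (sums.mean() / sums)
    if method == "median_ratio":
        pos = arr[(arr > 0).all(axis=1)]
        if pos.empty:
            raise ValueError("no guide has positive counts in every sample")
        log_gm = np.log(pos).mean(axis=1)
        size = np.exp(np.log(pos).sub(log_gm, axis=0).median(axis=0))
        return arr / size
    raise ValueError(f"unknown normalization method {method!r}")


def log2_fold_change(
    normalized: pd.DataFrame,
    t0: str,
    final: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """log2((final + pc) / (t0 + pc)) on normalized values."""
    for s in (t0, final):
        if s not in normalized.columns:
            raise KeyError(f"sample {s!r} not in table")
    lfc = np.log2(normalized[final] + pseudocount) - np.log2(normalized[t0] + pseudocount)
    lfc.name = f"log2fc_{final}"
    return lfc


def average_replicates(lfcs: Iterable[pd.Series]) -> pd.Series:
    """Mean per-guide log2 fold-change across replicate arms."""
    df = pd.concat(list(lfcs), axis=1)
    out = df.mean(axis=1)
    out.name = "log2fc"
    return out


def remove_context_nonspecific(
    basal_lfc: pd.Series,
    drug_lfc: pd.Series,
    benefit_threshold: float,
) -> tuple[pd.Index, pd.Index]:
    """Drop guides giving a survival benefit under normal growth.

    Guides whose no-treatment log2 fold-change exceeds the benefit
    threshold vary too widely under selection to score; they are
    excluded from differential scoring. Returns (kept, removed) guide
    indices over the shared guide set. Applies to drug-screen mode only.
    """
    shared = basal_lfc.index.intersection(drug_lfc.index)
    removed = shared[basal_lfc.reindex(shared) > benefit_threshold]
    kept = shared.difference(removed)
    return kept, removed
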