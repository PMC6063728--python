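"""Demultiplex amplicon reads into a guide x sample count table.

Builds a small library, emits structured amplicon reads for two in-line
barcoded samples (stagger + barcode + annealing sequence + protospacer),
and recovers the counts by structured matching. Assigned plus unassigned
always equals the number of input reads.
"""

import numpy as np
import pandas as pd

import dropscreen as ds
from dropscreen.simdata import simulate_reads

rng = np.random.default_rng(7)
cfg = ds.SimConfig(n_genes=6, guides_per_gene=2, n_intergenic_controls=2,
                   n_nontargeting_controls=2, seed=7)
guides, _ = ds.simulate_library(cfg)

spec = ds.AmpliconSpec(barcodes={"AAACCC": "day0", "GGGTTT": "day45"})
wanted = pd.Series(rng.integers(1, 6, len(guides)), index=guides["guide_id"])
reads = list(simulate_reads(wanted, guides, spec, "AAACCC", rng))
reads += list(simulate_reads(wanted, guides, spec, "GGGTTT", rng))
reads.append(("garbage", "ACGT" * 15))  # no annealing sequence -> unassigned

table, unassigned = ds.demultiplex(reads, spec, guides)
print(f"reads in: {len(reads)}; assigned: {int(table.counts.to_numpy().sum())}; "
      f"unassigned: {unassigned}")
print(table.counts.head(6))
print("\nEach read is located by its annealing sequence; the 6 nt before")
print("it name the sample and the 20 nt after it must match a library")
print("protospacer exactly.")
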