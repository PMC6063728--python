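"""Cross-species comparisons: paralog buffering and copy-number bias.

Maps each fly fitness gene to its most essential expressed human
ortholog and compares cumulative essentiality (negative Bayes factor)
between genes whose ortholog duplicated in the vertebrate lineage
(paralog stratum) and singletons; redundancy buffers the duplicates, so
their curve runs lower. Separately, measures per-copy-number-bin
dropout to show the cutting penalty is specific to extreme
amplification.
"""

import dropscreen as ds

cfg = ds.SimConfig(seed=5)
guides, truth = ds.simulate_library(cfg)
comp = ds.simulate_companions(truth, cfg)

flags = ds.paralog_flags(comp.orthology)
chosen = ds.most_essential_orthologs(comp.orthology, comp.human_fitness,
                                     comp.human_expressed)
ess = set(truth.essential_genes)
for name, is_par in (("singleton", False), ("paralog", True)):
    flys = [g for g in chosen.index if g in ess and bool(flags.get(g, False)) == is_par]
    ordered = sorted(chosen[flys], key=lambda h: -comp.human_fitness[h])
    curve = ds.cumulative_essentiality(ordered, comp.human_fitness)
    print(f"{name:9s} stratum: {len(ordered):3d} orthologs, "
          f"mean cumulative essentiality {curve.mean():6.1f}")
counts, missing = ds.dependency_counts(sorted(chosen), comp.ceres, cutoff=-0.8)
print(f"dependency calls over {comp.ceres.shape[1]} pseudo cell lines: "
      f"median {counts.median():.0f} per gene ({len(missing)} genes absent)")

# copy-number bias on a neutral screen with damage only at >= 8 copies
cn_cfg = ds.SimConfig(n_genes=2000, frac_essential=0.0, seed=5,
                      cn_spec=ds.CnSpec(fractions={2: 0.60, 4: 0.27, 5: 0.10, 8: 0.03},
                                        delta=0.05, damage_min_copies=8))
g2, t2 = ds.simulate_library(cn_cfg)
tbl = ds.simulate_screen(g2, t2, cn_cfg)
sc, _, _ = ds.score_screen(tbl, g2, n_iter=1000, seed=5)
summary = ds.copy_number_bias(sc, t2.copy_number, extreme_cn=8)
print("\ncopy-number bins (depletion ratio vs 1-2 copies):")
print(summary[["n_genes", "mean_depletion", "ratio"]].to_string())
print("\nThe buffered paralog stratum scores far lower than singletons —")
print("redundant duplicates hide from single-knockout screens — and the")
print("cutting artifact appears only in the extreme-amplification bin.")
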