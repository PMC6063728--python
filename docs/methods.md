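# Methods

This note documents the models, parameters, numerical conventions, and known
limitations behind `dropscreen`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Generative model of a dropout screen

The synthetic-screen generator emulates single-copy integration of a pooled
sgRNA library followed by extended passaging. Its design goal is closed-form
expectations in limiting cases, not biochemical fidelity.

**Library.** Each of `n_genes` genes receives `guides_per_gene` random 20-nt
protospacers with an NGG PAM; intergenic and non-targeting negative controls
are appended (controls target no gene and carry no fitness effect). A
configured fraction of genes is essential with per-doubling fitness deficit
`beta ~ Uniform(beta_min, beta_max)`, `beta <= 0`; all others have
`beta = 0`.

**Editing.** A cell is edited once, at integration, with per-guide
probability

    e_i = logistic( sum_p W[p, base_i(p)] + eps ),  eps ~ Normal(0, sd)

over the 21-position convention (20 protospacer positions 5'→3' plus the
first PAM base). `W` is the 21×4 efficiency matrix (zeros by default, so
e ≈ logistic(eps)). The real delayed-editing/multi-cassette transient of a
transfection-delivered library is not modeled mechanistically; an optional
lognormal "pre-mixing" jitter (`t0_premix_noise_sd`, off by default)
decorrelates the integrated cell pool from the sequenced plasmid pool as a
coarse stand-in.

**Growth.** Per doubling, an unedited cell multiplies by 2; an edited cell
by `2^(1 + beta_g - damage_g + drug_shift_g)` where
`damage_g = delta * max(0, c_g - 2)` applies only when the locus copy number
`c_g` is at or above `cn_damage_min_copies` (default 8) — amplification-
driven cutting toxicity is only seen at extreme copy number. Drug shifts
apply only during the treatment window of a drug arm.

**Passaging and sequencing.** Every `passage_interval_days` (default 5) the
population is resampled multinomially to `cells_per_guide × n_guides`
cells. Sequencing draws `read_depth_per_guide × n_guides` reads
multinomially from final abundances; the t0 sample is drawn from the plasmid
pool, whose per-guide abundance is lognormal with configurable CV (the
plasmid dispersion is not pinned by any protocol measurement; 0.3 is a
typical pooled-cloning spread). An **expected-value mode** replaces every
draw by its expectation, making oracle tests exact (e.g. a fully edited
`beta = -1` gene ends at exactly `2^-45` relative abundance after 45
doublings).

### Default study conditions

| parameter | default | unit / meaning |
|---|---|---|
| `total_days` / `doublings_per_day` | 45 / 1.0 | screen duration; ~1 doubling per day |
| `passage_interval_days` | 5 | days between bottlenecks |
| `cells_per_guide` | 1500 | library representation per passage |
| `guides_per_gene` | 6 | reagent multiplicity |
| `read_depth_per_guide` | 500 | mean sequencing reads |
| `frac_essential` | 0.10 | fraction of genes with beta < 0 |
| `beta_range` | [-1.0, -0.2] | per-doubling fitness deficit of essentials |
| `n_intergenic/nontargeting_controls` | 250 + 250 | permutation-null pool |
| `efficiency_noise_sd` | 1.0 | wide per-guide efficacy spread (most e in ~0.1–0.9) |
| `frac_unexpressed` | 0.25 | neutral genes with RPKM < 1 |
| `t0_abundance_cv` | 0.3 | plasmid pool lognormal CV |
| CN classes | {2: 0.90, 4: 0.07, 8: 0.03} | delta = 0 unless configured |
| drug shifts | +0.25 / −0.5 per doubling | resistance / synergy over a 15 + 30 day arm |

Drug shifts were sized so resistance guides gain a few log2 units over the
treatment window, the magnitude positive-selection arms actually show; much
larger shifts make a handful of guides swallow the sequencing library, which
is a pathology of the model, not of real screens.

**Companion tables.** 80% of fly genes are conserved; 35% of conserved genes
have a two-member human duplicate family, the rest are singletons (a few
extra low-confidence pairs exercise the confidence filter). Buffering:
duplicates of a fly fitness gene get near-null human knockout scores
(negative Bayes factor ~ Normal(0,2); CERES ~ Normal(−0.05, 0.25) per line),
while singleton orthologs of essentials inherit strong scores
(negBF ≈ 20·|beta|; CERES ~ Normal(−1.5, 0.3)). Expression flags are true
for 90% of human genes. Gold-standard "complex" term sets are slices of the
essential gene list plus a neutral decoy set.

## Scoring model

`beta_hat` per gene is the Normal-model MLE of a common shift — the
precision-weighted mean of guide LFCs, reducing to the arithmetic mean for
equal variances. The null is built by resampling, without replacement within
each iteration, size-matched sets from the control-guide LFCs (both control
classes by default; 1000 iterations). Size-matching is per guide count, so
genes keeping 4 guides after filtering are compared to 4-guide control sets.
Genes that lose every guide to filtering are absent from the score table
(unscored), never reported as Z = 0. A degenerate null (constant controls)
is floored at `sigma = 1e-9` rather than dividing by zero. On pure-null
screens the pooled tail fraction P(Z < −1.645) is ~0.05 (computed by the
test suite and the acceptance script).

Differential (drug) scoring first removes context-nonspecific guides whose
no-treatment LFC exceeds a benefit threshold (default +1), then scores
`LFC_drug − LFC_none` identically; this filter applies only in drug mode.

## FDR estimator and its honest behavior

Two variants are implemented because the quantity is defined two ways in
common use: `main_text` (cumulative unexpressed count divided by rank, the
default used for hit calling) and `legend_normalized` (divided by the total
possible errors). The curve is reported raw — no monotonization, no pi0
correction; a running-minimum smoothing exists for plotting only. Ties in Z
break lexicographically by gene id so ranks are reproducible. Hits at level
alpha are ranks up to the **largest** r with fdr(r) ≤ alpha (the q-value-like
convention; a raw curve can dip back under alpha after a local excursion).
Genes missing from the expression table are an error, not silently dropped.

A structural property the package measures rather than hides: the estimator
only *sees* the unexpressed fraction of false positives. If a fraction `u`
of truly-neutral genes is unexpressed and noise ranks neutral genes
exchangeably, then at a boundary set by estimated FDR = alpha the realized
false-discovery proportion approaches `alpha / u` once hits extend past the
block of true essentials (~20% at alpha = 5%, u = 0.25 under the default
conditions — the acceptance battery computes this number). In real data `u`
among false positives is higher (artifacts concentrate in unexpressed,
poorly covered genes), so the estimator behaves better there than in this
worst-case simulation; the simulation makes the gap explicit instead of
tuning it away.

## Guide design conventions

Coordinates are 0-based half-open; the cut site is the boundary between
protospacer positions 17 and 18 (3 bp from the PAM), and candidates must cut
strictly within the first half of the CDS. Both strands are searched (minus-
strand PAMs appear as CC-dinucleotides in the CDS text). The seed is the 12
protospacer nucleotides adjacent to the PAM; "downstream of the PAM" in
screen-derived design lore is orientation-ambiguous, so the PAM-proximal
reading is implemented and the convention is documented here rather than
silently assumed. Seed uniqueness counts occurrences of the seed and its
reverse complement in the supplied genome text (palindromic seeds therefore
count twice per site — consistent between ranking and its oracle).
Efficiency/frame-shift filters from design pipelines are plug-in predicates
(pass-all default); their algorithms are out of scope.

Good/bad classification thresholds (`good_cut = −1`, `bad_band = 0.25` on
replicate-averaged LFC, guides restricted to the top 500 genes at 2% FDR)
are not dictated by any measurement; they are configurable and logged. The
position matrix uses exact integer hypergeometric tails (`math.comb`), so
agreement with brute-force enumeration is limited only by one final float
division; at an exact two-tail tie the score is 0 by convention.

## Comparative analyses

Ortholog selection uses high/moderate-confidence pairs only, excludes
unexpressed human genes, and takes the maximal fitness score (ties resolve
to the lexicographically first gene, deterministically). Cumulative
essentiality curves order each stratum by descending score before running
the mean — the ordering is part of the display convention. The CERES fitness
cutoff defaults to −0.8: the printed convention "< 0.8" is sign-ambiguous
against the score's negative essential scale, so the cutoff is a parameter
rather than a hard-coded guess. The RNAi re-analysis keeps single-target
amplicons, re-standardizes scores screen-wide ((x − mean)/sd — the original
screen's exact standardization is not restated anywhere accessible, so this
stand-in is isolated behind the function interface), and assigns each gene
its largest-|Z| retained amplicon.

## Numerical and procedural choices

- Percentile filtering uses the linear-interpolation sample percentile with
  strict "below" removal, per sublibrary. Re-applying the filter recomputes
  the percentile on the survivors and can remove more guides; the operation
  is idempotent only at ties. The removal list is always returned for
  logging.
- `median_ratio` normalization computes size factors over guides with
  all-positive counts (DESeq-style); `total` scales columns to the mean
  column sum. Both are provided because count pipelines differ on this
  point; `total` is the default.
- Pseudocount 0.5 on both numerator and denominator of the fold-change. A
  nonzero pseudocount is deliberately not scale-free.
- log2 of noisy counts has an O(CV²) Jensen bias (~−0.004 at default depth
  and bottlenecking) — systematic but an order of magnitude below per-guide
  noise; neutrality checks are made at the distribution scale.
- All randomness flows through `numpy.random.default_rng` seeded from the
  config; replicates and arms use disjoint child streams, so identical
  configs are byte-identical end to end (the pipeline manifest records
  parameters and output hashes to prove it).

## Problem sizes

Test batteries run at desk scale, chosen to keep the full suite in minutes
while leaving comfortable statistical power: 1000-gene screens (6500 guides)
for the FDR/recovery/PWM batteries (20 seeds), 200-gene pure-null screens
for calibration (50 seeds), a 2000-gene neutral screen for copy-number
specificity, and 10,000 reads for demultiplexing conservation. A full
simulated screen of this size scores in roughly a second.

## Limitations

The generator does not model integration biochemistry, plasmid dilution,
antibiotic selection, guide-specific off-target toxicity, or time-varying
editing; efficiency is sequence-driven but position-independent within the
protospacer beyond the matrix convention. Companion tables emulate the
*structure* of orthology/fitness/CN/expression resources, not their content:
passing tests demonstrates the statistics behave as designed under the
declared model, not that any biological conclusion transfers to a specific
organism or cell line.
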