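# Methods

This note documents the models and procedures implemented in regulomekit,
the parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that affect
results. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)`. BED input
is native; GTF-style annotation (1-based inclusive) is converted on read.
The TSS of a plus-strand gene is `start`; for a minus-strand gene it is
`end − 1`, the last covered base, so that every anchor is a position the
gene actually covers (a single-base gene has TSS = TES on either strand).
Interval sort order is (chromosome lexicographic, start, end), ties broken
by score descending then input order; a peak without a recorded summit
defaults to the interval midpoint `floor((start+end)/2)`. These choices
remove the off-by-one ambiguities that plague mixed-convention pipelines;
they are asserted by round-trip and involution tests.

## Consensus shortlisting

Significance is `q < α` strictly, with q-values from the
Benjamini–Hochberg step-up procedure (`statsmodels` implementation behind
the `bh_fdr` surface; an independent O(n²) oracle in the test suite checks
it). Direction is the sign of log2 fold change; a significant row with
log2FC exactly 0 raises, since its direction is undecidable. The
*reproducible* set requires significance in both knockdown comparisons
with equal signs and no significance in the transfection-control
comparison; the *rescued* set requires significance in all three with the
shared knockdown sign opposite to the control sign. Knockdown-significant
genes whose two knockdown signs disagree are excluded and counted, not
raised — they indicate off-target effects, which is information. The total
is the size of the disjoint union (disjointness is asserted at property
level). Pathway-mode consensus applies the same rule to GSEA-style
(pathway, NES, FDR) tables, additionally requiring NES sign agreement
between the knockdowns, and orders output by mean |NES|.

ΔΔCt fold changes use the arithmetic mean of the control samples' ΔCt
(the standard convention); the control group's fold changes therefore have
geometric mean 1 by construction, and adding a constant to all Ct values
of one sample cancels exactly — both are tested invariants.

## Peak annotation

Peaks are assigned by **summit position**, not interval overlap, so the
five categories (promoter, exon, intron, downstream, intergenic) form a
partition and percentages sum to 100. Precedence is promoter > exon >
intron > downstream > intergenic, configurable; the promoter is TSS ±
3000 bp, "proximal" is TSS ± 1000 bp, and downstream extends 3000 bp past
the TES in the direction of transcription. The proximal window and the
precedence order are declared defaults — analyses of this kind rarely
print them, and they materially change the percentages, so they live in
`AnnotationConfig` rather than in code. A summit inside two genes takes
the higher-precedence category; an exact tie is broken by nearest TSS for
determinism.

Metagene profiles scale each gene body to a fixed number of bins (default
60) with fixed-bp flanks (2000 bp in 20 bins); minus-strand genes are
reversed so bin 0 is always the far 5′ flank. For peak input the per-bin
value is mean summit density in summits/kb; for track input it is the
signal sampled at bin centres. Genes shorter than the body bin count are
skipped and counted. Flank bins use genomic bp, so TSS-proximal structure
is not diluted by body scaling.

## Randomization overlap testing

The test statistic is the fraction of query intervals overlapping at least
one feature (half-open semantics), optionally after expanding features by
a `gap` ("vicinity") parameter, default 0. The null re-places each query
interval uniformly at random within its own chromosome with its length
preserved — per-chromosome interval counts and the length spectrum of the
query set are held fixed, isolating positional association from
compositional differences between chromosomes. Z = (observed − null mean)
/ null sd; the empirical p-value is `(1 + #{perm ≥ obs}) / (1 + n)`, which
can never be 0. When the null distribution is degenerate (sd = 0), Z is
reported as NaN and only the empirical p is meaningful. The implementation
vectorises all permutations against a sorted merged feature index
(binary-search stabs), which is what makes the 200-run × 500-permutation
null-calibration test affordable; an independent million-draw Monte-Carlo
oracle in the test suite checks the empirical p on a small toy.

Signal correlation is the Pearson correlation of two equally-binned
tracks, over all bins or restricted to bins intersecting a region set
(promoter windows, peak unions); restricting to an all-covering region set
equals the unrestricted result exactly, which is tested.

Motif central enrichment takes occurrence offsets relative to peak summits
as input (motif scanning is out of scope). The positional curve is a
Gaussian-kernel-smoothed histogram (σ = 10 bp, declared; smoothing affects
only the curve, never the test). The central half-width h is the smallest
symmetric window holding ≥ 50% of the raw occurrence mass, and the
enrichment p-value is a one-sided binomial tail for the count inside ±h
against the uniform expectation (2h+1)/(2W+1). This is a deliberately
plain, fully specified statistic; it is not the (unpublished) procedure
behind any particular printed motif p-value, and no numeric claim is tied
to one.

## Regulatory potential

`S_binding = Σ e^(−(0.5+4Δ))` over peak summits within ±W of the TSS, with
Δ = |summit − TSS| / W so that Δ is dimensionless on [0, 1] — the decay
formula only makes sense with a declared normalization window. W defaults
to 100 kb, the scale at which distal regulatory influence is conventionally
truncated in distance-decay target scoring on mammalian genomes. On the
compressed synthetic genomes used in tests (megabase chromosomes, ~8 kb
gene spacing) the same W would sweep in dozens of unrelated peaks per
gene, so recovery tests use W = 5 kb, matched to the generator's gene
spacing; W is a first-class config parameter for exactly this reason.

Ranks: binding descending, q ascending, rank 1 strongest, ties averaged;
q = 0 is clamped to the smallest positive float before ranking (only tie
structure matters to a rank statistic, so the clamp is inert beyond making
log-free code safe). RP = (rank_b/n)·(rank_de/n) ∈ (0, 1]. Direction
classes: up/down from the DE sign among significant genes, static =
tested and not significant (not "all remaining genes" — untested genes
are excluded from the universe by construction since both inputs must
cover it).

The direction analysis runs two-sided two-sample Kolmogorov–Smirnov tests
of RP(up) vs RP(static) and RP(down) vs RP(static), and reports the
fraction of down genes with RP below the median up-gene RP. Note that the
KS statistics are *conditional on the DE planting*: because RP contains
the DE rank, significant classes always separate from static whenever
significance exists. The null-calibration question — does the procedure
invent direction biases? — is therefore tested by drawing RP values from
one distribution and assigning labels independently, where the
false-positive rate is at the nominal level; and separately, when DE is
planted with no reference to binding, the *binding-score* distributions of
significant and static genes are statistically indistinguishable.

Expression classes follow the FPKM-triplet rule: expressed = FPKM > 0 in
at least one of three replicates, silenced = zero in all three. TSS
binding enrichment is summit density inside the merged ±window TSS
footprint of a gene set divided by genome-wide summit density (uniform
background model, declared; an empirical shuffled background is available
via the overlap module). Regulome classification marks a gene bound if
any summit lies within TSS ± 1000 bp and defines the regulome as bound ∧
differentially expressed.

## Synthetic data

Every generator is a pure function of (parameters, seed); one global seed
expands into fixed per-generator child streams of a `SeedSequence`, so
adding a generator never perturbs another's draws. Each dataset can carry
a `SyntheticTruth` sidecar; recovery tests read planted values only from
the sidecar.

- **Genomes**: genes packed without overlap by stick-breaking over each
  chromosome's free space, strands Bernoulli(1/2), class counts honoured
  exactly. Gene lengths are lognormal with class-specific medians
  (protein-coding 3 kb, lincRNA 1.5 kb, snRNA 150 bp, snoRNA 120 bp,
  miRNA 85 bp) — compressed relative to real mammalian genes so that
  megabase toy chromosomes hold thousands of genes; relative class scale
  is preserved.
- **Peaks**: a fraction π of summits land uniformly within ±window of a
  random TSS, the rest uniformly over the genome; widths truncated normal
  (default 300 ± 80 bp).
- **Feature sets**: `round(f·|peaks|)` features centred inside distinct
  random peaks; the remainder placed uniformly *avoiding* all peaks, so
  the planted overlap fraction is exact against the chosen peaks and
  chance overlap is zero by construction.
- **Signal pairs**: bivariate-normal bins with population correlation ρ,
  shifted to mean 10, sd 1 and clipped at zero (negligible mass clipped).
- **Conservation tracks**: baseline plus Gaussian bumps at summits; the
  planted "width" is the full width at half maximum, σ = FWHM/2.355.
- **DE tables**: significance is planted by constructing p-values
  directly. Genes in a planted Venn region receive p below
  α·m/(2n) — strictly under the BH threshold for their table — and all
  other genes draw p ~ Uniform(0,1); the rare uniform draws that would
  sneak past BH next to the planted block are re-drawn from
  Uniform(α, 1) until the planted significance pattern is exact (a
  bounded loop, asserted). Within the triple intersection, exactly the
  requested number of genes flip their control-comparison sign. Effect
  sizes are |N(1.5, 0.75)| log2 units with the planted sign, shrunk by
  0.15 for non-significant genes — matching the 2–9-fold changes typical
  of validated knockdown targets.
- **Binding-dependent DE** (`plant_binding_dependent_de`): promoter-bound
  genes (summit within ±1 kb of TSS) become significant with odds
  multiplied by β (default 5) over a base rate of 0.08, and significant
  bound genes are downregulated with probability 0.85 vs 0.5 for unbound —
  the planted truth behind the direction-test recovery checks.

What the generators do **not** emulate: read-level noise, fragment-size
effects, peak-caller artefacts, mappability, GC bias, correlated
replicates, isoform structure, and DE-engine-specific p-value behaviour.
Passing recovery tests therefore demonstrates correctness of the
*integration and filtering logic* under known truth, not robustness to
upstream noise sources.

## Problem sizes and determinism

The default end-to-end demo uses 2 × 10 Mb chromosomes, 2000 genes, 5000
peaks and 1000 permutations and completes in a few seconds; calibration
tests use 200 runs × 500 permutations and a million-draw oracle, sized so
the whole suite stays fast while keeping Monte-Carlo error well below the
asserted tolerances. All pipeline outputs embed the config hash and seed;
re-running a config reproduces the summary byte for byte.

## Known limitations

- One TSS per gene model; no isoform-aware promoter handling.
- The uniform-background fold enrichment inherits the usual caveat that
  genome background is not uniform in real data; the shuffled-peak
  empirical background is the conservative alternative.
- The per-chromosome randomization null preserves lengths and counts but
  not inter-peak spacing; clustered query sets inflate Z slightly relative
  to a clustering-preserving null (e.g. circular rotation, available as a
  design extension point).
- The packaged published tables are printed-precision excerpts (two
  decimal fold changes; FDR as printed); analyses over them are limited to
  that precision.
- The eQTL module implements FDR correction and cross-gene filtering of an
  existing association table only; it does not fit eQTL models.
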