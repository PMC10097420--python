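# Methods

## The problem and the design

Genomic imprinting produces parent-of-origin-dependent allelic expression.
In reciprocal crosses between inbred strains (B6 dam × Cast sire, "BxC", and
the reverse, "CxB"), strain-distinguishing SNPs let RNA-seq reads be
assigned to the maternal or paternal allele. A genuine parental effect gives
the *same* paternal share in both crosses; an effect of the Cast genome
gives *opposite* deviations, because the Cast allele is paternal in BxC and
maternal in CxB. All of the package's estimators exploit this symmetry.

## Bias metrics

Let p_BxC and p_CxB be the percent of transcripts from the paternal allele
in each cross (from pooled read counts, paternal/(paternal+maternal)·100,
or from a maternal/paternal fold change via FC/(1+FC)·100 — the published
fold-change formula string is ambiguous in its parenthesisation; the
FC/(1+FC) reading is adopted because it is the unique monotone map sending
FC=1 to 50% with limits 0 and 100).

- parental score = (p_BxC + p_CxB)/2 — strain effects cancel exactly;
- strain score = (p_BxC + (100 − p_CxB))/2 — the mean Cast-allele share;
  parental effects cancel exactly.

The pair (parental, strain) is an invertible linear transform of
(p_BxC, p_CxB): p_BxC = parental + strain − 50, p_CxB = parental − strain +
50. Tests assert exact reconstruction.

A gene's *maximum symmetric bias* is the per-tissue maximum of
max(p, 100−p) ∈ [50, 100]. If tissues achieving the maximum favour
different parents the gene's direction is "both". Biases are binned into
50–60, 60–70, 70–80, 80–90, 90–100. The published bin list states no
boundary rule; bins are left-closed right-open with the top bin closed at
100 (standard histogram convention, documented here). The canonical-
imprinting flag is strict: canonical iff bias > 70 ("more than 70% from one
allele"), so 70.0 itself is weak.

Zero informative reads raise an error rather than yielding 50%: an
undefined bias must be filtered explicitly, never mistaken for balance.

## Genomic-context classes

Distances use the interval gap (0 for overlapping intervals, ∞ across
chromosomes) rather than TSS-to-TSS — robust to annotation length and
strand, and configurable via the window. "Within 1 Mb" means gap ≤
1,000,000 bp; "more than 1 Mb" is its strict complement, making the two
published phrasings consistent. Labels, in precedence order (the classes
are disjoint):

- **class3**: within the window of a known imprinted gene;
- **class2**: otherwise, within the window of another novel candidate;
- **class1**: otherwise (novel singleton).

The implementation is a per-chromosome sorted sweep with prefix maxima of
interval ends (O(n log n)); the test suite compares it against an
independent all-pairs O(n²) oracle on hundreds of random registries.

"Flanked" vs "peripheral" within a cluster is not formally defined in the
literature this package serves; the convention adopted is midpoint-based
and strict: a class-3 gene is flanked iff known cluster members lie
strictly on both sides of its midpoint, else peripheral. Cluster membership
comes from the registry, never re-derived. ICR orientation is "meth_icr"
when the preferred parent equals the parent carrying the germline
methylation mark of the cluster's ICR, "un_icr" for the other parent,
"both" passes through, and clusters without a linked ICR yield "no_icr".

## Cross-study overlap

Studies annotate the same transcript under different symbols, so gene names
are merged by union–find over a user-supplied alias relation (the
historical alias lists are editorial, hence an input, not a constant).
Merged records span the union interval; merging across chromosomes is an
error. Membership matrices are boolean gene × study (or study-tissue)
tables; overlap is reported by degree (number of studies) and exact subset.
Rows with no memberships are dropped with a warning.

## ASE decomposition and the permutation screen

Replicates are pooled by summing counts within each cross before fractions
are formed (matching the pooled published formula); a per-replicate-mean
variant exists for the permutation statistic, which works at replicate
level. Genes with fewer than `min_reads_per_cross = 20` pooled reads in
either cross are dropped: below ~20 reads a single read moves the fraction
by ≥5 points, which is exactly the low-expression failure mode that
produces spurious weak-bias calls. TPM is computed per replicate library
from both genomes' summed counts (rate_g = count_g/length_g, scaled to sum
to 10⁶) and averaged across libraries.

The significance screen permutes maternal/paternal labels of whole
replicates (fraction f → 1−f), preserving the cross structure, with
statistic |parental% − 50| on replicate-level fractions and
p = (1 + #{perm ≥ obs})/(1 + n_perm). It is a deliberately simple,
seed-reproducible stand-in screen — not a reimplementation of any published
resampling caller, and it has no "undetermined" category. Tests verify
type-I error within [0.03, 0.07] at α = 0.05 over 1000 null genes and p ≤
0.01 power on strong (90:10) effects.

## Pyrosequencing validation calling

Pyrosequencing reports the paternal share at a SNP; primers can amplify the
two alleles unequally. With gDNA (true 50:50) measured per assay, the
correction divides the measured odds by the gDNA odds:
corrected = 100·o/(1+o), o = (raw/(100−raw))/(gdna/(100−gdna)). No formula
for this correction is standard; odds normalisation is chosen because it is
the unique correction that is the identity for an unbiased assay and maps
the gDNA measurement itself to exactly 50. Values at 0/100 are clamped to
[1, 99] with a warning before odds are formed. The generator applies the
exact inverse distortion, so correction recovers truth to <0.1 points at
zero noise (tested).

Calling rules: replicate means per cross, then the cross mean (strain
cancels); a tissue is paternal if its mean > 55, maternal if < 45,
biallelic in the closed window [45, 55]. Gene-level precedence:
Low_expression (no callable tissue — all below the strict 0.05×Tbp
expression gate, unmeasured, or single-cross) ≻ Placental_* (the only
out-of-window tissues are placental) ≻ directional (≥1 out-of-window
somatic tissue) ≻ Biallelic. Somatic tissues called in both directions are
resolved by majority with a recorded conflict warning — a documented
fallback the real survey never exercises. The strain-bias flag is set when
the per-tissue strain score leaves 45:55 (strictly) in more than one
tissue.

### The packaged survey and its two unreliable rows

`poebias/data/validation_summary.tsv` holds the 49-gene pyrosequencing
survey (corrected reciprocal-mean paternal percentages, 13 tissues, three
stages) with each gene's published status. The caller reproduces every
published status except two rows documented in `datasets.UNRELIABLE_ROWS`:

- **Calm1** is published as Biallelic although its P7 brain-stem mean is
  43.4; strict application of the <45 rule calls Maternal. The row also
  carries a strain-bias flag, suggesting a confound. The package applies
  the stated rule and surfaces the disagreement rather than special-casing
  it.
- **Slc25a29** shares a long run of identical values with the adjacent
  Wars row in this rendition of the table — a likely transcription
  corruption. The row is excluded from strict regression; its placenta
  value (18.9% paternal ⇒ 81.1% maternal) is independently corroborated
  and is used on its own.

## Promoter windows and signal summaries

The promoter is the 500 bp upstream of the transcriptional start site
(one description of the source heatmap says "transcription factor binding
site"; the TSS wording is adopted as the biologically standard promoter
definition): [start−500, start) on +, [end, end+500) on −, clipped at the
chromosome origin with a warning; unknown strands are an error rather than
an assumed '+'. bedGraph coverage is sparse, so the mean is weighted by
covered base pairs only (uncovered bases excluded); a zero-fill mode
averaging over the whole window is available. Overlapping track intervals
are resolved by averaging, with a warning.

## The synthetic generator

The generator emulates the study designs: 6 biological replicates per
reciprocal cross, ~10⁴ informative reads per gene per replicate, and for
pyrosequencing 4 replicates per cross with 1.5-point Gaussian assay noise
and a 55% gDNA amplification bias. Per replicate, paternal reads ~
Binomial(depth, clip(θ_p + s·θ_s, 0.02, 0.98)) with s = +1 in BxC, −1 in
CxB. Effects are additive on the *probability* scale so the reciprocal-mean
estimator is exactly unbiased whenever the clip is inactive, making the
unbiasedness tests sharp; the clip bounds merely prevent degenerate
binomials while permitting 98:2 imprinting. Registries are constructed, not
sampled: genes are placed in slots that realise their class labels by
design (seeded jitter within slots), so truth labels are exact.

What the generator does **not** emulate: mapping/SNP-coverage bias,
overdispersion beyond binomial, correlated replicates, tissue-specific
effect profiles, or annotation errors. Passing tests therefore demonstrate
correctness of the estimators and callers under the stated model, not
robustness to those real-data artefacts.

## Problem sizes and determinism

The test suite and the acceptance script use 200 random registries (5–40
candidates each), 500-gene estimator panels at depth 10⁴, and 1000 null
genes × 199 permutations for calibration — sizes at which the Monte-Carlo
error of each checked quantity is comfortably below its tolerance. Every
stochastic component takes a `numpy.random.Generator` or integer seed; same
seed, same output, byte-identical pipeline reports.

## Known limitations

- The cross-study totals of the original four-study meta-analysis require
  the per-gene supplementary list of those studies, which is not
  redistributable here; the overlap machinery is instead validated on
  synthetic data.
- The permutation screen is a screen, not a calibrated caller for small
  replicate numbers (≤2 per cross it refuses to run).
- Alias merging is only as good as the supplied alias map; no name
  normalisation is attempted.
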