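# Methods

This note documents the models and procedures implemented in `ucsomatic`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter when
reproducing results.

## Variant post-filtering

Filters operate on tumor/normal-matched calls with per-sample depths and
alt-supporting read counts. VAF is always alt/depth on the named sample.

- **Deamination filter** (C>T and its G>A strand mirror): remove when tumor
  VAF < 0.1, OR tumor coverage < 20x, OR coverage 20–99x and VAF < 0.2. The
  three clauses are a disjunction; "coverage" is tumor coverage. At ≥ 100x
  only the VAF < 0.1 clause applies. All comparisons use strict `<` at the
  printed thresholds.
- **Oxidative filter** (C>A / G>T): same thresholds, restricted to C>A whose
  5′ reference base is C or T (CCN/TCN), equivalently G>T whose 3′ base is G
  or A. Variants whose context cannot be fetched (contig edge) are kept and
  listed as warnings rather than silently dropped.
- **General filter**: keep iff tumor depth ≥ 10, normal depth ≥ 10, tumor
  VAF ≥ 0.1 (≥ 0.05 when coverage ≥ 300x), and normal VAF < 0.01.
- **Common variants**: removed at population AF ≥ 0.01 (inclusive); sites
  absent from the database are treated as rare.
- Only SNVs are subject to the two artifact filters; MNVs and indels pass
  through them and are filtered by the general rules only.
- Default chain order: common-variant → deamination → oxidative → general.
  Every filter is a pure function returning (kept, removed, report); the
  report enforces count conservation at each step, and all filters are
  idempotent, so the order is configurable without surprises.

Germline candidate selection keeps rare (AF ≤ 0.001 or unknown), bi-allelic,
well-genotyped (> 50% of cohort) truncating variants (frameshift/nonsense)
in genes one-to-one orthologous to a Cancer Gene Census gene.

## Catalogs and opportunities

SBS-96 channels use the pyrimidine convention (purine-reference
substitutions are reverse-complemented, flanks swapped and complemented).
DBS-78 canonicalizes the reference doublet by reverse complement into the
ten canonical doublets; for the four palindromic references (AT, CG, GC,
TA) the alternate doublet is collapsed onto the conventional representative
of its reverse-complement pair. ID-83 labels encode indel length (1–5+),
type, base for 1-bp events (pyrimidine representation), tandem-repeat copy
number, and — for ≥ 2 bp deletions without a tandem copy — flanking
microhomology length, computed symmetrically on both flanks so the label is
strand-invariant. Indels must arrive left-aligned in VCF-anchored form; the
classifier validates but does not realign.

Opportunities are counts of the 32 pyrimidine-centric trinucleotides over a
flank-extended, overlap-merged territory (default flank 2 bp, the
splice-site convention). Trinucleotides containing N, and territory
positions without a complete trinucleotide, are skipped with a count.

Catalog conversion between territories reweights channel `c` with context
`t` by `(target_freq(t) / source_freq(t))` and by default rescales each
sample to its original total mutation count (reweight-then-renormalize).
Whether to renormalize is genuinely ambiguous; the raw reweighted counts are
available via `preserve_totals=False`. The default preserves per-sample
mutation counts, which downstream exposure estimates are reported in.

## Signature extraction and refitting

Extraction minimizes generalized KL divergence between the catalog `V`
(channels × samples) and `W·H` using multiplicative updates, the
maximum-likelihood counterpart of Poisson-likelihood Bayesian samplers used
for the same task. Defaults: 20 random restarts, up to 2,000 iterations,
relative loss tolerance 1e-8 (checked every 10 iterations), all seeded
through `numpy.random.SeedSequence` so results are reproducible
bit-for-bit. Signature columns are normalized to probability vectors with
the scale absorbed into exposures; signatures are ordered by total
attributed mutations. The implementation agrees with scikit-learn's
KL/MU solver to < 1% in final loss on test cohorts (asserted in the test
suite; scikit-learn is used only as an independent cross-check).

Model order selection computes, for each K, the mean per-sample
reconstruction cosine and selects the last K whose gain over K−1 is at
least 0.01. The published procedure reads the elbow off a goodness-of-fit
plot by eye; the 0.01 gain threshold is a stand-in for that visual judgment
and is configurable.

Refitting against fixed signatures uses multinomial-EM (KL-NMF with frozen
`W`). The prune-and-refit rule drops signatures attributed ≤ 5% of the
fitted mutations, refits the survivors, and iterates to a fixed point; all
candidate sets visited are scored by reconstruction cosine and the best is
returned. Reference matching ranks by cosine similarity; the "confident"
cutoff defaults to 0.85 (inclusive, with a 1e-12 floating-point guard) —
chosen because similarities near 0.73 are treated as low-confidence and
0.82 as only a good resemblance in this literature — and is configurable.

The mismatch-repair-deficiency flag is a documented heuristic, not a
classifier: a sample is flagged iff its mutation rate exceeds 3× the cohort
median AND the summed exposure fraction of the MMR signature set (default
SBS6, SBS15, SBS20, SBS21, SBS26, SBS44) is ≥ 0.2. Both factors are
configurable; cohorts of fewer than 3 samples are rejected because the
median is unstable.

### Identifiability of extraction

NMF recovers signatures only up to the geometry of the cohort: the fitted
factors span the cone of observed spectra, so a signature is recoverable
only if some samples lie close to it. In a cohort whose exposures for one
signature never drop below ~0.5 (e.g. 8 samples spanning 0.49–0.89), the
minor signature's pure form lies outside the data cone and the ML solution
returns the extreme observed mixtures instead — the fit is better than the
truth factorization in likelihood, so this is a property of the data, not
an optimizer failure. The dominant, peaked signature is still recovered
(cosine ≈ 0.99), and per-sample exposures are recovered exactly by
*refitting against known signatures*, which does not suffer from this
geometry. Recovery of both signatures to cosine ≥ 0.95 and exposures to
±0.05 RMSE requires exposure spreads that approach the simplex corners, as
in the 50-sample Dirichlet cohorts used in the acceptance tests.

## Strand bias

Strand assignment uses the pyrimidine convention: the strand carrying the
mutated pyrimidine determines whether the lesion sat on the template
("transcribed") or coding ("untranscribed") strand of the covering gene.
Positions outside genes or covered by transcripts on both strands are
unassigned; overlapping same-strand transcripts collapse to one assignment.

The "exact Poisson test" of two strand counts is implemented in its exact
conditional form: given the total n, the transcribed count is
Binomial(n, ½) under the null, and the two-sided p-value sums all outcomes
whose probability does not exceed the observed outcome's (minimum-likelihood
method, ties included within 1e-12). This equals the classical exact
comparison of two Poisson rates conditioned on their sum.

## Copy number

Ploidy is the length-weighted modal total CN over segments with mean
B-allele frequency > 0.3 (balanced); ties break toward the lower CN.
Length-weighting (rather than counting segments) makes the estimate robust
to segmentation granularity. Gains and losses are relative to ploidy.

Chromothripsis-like scoring counts CN state switches after merging adjacent
equal-CN segments (so segment splits cannot inflate counts). Chromosomes
≥ 50 Mb take the maximum switch count over 50-Mb windows sliding at 1-Mb
steps — the windowing is not specified in the source procedure and is
flagged as a choice; chromosomes < 50 Mb are scored whole against thresholds
scaled by length/50 Mb and rounded half-up (30 Mb → 6/5/4). Tiers are
high ≥ 10, intermediate 8–9, low 6–7 (pre-scaling). The canonical
(2–3 distinct CN states) versus non-canonical class is evaluated over the
qualifying window.

Penetrance profiles count, per 1-Mb window, the fraction of samples with a
qualifying gain or loss (events ≥ 5 Mb only). The recurrence permutation
test relocates each sample's altered runs uniformly along the chromosome
(sizes preserved, placements independent) and compares each window's
observed altered-sample count against the null distribution of the
chromosome-wide **maximum** count: p = (1 + #{perm max ≥ observed})/(n_perm
+ 1). The max statistic controls chromosome-wide multiplicity, which makes
the per-window p-values conservative at non-peak windows and **discrete**
(multiples of 1/(n_perm+1)): calibration checks should therefore test
validity (P(p ≤ α) ≤ α; one-sided KS) rather than exact two-sided
uniformity. This frequency-based permutation stands in for footprint-style
statistics, which are out of scope.

## Cross-species comparison

Gene-level mutation status is "≥ 1 retained non-silent variant"; the silent
consequence list is configurable. Recurrence is count/n ≥ 0.05 with an
inclusive boundary (5 of 87 samples qualifies at 5.7%). Only one-to-one
ortholog pairs are compared; the table constructor rejects any gene
appearing twice on either side. The subgroup association test is Pearson's
chi-squared on the 2×2 table with 1 df and **no continuity correction** —
the uncorrected statistic reproduces the reference two-group comparison
(19/24 vs 34/63 → p = 0.0313); Yates' correction does not.

## Synthetic cohorts

The generator produces, from one seed, a random reference (default two
contigs of 400 kb and 300 kb at GC 0.42, mammalian-like), an exome of 300-bp
exons every 1 kb (~30% of the genome, giving desk-scale territories with all
32 trinucleotide contexts well represented), strand-alternating transcript
annotations, signature-driven SNV cohorts and CN segment profiles.

Each simulated mutation draws its generating signature from the sample's
exposure fractions (so configured exposures are exactly the expected
per-signature mutation fractions), then a channel proportional to signature
probability × context opportunity, then a uniform position with that
context. Read counts use a negative-binomial depth model (mean 100x tumor,
60x normal, dispersion 10) and binomial alt counts at a truncated-normal
clonal VAF (mean 0.4, sd 0.1, bounds 0.05–0.95) — the purity-diluted
heterozygous regime typical of these cohorts. Deamination-like artifacts
are injected as C>T/G>A records with uniform VAF in (0.02, 0.09), bounded
below 0.2 by construction, at a configurable fraction of the final table.

The bundled truth signatures are synthetic stand-ins, not COSMIC data: an
alkylation-like signature (strong T>C at CTC/TTC, T>A at ATA/CTA/TTA, minor
T>G, no C-channel activity), a C-channel-only CpG clock, two
mismatch-repair-like spectra, and a featureless background. The alkylation
and clock signatures have disjoint channel support by design, which makes
two-signature recovery cohorts identifiable. `synthetic_reference_db()`
exposes the stand-ins under COSMIC-style names (SBS1, SBS5, SBS6, SBS44)
solely so name-driven logic (the dMMR flag) can be exercised offline.

Cohort presets: `bovine-like` (8 samples × 5,000 mutations, alkylation
exposure 0.49–0.89), `canine-like` (12 samples × 150 mutations, one
hypermutator at 13× the cohort rate with MMR-heavy exposures, 10% injected
artifacts), and `pt-timecourse` (rising mutation counts with rising
alkylation fraction). Mutation counts are per-sample totals at desk scale;
they preserve the *relative* rate structure (13× hypermutator; high-rate vs
low-rate cohorts) rather than absolute per-Mb rates, since the synthetic
territory is ~1000× smaller than a real exome.

What the generator does **not** emulate: read-level errors and mapping
artifacts (depths are drawn, not aligned), germline contamination beyond a
zero normal-alt count, subclonal structure (single clonal VAF mode),
indel/DBS cohort simulation (classification of indels and doublets is
tested on constructed cases instead), and realistic genome composition
(uniform random sequence at fixed GC). A green recovery test therefore
establishes correctness of the statistical machinery on its stated model,
not robustness to alignment-level noise.

## Numerical choices

- All stochastic code takes explicit seeds; child streams derive from
  `SeedSequence` spawning, so adding restarts never perturbs earlier ones.
- KL-NMF guards zero rates with a 1e-12 floor; EM refitting stops when the
  L1 change in exposures falls below 1e-10 relative.
- Scaled chromothripsis thresholds round half-up (`floor(x + 0.5)`), per
  "rounded to the nearest whole number" with the 30-Mb worked example as
  the anchor (4.8 → 5, 3.6 → 4).
- BAF values > 0.5 are folded to 1 − BAF on input.
- Zero-depth normals yield normal VAF 0 but fail the general filter's depth
  clause first; zero-depth tumor candidates for artifact filters are
  rejected as malformed input.
- An all-zero spectrum refits to zero exposures with an undefined (NaN)
  reconstruction cosine rather than raising.

## Known limitations

- Extraction identifiability depends on cohort exposure geometry (above);
  the package reports reconstruction cosine per sample so users can detect
  rank-deficient cohorts, but does not warn automatically.
- The recurrence permutation null treats each sample's altered runs as
  independently placeable; correlated events (e.g. whole-arm losses shared
  by lineage) violate this null and make the test anti-conservative for
  such structures.
- DBS catalogs require both doublet bases to change; single-base changes
  inside an MNV are not decomposed back into SNVs.
- The CLI reads whole variant tables into memory; cohorts far beyond
  exome scale should use the library API streaming-style.
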