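# Methods

This note documents the models and estimators implemented in `metpool`,
the numerical choices behind them, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Read-to-barcode assignment

Barcoded amplicon/RNA-seq libraries shear cDNA randomly, so a 75-bp
read can carry a 26-nt barcode in full or only a terminal piece of it.
A barcode is a *candidate* for a read when either

1. its full sequence occurs anywhere in the read within the Hamming
   mismatch budget (`max_mismatches`, default 0; indels are not
   modelled), or
2. a terminal fragment — a barcode **prefix** flush with the read's 3'
   end, or a barcode **suffix** flush with the read's 5' end — covers
   strictly more than `min_overlap_fraction` of the barcode (default
   0.5, i.e. ≥14 of 26 nt, resolved as `floor(f·L) + 1`).

Both orientations are searched by default, since library preparation
does not fix read orientation. `N` never matches. A read with exactly
one candidate is assigned; several candidates make it *ambiguous*
(excluded from counts and tallied — splitting or winner-takes-all
assignment would bias composition estimates); none leaves it
*unassigned*. Reads containing characters outside A/C/G/T/N contribute
no candidates and are tallied separately as rejected. Paired-end mates
are collapsed to fragments: the candidate set is the union over mates,
so a fragment is never counted twice and disagreeing mates are
ambiguous. The identity `assigned + unassigned + ambiguous = fragments`
holds unconditionally.

With the default zero-mismatch budget the matcher runs on substring
search plus hash lookups of all barcode prefixes/suffixes; with
mismatches allowed it falls back to explicit Hamming scans. The test
suite checks exact agreement with an independent brute-force oracle that
enumerates every alignment offset.

## Composition and metastatic potential

Barcode fractions are `p_j = (count_j + pc) / Σ_k (count_k + pc)` with
pseudocount `pc = 0` by default; a sample with no assigned reads is
flagged undefined rather than given a made-up composition.

**Absolute potential** (cells): `M_ij = (1/n) Σ_k c_i p_j` — the mean
over the `n` mice of organ `i`'s total isolated cancer-cell count times
line `j`'s barcode fraction in that mouse.

**Relative potential** (dimensionless): counts are depth-normalized to
counts-per-million per sample; `rM_ij` is the mean normalized organ
count of line `j` over mice, divided by its mean normalized count over
pre-injection replicates. `rM = 1` means unchanged abundance relative
to the injected pool. Lines absent from every pre-injection replicate
have no defined denominator and propagate as missing (never infinity).
No pseudocount is added to organ counts: a line with zero organ reads
has `rM = 0`, which the overall-potential floor (below) handles.

**Penetrance** is the fraction of an organ's mice in which a line
passes the detection rule — by default ≥5 raw reads, a small floor that
separates presence from index-hopping-scale noise; a fractional rule
(`min_fraction`) is available. Petal-plot exports carry exactly
(potential, CI, penetrance) per line and organ: length = potential,
width = penetrance.

**Overall potential** per line is the mean over organs of
`log10(max(rM, floor))` with `floor = 1e-4`. The floor bounds the
penalty for organs with no detection (raw `log10(0)` would dominate any
average) and matches the dynamic range of the simulated potentials; the
aggregation is configurable because a single published scalar summary
of multi-organ potential has no canonical definition.

**Bootstrap confidence intervals** resample mice — the biological
replicate — with replacement, recomputing the mean statistic per
resample, with the same mouse resample applied jointly across lines and
organs so within-mouse correlation is preserved. Intervals are read
from the bootstrap distribution at *expanded* tail levels
`Φ(t_{α/2, n−1}·√(n/(n−1)))` rather than the raw `α/2`: plain
percentile intervals are systematically narrow at the cohort sizes of
this assay (5–10 mice; measured coverage ≈ 0.86–0.89 at nominal 0.95
for lognormal burdens, and scipy's percentile bootstrap reproduces
this), while the expanded levels restore ≈ 0.92 coverage at n = 10 and
≈ 0.90 at n = 5. `expand=False` gives the plain percentile interval. At
very small replicate counts a percentile interval can exclude the point
estimate; the table constructors clamp bounds to bracket it.

## In-silico mixtures and differential expression

A bulk profile measured from a pool-derived metastasis confounds
in vivo expression changes with pool composition. The control is the
composition-matched mixture `ĝ_i = Σ_j g_ij p_j`, built on the linear
scale (read proportions mix linearly in abundance, not in log space)
from the in vitro baselines of exactly the lines present in the sample;
compositions must sum to 1 within 1e-6.

Testing is paired per organ: both matrices are CPM-normalized and
log2-transformed with pseudocount 0.5 (CPM rather than trimmed-mean
normalization; the normalization step is pluggable), and per gene the
paired differences `d = log2(in vivo) − log2(in silico)` are tested
with a moderated t. Gene-wise variances `s²_g` (df `n−1`) are shrunk
toward a scaled-inverse-chi-square prior whose scale `s0²` and degrees
of freedom `d0` are estimated by matching the first two moments of the
observed variance distribution to the marginal `s0²·F(df, d0)` law;
when the observed dispersion is at or below pure sampling noise the
prior is effectively infinite and all genes share the common variance.
The moderated statistic `t = d̄ / (s̃/√n)` gains `d0` degrees of
freedom; p-values are two-sided; q-values are Benjamini–Hochberg
(implemented directly, tested against statsmodels and a brute-force
step-up). Mean–variance precision weighting is deliberately not
implemented: the bespoke content here is the mixture pairing, and the
test's null calibration is verified directly on pure-mixture
simulations. A cross-check test confirms the moderated t ranking
matches limma's eBayes (correlation > 0.95; the two moment-match the
prior on different scales, so exact equality is not expected).

Signature scores are transparent mean z-scores: each set gene is
standardized across samples and a sample's score is the mean over set
genes — invariant to gene-wise affine rescaling and adequate for
comparing samples, which is how projection scores are used here.

## Feature association

Lines are gated into potential classes by two thresholds on overall
potential (above → high, below → low, between → excluded; both
configurable — published analyses contrast "metastatic" vs
"non-metastatic" lines without canonical cutoffs). Binary features
(mutations; copy number binarized at ≤ −1 loss / ≥ +1 gain, inclusive)
are tested by Fisher's exact test on the detection 2×2 table — exact
and verifiable by tail enumeration at these class sizes — with the
detection-rate difference as the effect; continuous features use a
two-sample moderated t with the shared shrinkage machinery (pooled
variances, moderated at the modal residual df since missingness makes
df vary per feature). Missing values are dropped pairwise per feature;
constant continuous features are untestable and excluded. Effects are
signed positive when enriched in the high class; ranking is by signed
effect with ties broken by q then name, deterministically.

## Screen scoring

Guide counts are normalized by the upper-quartile method (each sample
scaled so its 75th percentile of nonzero counts equals the geometric
mean of all samples' 75th percentiles — idempotent by construction) and
log2-transformed with pseudocount 0.5. Per guide, LFC = mean over
tissue replicates − mean over reference replicates. Gene-level
inference is a one-way linear model on guide LFCs with groups = genes
plus the control class: a single residual variance pooled over all
within-group scatter (its honest df = Σ(group size − 1)), and per gene
a t contrast of its guides' mean against the control-guide mean.
Anchoring on control guides absorbs global outgrowth differences
between animals, which span orders of magnitude in intracranial
mini-pools. The complete pooling is the appropriate limit of
empirical-Bayes moderation here: a two-guide gene contributes a single
residual degree of freedom, and treating per-gene variances that all
reuse the control scatter as independent estimates overstates precision.
Depletion and enrichment calls are reported by sign; note that
normalizing a screen in which several genes drop strongly shifts
neutral guides slightly positive (a composition effect of any
depth normalization), which is why directional interpretation matters.

## Synthetic data generator

`simulate_experiment` emulates a pooled intracardiac assay:

1. a library of distinct random 26-nt barcodes, one per line;
2. pre-injection replicates sequence a nominally equimolar pool with
   multiplicative lognormal jitter (sd 0.2);
3. per mouse × organ × line: seeding ~ Bernoulli(penetrance), and a
   seeded line grows to `cells_per_line × 10^potential ×
   LogNormal(0, growth_cv)` cells;
4. the organ's composition is the cell-number simplex; sequencing draws
   a Dirichlet-multinomial with concentration `overdispersion × p`
   (multinomial in the infinite-concentration limit, which a test
   verifies);
5. total cells per (mouse, organ) — what sorting would report — is the
   sum over lines.

Defaults are the 25-lines-per-pool design: 5 organs, 5 mice per organ,
500 cells per line, potentials Uniform(−4, 1) in log10, penetrance 0.8,
growth CV 0.5 (natural-log sd), 10⁶ reads per sample, concentration
100, 3 pre-injection replicates. Penetrance 0.8 and growth CV 0.5 are
the generator's own choices of a realistic regime — incomplete
penetrance and order-of-magnitude burden variation between mice —
chosen to make recovery nontrivial; the true dispersion of the real
assay is not identifiable from published summaries. The generator does
**not** model spatial or immune biology, clonal evolution within lines,
PCR chimeras, index hopping, or barcode sequencing errors beyond the
optional uniform per-base substitution rate in `emit_fastq`; passing
recovery tests therefore demonstrates correctness of the estimators
under the stated noise model, not robustness to every artifact of real
libraries.

`simulate_expression` layers lognormal in vitro baselines per line and
builds in vivo samples as exact composition-weighted mixtures times
multiplicative lognormal noise, with a chosen organ's DE genes shifted
by `2^lfc` — precisely the structure the mixture-DE model assumes, which
is what makes its null calibration and power measurable.

## Validation experiments (`metpool.experiments`)

* **Recovery**: the default design is simulated, rM estimated, and the
  within-organ Spearman between true and estimated log potential
  (lines above the detection floor of 10⁻³, ~1 read per million at
  typical compositions) averaged over organs. Correlating within organs
  is deliberate: each organ's total read share imposes a common offset
  on its lines' log rM, which a pooled cross-organ correlation would
  mix into the ranking signal. The reported value averages 5 replicate
  simulated cohorts (single-cohort simulation noise ≈ 0.013 sd).
  Typical value ≈ 0.93.
* **Pooling-design concordance**: the same 125-line truth is assayed as
  one large pool (500 cells/line) and as five 25-line sub-pools in
  separate cohorts (10,000 cells/line) — the two formats whose
  agreement established the assay's robustness — and the floored log10
  potentials are correlated over all (line, organ) pairs. Typical
  Pearson r ≈ 0.85; the irreducible gap is pool-composition offsets
  plus seeding stochasticity, both of which the real comparison also
  faces.
* **CI coverage**: percentile-bootstrap intervals for the mean of 10
  lognormal(σ = 0.5) per-mouse burdens over 1000 simulation replicates
  (binomial measurement error ±0.9%); measured ≈ 0.92 at nominal 0.95.
* **DE calibration/power**: 2000 genes, 5 pairs; null runs keep the
  q < 0.05 fraction at ~0; 100 genes spiked at +2 log2 with noise sd
  0.5 are recovered essentially completely with median LFC within 0.1.
* **Screen recovery**: 29 genes × 2 guides + 10 controls, 3 reference
  and 5 tissue samples, 5 genes depleted at −3 LFC against lognormal
  mouse effects (sd 1.0 natural log): 5/5 recovered, ≤1 directional
  false positive across all tested seeds.

Problem sizes throughout (25–125 lines, 10⁶ reads, 1000 bootstrap and
coverage replicates, 2000 genes) were chosen so the full validation
battery runs in well under a minute on one CPU while leaving each
check statistically meaningful.

## Limitations

* Matching is substitution-only; indel-bearing barcode reads are lost
  (at 26 nt and amplicon error profiles this is a small, unbiased loss).
* rM is a ratio estimator; with ≤5 mice its bootstrap intervals are
  wide and their coverage inherits the small-n limits discussed above.
* The mixture model assumes in vitro baselines transfer to the in vivo
  context up to the tested differences; systematic culture-vs-tissue
  shifts load onto the paired differences by design (that is what the
  test reports) but cannot be separated from microenvironmental
  induction without additional controls.
* Class-threshold choice in feature association changes which lines
  enter the 2×2 tables; conclusions should be checked across a range of
  cutoffs.
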