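# metpool

Quantification of organ-specific metastatic potential from pooled,
barcoded cell-line xenograft experiments.

In a pooled in vivo metastasis assay, up to hundreds of cancer cell
lines — each carrying a stable 26-nt DNA barcode — are injected together
into the arterial circulation of mice. Weeks later, target organs
(brain, lung, liver, kidney, bone) are sequenced and each line's
metastatic output is read off from its barcode's abundance. `metpool`
implements the full desk-side analysis of such an experiment:

* **Barcode deconvolution** — assign sequencing reads to barcodes. A
  read counts for a barcode if it contains the barcode in full, or if a
  terminal barcode fragment covering *more than 50%* of it runs off a
  read end (reverse-complement aware, configurable Hamming mismatch
  budget; ambiguous reads are excluded, not split).
* **Metastatic potential** — absolute potential
  `M_ij = (1/n) Σ_k c_i p_j` (mean over mice of the organ's sorted
  cancer-cell count times the line's barcode fraction), and relative
  potential `rM_ij = mean_k(c_ij) / mean_m(p_j)` (mean depth-normalized
  organ read count over mean pre-injection read count), with penetrance
  (fraction of mice with detection) and bootstrap confidence intervals
  that resample mice.
* **Composition-corrected differential expression** — each in vivo
  profile is paired with an *in-silico mixture* `ĝ_i = Σ_j g_ij p_j` of
  its constituent lines' in vitro baselines, and paired differences are
  tested per organ with an empirical-Bayes moderated t.
* **Feature association** — two-class (high vs low potential) testing of
  mutation, binarized copy-number (loss ≤ −1, gain ≥ +1), expression and
  dependency matrices; Fisher exact for binary features, moderated t for
  continuous ones.
* **Mini-pool CRISPR screen scoring** — upper-quartile normalization and
  a control-guide-anchored linear model for per-gene depletion.
* **Forward simulation** — a generative model of the whole experiment
  (Bernoulli seeding, lognormal outgrowth, Dirichlet-multinomial
  sequencing noise, FASTQ emission) with known ground truth, so every
  stage is testable without animal data.

## Worked example

Estimate relative metastatic potential on a simulated default
experiment (25 lines, 5 organs, 5 mice per organ, one million reads per
sample):

```bash
python examples/02_metastatic_potential.py
```

```
top 5 lines by overall potential (mean floored log10 rM over organs):
  line0009   -0.07
  line0006   -0.23
  line0013   -0.42
  line0014   -0.83
  line0010   -1.17

brain potential for those lines (rM [95% CI], penetrance):
  line0009   rM=   2.642 [0.000, 6.684] penetrance=0.4
  ...
mean within-organ Spearman(truth, estimate) above detection floor: 0.935
```

`rM = 2.64` means the line is 2.6× as abundant in brain tissue as it was
in the injected pool; the interval is a bootstrap CI over the 5 mice,
and penetrance 0.4 means it was detected (≥5 reads) in 2 of 5 mice. The
Spearman line compares the estimates against the simulation's known
truth. The other scripts in `examples/` walk through read-level
quantification, mixture differential expression, feature association
(including the exact-Fisher 4/7-vs-0/14 configuration, p = 35/5985), and
screen scoring.

The same operations are available from the shell:

```bash
metpool simulate --out-dir sim/ --seed 17 --emit-fastq
metpool count --library sim/library.fasta --fastq sim/fastq/brain_0.fastq -o counts.tsv
metpool potential --counts sim/counts.tsv --library sim/library.fasta \
    --meta sim/samples.csv --bootstrap 1000 --seed 17 -o petal.csv
```

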