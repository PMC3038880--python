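# Methods

This note records the statistical model behind `imprintqc`, the defaults it
ships with, and the choices made where more than one defensible convention
exists.

## The measurement and its calling model

A pyrosequencing (PSQ) methylation assay reports, for each of 3–9 CpG
sites in a short amplicon, the percentage of template molecules methylated
at that site. At an imprinted DMR in normal tissue exactly one parental
allele is methylated, so the expected read is ~50%. The calling interval
("differential window") is derived from 50%-methylated standards:

    lower, upper = mean ± k · SD(standard readings),   k = 1.5 by default

with the sample SD (ddof = 1). On standards calibrated at mean 50.38% the
published spread implies SD = (65.03 − 50.38)/1.5 = 9.7667, giving the
window 35.73–65.03%. Bounds are inclusive (the "35%–65%" phrasing is read
as a closed interval), reported rounded to 2 decimals and kept at full
precision internally. An assay × tissue mean below the window is
*hypomethylated*, above it *hypermethylated*, inside it *differential*;
an assay is *ever differential* when at least one tissue falls inside.

Tissue means average each individual over CpGs first, then individuals
within the tissue, unweighted by CpG count, so an individual with a
dropped dispensation does not change its weight.

## Assay design

Primers are searched on the bisulfite-converted top strand (the reverse
primer against its reverse complement; strand choice is a convention, not
a claim). Constraints: Wallace-rule melting temperature 2(A+T) + 4(G+C)
within ±2 °C of 56 °C, primer length 18–30 nt, amplicon ≤ 350 bp, no CpG in
a primer footprint (so the primer sequence is identical on methylated and
unmethylated templates), and no overlap with supplied SNP positions. The
Wallace rule was chosen because the design target is a window around a
nominal temperature, not a physical hybridization prediction; length and
amplicon bounds are configurable defaults, not measured values. The search
is exhaustive over the flanking windows and deterministic: shortest
amplicon wins, ties broken leftmost. The second-round reverse primer is
the gene-specific primer prefixed with the universal biotinylated tail
`CGCCAGGGTTTTCCCAGTCACGAC` (the biotin itself is wet-lab metadata).

## Validation statistics

*Linearity*: OLS of observed on expected over the mixture series
0/25/50/75/100%; r² is the squared Pearson correlation. A flat response is
reported as r² = 0 with a warning rather than an error.

*Replicate agreement*: bias = mean(rep1 − rep2); limits of agreement
bias ± 1.96·SD(differences) (classic Bland–Altman with the sample SD —
the method is named in the source literature without parameters, so the
textbook form is used); r² from OLS of rep2 on rep1. Both the per-CpG and
per-assay-mean forms can be computed by feeding the corresponding vectors;
pairs with a missing member are dropped (pairwise deletion).

*Titration sensitivity*: per template mass, the mean of replicate means is
tested for window containment; a mass shows *allelic dropout* when any
replicate mean lies beyond the window by ≥ 20 percentage points toward a
rail (≤ lower − 20 or ≥ upper + 20). The 20-point margin is a package
default — dropout is reported qualitatively in the source literature — and
is configurable. The minimum reliable mass is the smallest mass inside the
window with no dropout.

## Stability and association tests

Tissue deviation (e.g. testis at maternal germ-line DMRs, where sperm have
erased the mark) is a matched-pair t-test across assays of (focal-tissue
mean, mean of other tissues). Maternal-vs-paternal intra-CpG variability
compares per-sample mean SDs by a matched-pair t-test (Welch unpaired as
an option). Feature associations use Welch two-sample t-tests (CTCF
binding — variable and constitutive pooled — vs none; island vs not),
one-way ANOVA over location categories (groups with n < 2 dropped with a
warning), and OLS r² for CpG density. CpG density counts top-strand CG
dinucleotides whose first base lies in a 500 bp window centred on the
amplicon midpoint, divided by 5 (CG is its own reverse complement, so
top-strand counting equals site counting); every catalog density is a
multiple of 0.2, consistent with that divisor. No multiple-testing
correction is applied anywhere; raw p-values are reported, mirroring the
single-platform descriptive analysis this package supports.

## Population screening and treatment response

The "95%/99% CI" used for outlier flagging is implemented as a normal
*reference range* for individuals, mean ± z·SD of the cohort, truncated to
[0, 100] — not a confidence interval of the mean, since individuals rather
than means are being flagged. An empirical-percentile variant is available
behind `method="percentile"`, and leave-one-out intervals behind
`leave_one_out=True`; the defaults (parametric, individual included) are
the simplest reading of the published procedure. Flags are nested by
construction (99% interval contains the 95% one).

Per-individual burden is a two-way ANOVA without replication on per-assay
z-scores (individual and assay as crossed factors), reporting the
individual main effect; more than 20% missing cells aborts, because the
unreplicated layout has no honest estimate under heavy imbalance.
Cis-cluster correlation computes r² of per-individual means for every
same-cluster assay pair (cluster membership from the catalog) and reports
the maximum.

Treatment response is percent reduction 100·(control − treated)/control
per assay and dose; a gain is a negative reduction and a zero control mean
is flagged undefined rather than 0. Ranges across replicate experiments
are attached when replicate pairs are supplied.

## Synthetic data: what it emulates and what it does not

Readings are simulated as

    value = clip(true(assay, tissue) + cpg_offset + ε, 0, 100)

with `cpg_offset ~ N(0, intra_cpg_sd)` drawn once per (assay, CpG) and
held fixed across samples (systematic dispensation bias — this is what
makes intra-CpG SD a stable per-assay property), and
`ε ~ N(0, measurement_sd)` per reading. Defaults: measurement SD 2.0%,
maternal intra-CpG SD 2.0%, paternal 5.0% — chosen to be of the order of
the ~1.6% replicate bias typical of validated PSQ assays; the source
literature gives no full noise decomposition, so these are package
defaults, not measured values. Truncated Gaussian noise was preferred to a
Beta model because PSQ percentages are aggregate peak-ratio estimates with
roughly symmetric technical error; the clip handles the rails.

Structural rules: germ-line assays whose profile omits testis get 2%
(maternal, erased in sperm) or 98% (paternal, complete in sperm); the
default tissue panel has 8 tissues × 3 individuals, matching the pooled
design of the emulated survey; the default blood cohort has 23 assays × 50
individuals with between-individual SD 1.5% and optional spiked outliers
recorded in the truth. Allelic dropout at low template replaces a 50%
reading with a draw within 3 points of a rail (equal odds), modelling
whole-allele amplification failure; the default dropout probability is
0.05 per replicate at ≤ 1 ng and 0 above. Design regions are built with
all-A/T CpG-free flanks embedding one exact-56 °C primer site per side and
an island with an exact CG count, verified by an exhaustive Tm scan before
return.

Passing tests on these cohorts show that the statistics recover known
truth under the stated noise model; they do not show robustness to
features real PSQ data can have and the generator does not model:
bisulfite conversion failure, PCR bias varying with methylation state,
probe-specific baselines, or non-Gaussian heavy tails.

## Numerical choices and degenerate inputs

Sample SD (ddof = 1) throughout; classification bounds inclusive; constant
inputs return exact null results (t = 0, p = 1) instead of NaN; linearity
on a constant predictor, reference intervals with < 3 values, paired tests
with one class absent, and windows from < 2 readings are errors. All
generators take integer seeds (numpy `default_rng`) and are reproducible
across platforms; the pipeline reruns byte-identically for a fixed config
and seed (timestamps live only in the log). Reported CSVs round
percentages to 2 decimals; the machine-readable summary keeps full
precision.

## Known limitations

- The packaged catalog is transcribed as printed (49 rows; see
  `src/imprintqc/data/README.md` for the one-row discrepancy with the
  "50 assays" text) and its positions are opaque coordinates on their
  original assembly — no liftover.
- The CpG-density association over the catalog yields r² ≈ 0.029, smaller
  than the value reported from the original per-tissue data (0.090); the
  per-tissue table behind that figure is not machine-readable, so the
  association here is computed from the catalog's somatic averages. The
  conclusion (no correlation) is unchanged.
- Tissue-level published means are not redistributable, so population and
  tissue analyses are exercised on synthetic cohorts; published counts
  such as "17/23 DMRs with outliers" are shapes the generators emulate,
  not values the package reproduces.
- The burden ANOVA assumes a near-complete individual × assay matrix and
  one value per cell; unbalanced designs need a mixed model, which is out
  of scope.
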