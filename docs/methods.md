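# Methods

## Study design and data model

The pipeline targets a two-group plasma miRNA screen: 16 healthy individuals
(HI) each sampled three times within a month (morning, fasting), and 16
glioblastoma patients (GP) with one analyzed sample each plus survival
follow-up (months, right-censored). The panel holds 734 endogenous probes
(654 human `hsa-`, 80 herpesvirus-family viral: `ebv-`, `hsv1-`, `hsv2-`,
`kshv-`, `hcmv-`), 6 positive-control and 8 negative-control probes. Counts
are direct digital molecule counts, so the natural noise model is a counting
distribution, not a continuous intensity model.

Species is inferred strictly from the probe-id prefix; an unrecognized prefix
is an error rather than a silent "human" default, because a silent default
would corrupt the viral analysis. The prefix table is explicit configuration
covering exactly the panel's five virus species.

## Background and detection

Negative controls measure non-specific binding. The per-sample detection
threshold is mean + 2·sd (sample sd, n−1) of that sample's negative-control
counts — the conventional rule for this assay family; the method is recorded
in the model object for provenance. Two filters follow:

1. **Panel-wide**: endogenous probes below threshold in ≥ 80% of all samples
   are removed ("at least 80%" read inclusively), as is `hsa-miR-720`
   regardless of signal (retired from miRBase as a likely tRNA fragment).
2. **Per-comparison**: a probe enters a two-group test only if its
   below-threshold fraction is < 20% within *each* group ("less than" read
   strictly). Boundary semantics follow the protocol wording literally.

## Normalization

Three strategies are offered. Each computes per-sample totals T_s over a
probe set (all endogenous probes; the positive controls; or the 50 endogenous
probes with lowest across-sample CV among those detected everywhere) and
scales sample s by T̄/T_s, so every sample's strategy total equals the
across-sample mean. Values are log₂(scaled count + 1); the +1 pseudocount
keeps zeros finite and is immaterial at the counts where probes pass
detection.

Strategy selection exploits the only replicate structure the design provides:
for each strategy the score is the median within-subject replicate CV (linear
scale) across (subject, probe) pairs, and the minimizing strategy wins, with
ties resolved in the fixed order total_content, positive_control_sum,
stable_set. When between-sample variation is a pure library-scale factor,
totals-based strategies remove it exactly and are selected; the selection
criterion itself (median replicate CV) is a package design choice, as no
selection metric is implied by the design other than replicate agreement.

## Variability profiling

CVs are computed on the linear scale (2^value − 1): log-scale CVs understate
high-variance probes and the conventional definition of biological CV is
linear. Intra-individual CV is per (subject, probe) over that subject's
replicates; inter-individual CV is per probe over subject means. A (subject,
probe) pair is skipped when any replicate is below background — a near-zero
mean makes the ratio unstable. The inter CV estimated this way contains a
within-subject leakage term (subject means average only 3 replicates); tests
therefore compare planted orderings well separated in variance.

## Differential expression

Per-probe Welch's unequal-variance t on log₂ normalized values, two-sided,
with Welch–Satterthwaite degrees of freedom. Welch rather than pooled-variance
Student is the safer default for plasma data with unequal group variances; a
paired t (one-sample t on differences) is provided for related samples
(pre/post-surgery). HI replicates are collapsed to subject means before the
between-group test so subjects, not repeated samples, are the experimental
units. Degenerate zero-variance probes return t=0, p=1 when means agree and
the smallest representable p when they differ.

Multiplicity: Benjamini–Hochberg step-up (the transcriptomics standard;
Bonferroni and none are configurable). Candidates require p_adj < 0.01 and
|log₂FC| ≥ 1 (two-fold), boundary inclusive — the published candidate list
itself contains a probe at exactly −1.00. log₂FC is GP mean minus reference
mean, fixing the sign convention (down-in-patients negative). The default
reference is HI subjects older than 40 to age-match the patient group;
covariate splits within HI (age 40, sex, BMI 24) use raw p at 0.05 without
adjustment because they are screened as trends, and probes with more than
half of either stratum below background are flagged near-detection-limit.

## Survival analysis

Kaplan–Meier product-limit estimation with Greenwood variance and a
log(−log S) 95% band (kept inside [0,1] by construction; medians can be
undefined under heavy censoring, which also motivates the direction rule
below). The two-group log-rank statistic sums observed minus
hypergeometric-expected events over distinct event times, with the usual
variance term; p is two-sided from χ²(1). These primitives are implemented
in-package — the scan needs thousands of cheap calls and direct access to the
Greenwood term — and are cross-checked in the test suite against lifelines
and against brute-force formula evaluation to 1e-10.

The cutoff scan splits the patients at six predetermined low:high ratios
(0.25, 0.35, 0.45, 0.55, 0.65, 0.75 assigned to the low-expression group;
scanning all six covers both orientations of the ratio notation). Group size
is ⌊r·n + 0.5⌋ with stable tie-breaking by input order — both fixed for
reproducibility. The reported split is the one with minimal log-rank p; the
cut value is the midpoint of the boundary order statistics. Direction
(high-expression-longer vs lower) compares restricted-mean survival between
the groups at the best split. Ratios that would empty a group, or leave a
split with zero events, are skipped with a warning.

The minimum over six correlated tests is anti-conservative: on null data the
scan's false-positive rate at nominal 0.05 is measured at ~0.2 (recomputed by
the acceptance script). The screen therefore emits the uncorrected
`significant` flag — the screening convention — together with a BH-adjusted
column (`p_bh`) on every run.

## Target translation

ReliefF ranks miRNAs by two-class discrimination: features min-max scaled,
k = 10 nearest hits/misses by Manhattan distance (k auto-reduced with a
warning when a class is small), weight updates ±|diff|/(m·k) over all
instances; defaults follow the algorithm's common parameterization and are
exposed in config. Entries with |log₂FC| < 0.2 are removed before translation
("lower than" strict), and ranks re-compacted.

Voting: miRNA m with rank r of M contributes s(m) = (M − r + 1)/M — a
normalized descending score in (0, 1], so the top-ranked miRNA contributes
most and scores stay bounded — multiplied by the miRNA→gene interaction
probability when the target database provides one (validated interactions
without probabilities count 1.0). A gene's score is the sum of its incoming
contributions (computed with correctly-rounded summation so reverse inference
re-sums to the forward score bit-exactly). Contributing ranks rather than raw
ReliefF weights is the package default; the weights remain available in the
ranked table.

Enrichment uses flat per-gene-set rules: one-sided Fisher exact
(hypergeometric tail) of the top-voted genes against each set, BH-corrected,
retained at p ≤ 0.05. The enrichment universe defaults to all genes in the
target database. A full conjunctive ontology-rule search is out of scope;
flat rules preserve the rule → cluster → review workflow shape. Retained
rules are Ward-clustered on binary membership vectors over the union of
overlap genes (Euclidean distance); the cut is configurable as an absolute
height or a cluster count (default k = 6). A fixed published cut height is
treated as data-dependent, not a constant. Hub reports list genes by distinct
contributing miRNAs and miRNAs targeting ≥ 10 genes in the analyzed universe.

## Synthetic data generator

The generator emulates the study design, not any particular dataset. Per
endogenous probe: log₂ baseline ~ N(9.5, 1.2²) for "expressed" probes (273
human + 11 viral = 284, matching the analyzed count) and N(0.5, 0.5²) —
essentially below background — otherwise. Per subject and probe a
N(0, σ_inter²) effect; per sample and probe a N(0, σ_intra²) replicate
effect; GP samples add the planted log₂FC spikes. Linear means are scaled by
a per-sample LogNormal(0, 0.2) library factor; counts are negative binomial
with var = μ + αμ². Negative controls are Poisson(10) independent of the
library factor; positive controls follow a fixed geometric ladder times the
library factor.

Noise defaults: σ_inter = 0.08, σ_intra = 0.20 (log₂), α = 0.003. These
encode three a-priori features of the emulated setting: day-to-day
(within-person) variability of circulating miRNAs exceeds between-person
variability in this design's own headline observation, detected probes sit at
high counts where the digital assay's technical CV is small, and the
candidate-recovery acceptance bar (≥17 of 19 spikes, three of which sit at
|log₂FC| ≈ 1.0, the candidate boundary) is only attainable at all when the
standard error of a 16-vs-16 log₂FC estimate is ≲ 0.07 — the defaults place
it near 0.06. A probe planted at exactly ±1.00 is recovered in only half the
runs whatever the noise, which bounds attainable run-level recovery.

Survival: GP times are exponential with log-hazard log(h₀) + Σⱼ βⱼ·z(xⱼ),
h₀ = 1/14 per month (median ≈ 10 months at baseline), βⱼ = 1.2 per z-score;
censoring is independent exponential calibrated to a 10% rate (GBM mortality
is near-complete within a study window). Planted prognostic probes load a
shared per-subject latent factor (log₂-sd 0.5): a set of co-detected
prognostic miRNAs behaves as correlated readouts of one underlying axis
(tumor burden), not as independent hazard contributions — with three
*independent* 1.2·z effects each probe's marginal association is diluted by
the other two acting as frailty, capping per-probe scan recovery near 65%
even with noise-free expression.

What the generator does **not** model: cartridge batch effects, probe
cross-hybridization, hemolysis signatures, non-proportional hazards, and any
real covariance structure of the plasma miRNome beyond the planted factor.
Passing recovery tests therefore demonstrates correctness of the pipeline's
inference under its own assumptions, not performance on real plasma data.

## Problem sizes

The test suite and acceptance script use: 200 seeded runs of the full
16-vs-16, 284-expressed-probe design for candidate recovery and log₂FC bias;
100 runs for the prognostic scan (scanned at the planted probes — the screen
is per-probe independent, so this measures exactly the per-probe recovery
rate); 100 null runs for the BH false-positive rate; 500 null runs for the
scan-inflation measurement; and reduced panels (30–50 probes, 4–8 subjects)
for property tests. Unit oracles use ≤ 6 observations where hand arithmetic
is checkable.

## Known limitations

- The headline counts of the original screen on real samples (284 analyzed,
  102 differentially expressed) are not recomputable without the undeposited
  raw data; the 284 figure is reproduced by construction of the generator,
  not by inference.
- The uncorrected cutoff scan is reported because it mirrors screening
  practice; its BH column should be preferred for any decision.
- ReliefF weights depend on k and on the distance metric; ranks are stable
  for well-separated classes but not guaranteed stable near ties (ties break
  deterministically by probe id).
- The paired t operation is provided but exercised only synthetically; the
  original pre/post-surgery pairing is not recoverable.
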