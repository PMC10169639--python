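# Methods

## Scales and transforms

Methylation is carried as beta values β ∈ [0, 1] (fraction of methylated
signal per CpG). Hypothesis tests run on m-values, m = log2(β/(1−β)),
which are approximately homoscedastic across the beta range; effect
sizes and call thresholds stay on the beta scale, where a difference is
directly a change in methylated fraction. Before the logit, β is clamped
into [ε, 1−ε] with ε = 0.001: normalized array betas essentially never
reach 0/1, so the clamp only guards synthetic or rounded inputs, capping
|m| near 9.97 while perturbing interior values by nothing (the inverse
transform round-trips to < 1e−12 for β ∈ (ε, 1−ε), which the tests
assert).

Coordinates are 1-based base pairs. Nearest-gene assignment minimises
the absolute distance to a transcription start site on the same
chromosome, ignoring strand; the reported distance is signed (CpG
position minus TSS). Equidistant ties, including co-located TSSs, break
to the lexicographically smallest gene id — deterministic and
order-independent. CpGs on chrX/chrY and CpGs overlapping known SNPs
are removed before any analysis; the filter is idempotent and refuses
unannotated CpGs rather than guessing.

## Paired moderated test

Each contrast (e.g. day 8 vs day 0 of cycle 1 in blasts) is a matched
serial design: every patient contributes one later/earlier sample pair.
We therefore test per-patient differences with a one-sample moderated
t. Per feature g, with n patients and d = n − 1 residual df, the sample
variance s²_g of the differences is shrunk toward a prior:

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),
    t̃_g  = mean_diff_g / (s̃_g/√n),   df = d + d₀.

The hyperparameters (d₀, s₀²) come from method-of-moments on the log
sample variances: with e_g = log s²_g − ψ(d/2) + log(d/2), the excess of
var(e) over ψ′(d/2) identifies ψ′(d₀/2), inverted by a Newton iteration
(trigamma is monotone and convex, so the iteration from x₀ = 0.5 + 1/y
converges; tolerance 1e−10). If the excess dispersion is non-positive
the prior df goes to infinity — fully pooled variance, normal reference
— with a logged warning. Zero sample variances are excluded from the
moment fit (they carry no scale information); a feature with zero
variance still gets a finite statistic through the pooled prior, and a
feature with zero mean and zero posterior variance reports p = 1.
Forcing d₀ = 0 recovers the ordinary paired t exactly (asserted to
1e−10), which is the reduction the tests and the suite's calibration
checks rely on. An all-zero-variance input (every difference identical
in every feature) is an error: there is no variance to pool.

Significance calls combine BH-adjusted p-values (step-up, via
statsmodels) with a beta-scale effect threshold: demethylated means
adj-p < α and Δβ < −δ; remethylated is the mirrored +δ rule. Both
inequalities are strict, matching "below 0.05" / "above 0.1" phrasing;
α = 0.05 and δ = 0.1 are defaults, exposed as parameters. (Array
literature also uses a much looser |Δβ| > 0.01 convention in some
figure-level summaries; we standardise on 0.1 and let the caller lower
it.)

Single-sample (per-patient) calls use the raw per-patient Δβ against the
same δ — one pair yields no variance estimate, so no per-patient p-value
is attached. Patients missing a timepoint are omitted and reported, not
imputed.

Per-patient demethylated-CpG counts are binned into strong
(> 100,000), limited (< 25,000) and intermediate response categories;
the boundaries refer to full 450K scale (~456k CpGs) and are scaled
proportionally when the universe is smaller (the pipeline scales them to
the simulated universe and echoes both into the kinetics table header).
Boundaries are strict, so a count exactly at a boundary is intermediate.

## Resampling null for common demethylation

The question "is the set of CpGs demethylated in all patients larger
than chance?" is answered against a null that preserves each patient's
call burden: per iteration, draw for each patient a uniform random
subset of the universe, without replacement, matched to that patient's
observed demethylated-set size; record the across-patient intersection
size. This is the minimal null that keeps per-patient burden while
destroying positional structure. A design alternative — one random set
per iteration shared by all patients — would conflate burden with
concordance and is not the default.

With realistic set sizes the observed common count can sit far beyond
anything 1000 iterations can witness, so the tail probability is
parametric: p = 1 − Φ((obs − mean)/sd) on the null counts. When the
null is degenerate (sd = 0, typical when per-patient burdens are small
relative to the universe so every null intersection is empty), p is 0
if the observation exceeds the null mean and 1 otherwise, and the
result carries a `degenerate` flag; summaries print it. The same
machinery tests the day-15 remethylated sets and the T-cell contrast.

The common set itself is the CpGs present in at least `min_fraction`
(default 1.0 = all) of per-patient sets, intersected with the
group-wise significant set, so a CpG must clear both the per-patient
and the moderated group-level bar.

## Remethylation

Day-15 rebound is quantified per patient: the fraction of that
patient's day-8 demethylated CpGs whose single-sample Δβ(d15 − d8)
exceeds a partial-remethylation threshold, averaged over patients. The
threshold default is 0.075 — the midpoint between the measurement-noise
floor on a beta difference (sd ≈ 0.03 at the default noise level) and
the smallest planted restore amount (30% of a 0.25 deficit) — so the
estimator is approximately unbiased for a per-patient rebound
probability; it is exposed as `partial_delta`. A group-level variant
(moderated + direction call on d15 vs d8, intersected with the group
day-8 set) is also reported, but under patient-independent rebound it
detects *any* patient rebounding and therefore does not estimate the
per-patient rate; the per-patient fraction is the headline number.

## Expression integration

Probe-level expression collapses to one row per gene by keeping the
probe with the largest across-sample IQR (ties to the smallest probe
id). Differential expression reuses the moderated paired test on log2
intensities. Per gene, promoter beta is the unweighted mean over CpGs
annotated TSS1500/TSS200/5′UTR and gene-body beta over
1stExon/ExonBnd/Body/3′UTR; a CpG carrying categories from both groups
contributes to both. Genes with no CpGs in a region are absent (NaN),
never 0, and are excluded from that region's screen.

The anti-correlation screen is patient-level: for each gene and region,
x = per-patient RNA log2 fold change, y = per-patient region Δβ;
ρ = Spearman with average ranks; the p-value is the one-sided lower
tail of the Fisher z normal approximation, z = atanh(ρ)·√(n−3), with ρ
clamped to ±(1 − 1e−12) so perfect correlations give finite, extreme z.
A gene is called anti-correlated only when p < α *and* ρ < 0; a
two-sided option exists. Fewer than 5 patients is refused (the normal
approximation is meaningless there); zero-variance vectors are flagged
`undefined`, never called. Promoter and body screens run and report
separately; "called genes" is the union with region labels retained. No
multiplicity correction is applied to the screen by design — the call
gate is the raw p < 0.05 with a direction requirement — so the expected
false-call rate among null genes is the per-region test level (~5%),
which the calibration tests bound; callers wanting FDR control can
apply `bh_adjust` to the reported p column.

## Context enrichment

A CpG set vs universe is tested per category (8 region categories, 4
island-context levels, repeat overlap) with a two-sided Fisher exact
test on the (in set) × (in category) table; BH across the ~13
categories. Multi-category CpGs count once per category — marginal
tests, not a partition chi-square — matching how array-context barplots
are built. Empty sets return p = 1 everywhere; the sample odds ratio
uses inf/nan sentinels for empty margins.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
at desk scale, with a ground-truth record for every planted effect.

Defaults (the package's study conditions):

| parameter | default | meaning |
|---|---|---|
| n_cpgs / n_genes | 20,000 / 2,000 | scaled-down 450K universe |
| n_patients_blast / tcell / cycle2 | 12 / 8 / 6 | serial blast cohort; T-cell and cycle-2 subsets |
| hyper_fraction, baseline_modes | 0.8, (0.9, 0.1) | bimodal baseline; heavy mode dominates so the cohort median sits near 0.9 |
| baseline_concentration | 50 | beta-distributed spread around each mode |
| signature_size / signature_effect | 100 / −0.3 | CpGs demethylated in every blast patient, both cycles |
| per_patient_background_rate | U(0.02, 0.35) | patient-specific demethylation rate — the wide range reproduces striking inter-patient variability |
| background_effect | −0.25 | beta shift of background-demethylated CpGs |
| background_selection | baseline_weighted | heavily methylated CpGs preferentially hit (weight ∝ baseline β); "uniform" available |
| remethylation_fraction | 0.5 | per-patient fraction of day-8 demethylated CpGs rebounding at day 15 |
| partial_restore_range | U(0.3, 1.0) | restored fraction of each rebounding CpG's deficit ("at least partial" reversal) |
| tcell_effect_rate | 0.005 | per-patient random T-cell demethylation, no common structure (scaled up from the roughly thousand-fold-lower in-vivo rate so desk-scale per-patient sets are non-empty) |
| n_anticorr_genes / anticorr_slope | 50 / −4 | genes whose expression log2FC = slope × promoter Δβ + noise |
| anticorr_delta_range | U(−0.25, 0) | per-patient promoter shift of planted genes; the range creates the patient-level variance a rank correlation needs while keeping chance all-patient demethylation of these promoters negligible |
| expression_noise_sd | 0.3 | log2 units on the planted fold change |
| measurement_noise_concentration | 600 | beta read noise; sd ≈ 0.02 at mid-beta, ≈ 0.012 at β = 0.9, matching 450K technical-replicate dispersion |

Observation noise re-draws each value from a beta distribution centred
on the latent mean — values stay in [0, 1] with no clipping artefacts
and the noise is mean-preserving, so planted effects are unbiased.
Signature CpGs are drawn from retained, heavily methylated CpGs with a
3× selection weight for open-sea/repeat context (so context enrichment
has signal to find). One pseudo-random stream per logical component
(annotation, baseline, effects, rebound, cycle 2, T cells, expression,
noise) derives from the master seed; tests can perturb one component
and assert the others byte-identical. Same config + seed gives
bit-identical output.

What the generator deliberately does **not** emulate — and hence what
passing tests do not show about real data: probe chemistry and
type-I/type-II effects, batch structure, cell-type composition drift,
genotype effects, clonal evolution, correlated *background*
demethylation across patients (background sets are independent per
patient, so the group-wise demethylated count is far smaller relative
to the universe than in real serial cohorts, where inter-patient
correlation inflates it), distinct T-cell baseline methylomes (T cells
reuse the blast baseline), and any real responder signal (response
labels are independent of methylation, so the 80/20 screen should find
only chance hits; at 12 patients a few dozen chance passes are
expected, and the screen's unit tests pin the rule on exact patterns
instead).

Calibration-style checks (no-signature null, remethylation-null
replicates) run the generator with `background_selection="uniform"`:
the resampling null assumes per-patient sets are uniform draws, and the
baseline-weighted default deliberately violates that exchangeability as
a biological feature. With weighting on, shared selection propensity
inflates observed intersections slightly relative to the uniform null —
which is exactly the point of modelling it, but it is not a calibration
condition.

## Problem sizes in the test suite

The suite exercises: oracle equivalence on all 2×2 tables with margins
≤ 12, all permutations of ≤ 8 p-values, and 1000 tied rank-correlation
vectors; moderated-test reduction on 500 features and calibration on
2,000; null calibration on 20 four-patient cohorts of 4,000 CpGs;
planted-signature detection on the default 20,000-CpG, 12-patient
cohort; remethylation on the default cohort plus 20 ten-patient
replicates; the anti-correlation screen on 10 replicates of a
23-patient, 2,000-gene cohort; and full-pipeline determinism at default
scale. These sizes were chosen so each property is measured with
comfortable statistical margin while a full run stays interactive on a
laptop.

## Known limitations

* The parametric upper-tail normal p extrapolates far beyond the 1000
  resampled counts; it is the standard device for this test but its
  extreme tail values are model-based, not empirical.
* The Fisher-z normal approximation for Spearman ρ is an approximation;
  at n near the minimum (5) its p-values are rough, which is why the
  direction requirement is part of the call.
* The moderated test assumes exchangeable per-feature variances around
  one scaled-F hierarchy; gross variance heterogeneity structure
  (e.g. probe-type strata) is not modelled.
* Group-wise counts at desk scale are not comparable to full-array
  counts: with 20,000 CpGs and per-patient-independent background, the
  group-level demethylated set is dominated by the planted signature.
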