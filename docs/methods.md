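# Methods

`mirserum` implements a dual-branch differential-expression workflow for
serum miRNA qPCR panels measured on pooled biological replicates, together
with the downstream enrichment and biomarker-validation arms. This note
documents the statistical model, the tunable parameters, the synthetic data
the tests run on, and the design choices made where the method description
left room.

## Data model

The substrate is a feature × sample matrix of cycle-threshold (Ct) values.
Ct is a log2-scale abundance readout (one cycle fewer ≈ twice the
template). Each feature carries a role — `target`, `reference` (delta-Ct
scaling anchors), `ipc` (inter-plate calibrator spike), `other_control` —
and a panel (`I`/`II`, the two physical assay plates of a ~750-assay human
panel). A well that never crosses threshold is **right-censored** at the
40-cycle instrument ceiling and stored as exactly 40.0 with a flag, never
as missing; blank cells in input files follow the same convention. This
keeps the expression filter well-defined: a target enters the analysis only
if *every* observation is strictly below the ceiling.

## Inter-plate calibration and QC

Each plate's IPC spike should read identically everywhere. The QC statistic
is the sample SD of plate-level IPC means, computed jointly across all
plates of the run; the gate is strict (`SD < 0.05` cycles). Calibration is
additive: CF(plate) = global IPC mean − plate IPC mean, added to every well
of the plate, which equalizes plate IPC means exactly, preserves
within-plate contrasts to machine precision, and leaves censored wells
censored. Calibrating past a failed gate requires an explicit, loudly
logged override. A well pushed to the ceiling by calibration is re-censored
rather than reported above 40.

## Delta-Ct normalization

dCt(f, s) = Ct(f, s) − mean over references of Ct(r, s). The default
reference set is the three serum-stable miRNAs miR-103a-3p, miR-423-5p and
miR-191-5p; the classic small-RNA references (SNORD38B, SNORD49A, U6) are
accepted as candidates but are typically absent in serum and excluded from
the default. Reference stability is ranked by cross-sample SD of calibrated
Ct — deliberately the minimal criterion; pairwise-variation algorithms
(geNorm/NormFinder style) are out of scope, and the default set is fixed so
the pipeline's configuration does not depend on the score. delta-Ct is
invariant under per-sample additive shifts (loading/efficiency effects),
which is property-tested. The left ("ipc_delta_ct") branch calibrates
first, then normalizes; the right ("raw") branch feeds uncalibrated Ct
directly to the model.

## Moderated t

With two pooled replicates per group, per-feature variance estimates have
2 residual df; the two-group statistic therefore shrinks each pooled
variance s² toward a prior s₀² shared across features:

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d),    t = Δ / sqrt(s̃²·(1/n₁ + 1/n₂)),

with Δ = mean(case) − mean(control) and p from a t distribution with d + d₀
df. The hyperparameters (d₀, s₀²) are estimated by method of moments on
log s²: under the working model s² ~ s₀²·F(d, d₀), log s² has closed-form
mean/variance in digamma/trigamma terms, and d₀ follows from a Newton
inversion of the trigamma function. When the observed spread of log s² is
at or below its sampling floor the estimator returns d₀ = ∞ (complete
shrinkage, s̃² = s₀²; the finite-d₀ identity above applies whenever d₀ is
finite). d₀ = 0 recovers the ordinary pooled t exactly. Zero-variance
features are excluded from the moment equations and handled through the
shrunk variance, so no division by zero occurs while d₀·s₀² > 0. The whole
kernel is vectorized over leading batch axes so permutation replicates are
one array program; an independent scalar-loop reimplementation (bisection
instead of Newton) serves as the test oracle at 1e-6.

Fold change is FC = 2^(−Δ): positive Δ (more cycles in cases) means
down-regulation, FC < 1.

## Permutation "sampling p"

The sampling p is a resampling control on the model p-value. Per replicate,
values are permuted **across features independently within each sample
column of a group** — feature identity is broken while per-sample loading
effects are preserved — and the full moderated-t analysis (including
hyperparameter re-estimation) is rerun. All B·F null p-values are pooled;
sampling p(f) = fraction of the pool ≤ the observed model p(f). Pooling
across features is what gives resolution below 1/B at small B and makes
p-values like 6·10⁻⁴ attainable with two replicates per group. The
published wording admits more than one permutation unit; per-column
permutation was chosen because it preserves sample-level structure and
makes exhaustive enumeration tractable for verification (6⁴ = 1296
combinations on a 3-feature, 2+2 fixture, tested against the Monte-Carlo
estimate at 3·SE). The plain fraction is reported by default (0 is
possible); a smoothing flag switches to the (b+1)/(B+1)-style estimate.
B defaults to 10 000 and a seed is mandatory — an unseeded call is a hard
error. Sampling p is non-decreasing in model p by construction, and on
null simulations its type-I error at α = 0.05 sits inside the binomial
99% band (tested at 200 features × 20 replicates, B = 1000).

Candidates are features with sampling p < α (default 0.05), ordered by
sampling p with model-p and name tie-breaks; direction is `up` iff FC > 1.
Branch intersection (raw ∩ delta-Ct) and group intersection (mild ∩ severe)
match on name **and** direction; direction conflicts are dropped and logged.

## Enrichment

Candidate miRNAs map to validated gene targets (set union, deduplicated);
terms are scored by the upper-tail hypergeometric p over a declared
background of size N, with fold enrichment FE = (k/n)/(K/N) and
Benjamini–Hochberg FDR across the term family. N is a required field of
the term map, not a constant, because the "whole transcriptome" background
is a property of the annotation release. The `ease` variant discounts one
hit (k−1), the conservative DAVID-style convention. Live database queries
are out of scope; mapping and term tables are packaged fixtures or user
files.

## Validation arm

Per-patient delta-Ct values are compared by the classical pooled-variance
Student t (Welch by flag), and diagnostic performance by the ROC curve with
the rank/Mann–Whitney AUC (half-credit ties). The positive-class convention
(`lower_is_positive` for a Ct-scale marker that is up-regulated in cases)
is explicit and logged; `auto` picks the orientation with AUC ≥ 0.5. The
sweep's trapezoid area equals the rank AUC exactly, including ties.

## Synthetic data

`simulate_experiment` draws Ct(f, s) = baseline(f) + plate effect + group
spike + N(0, σ). Defaults (the package's study conditions): 372 + 367
targets on panels I/II, 4 groups × 2 pools, per-feature baselines
~ U(22, 38), σ_e = 0.25 (replicate noise of pooled sera), σ_ref = 0.08
(references are an order of magnitude stabler than targets), IPC true value
20.0 with σ_ipc = 0.01, and σ_plate = 0.02 — a run that passes the 0.05
IPC gate, as a vendor-QC'd experiment would; failed-QC behavior is
exercised with explicitly larger plate effects. Spikes are additive
Ct-scale group effects; the magnitudes used in tests (|Δ| ≈ 1.9–5.3)
bracket the effect sizes a serum screen of this design reports. Censoring
(not truncation) is applied at 40.

The generator reproduces the statistical structure the analysis assumes —
Gaussian Ct noise, additive plate effects, exchangeable features under the
null. It does **not** model amplification-efficiency differences,
hemolysis, variance heterogeneity between groups, or the correlated
dropout ("on/off") patterns of weakly expressed serum miRNAs. Passing
tests therefore certify the inferential machinery under its own
assumptions, not robustness of those assumptions on instrument data.

## Problem sizes and determinism

Test and acceptance runs use B = 1000–10 000 permutations, 80–372-feature
panels and 20–100 replicate simulations — sizes chosen so the full suite
and the acceptance script each complete in well under a minute on one CPU
while keeping Monte-Carlo error far from the asserted margins. Every
stochastic step takes an explicit seed; per-task seeds in the pipeline are
derived deterministically from the run seed and the (branch, comparison)
labels, so outputs are byte-identical across runs and independent of
execution order.

## Known limitations

- With 2 pools per group the permutation null pools across features;
  features with genuinely heavier-tailed noise borrow significance from
  quieter ones.
- The moments estimator of (d₀, s₀²) is re-fit per permutation, which is
  conservative in feature count but correct for the pooled-null definition.
- The calibration formula is the standard additive spike-in convention;
  vendor software may center plates differently (the difference is a
  run-level constant that cancels in dCt and in group contrasts).
- The accession-data checks (173 filtered targets; candidate counts near
  15/29) require a network fetch of the deposited raw data and are skipped
  when it is absent; `scripts/fetch_gse110797.py` documents the path.
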