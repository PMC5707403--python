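# Methods

`arrestomix` implements the chemometric workflow used to compare the plasma
metabolomes of two cardiac-arrest etiologies — asphyxial (ACA) and
ventricular-fibrillation (VFCA) arrest — in a longitudinal animal
experiment: binned ¹H NMR spectra and quantified metabolite panels are
modelled with latent-variable regression, validated by resampling, and
monitored per animal with control charts. Because no public dataset of this
design exists, the package ships a synthetic cohort generator with known
ground truth; every estimator is tested against that truth or against an
independent oracle.

## Synthetic cohort generator

The generator emulates a two-arm swine experiment: two groups of 10
animals, sampled once at baseline and then every minute through an
asphyxial pre-arrest period (ACA only, 4–10 min), 5 min of untreated
arrest, 2–10 min of CPR, and a post-ROSC follow-up at 1–4 h and 24 h.

Concentrations follow

    y_it = b_i · g(phase, t; class) · exp(ε),   ε ~ N(0, σ_f²)

with animal baseline `b_i` lognormal around the metabolite's baseline mean
(CV default 0.15) plus an optional additive intercept, and `g` a
piecewise **log-linear** trajectory: constant at baseline, rising at a
class-specific per-minute rate during asphyxia/CA/CPR, and decaying
exponentially toward baseline after ROSC (time constant τ = 60 min, so
most disturbances normalise within the first hour). `g` is capped at a
class-specific maximum fold change. Multiplicative lognormal noise
(default σ_f = 0.08) keeps concentrations positive with CVs roughly
proportional to the mean.

Key shipped conditions:

| condition | value | reason |
|---|---|---|
| animals per group | 10 | study design |
| damaged fraction of ACA | 0.4 | 4 of 10 ACA animals had the poor outcome |
| succinate cap, damaged | 40-fold | observed overproduction ceiling |
| succinate cap, no-damaged | 3-fold | observed mild increase |
| damaged asphyxia duration | 7–10 min | damaged animals arrested only after > 7 min |
| CPR slopes (VFCA) | log(1+FC̄)/6 per min | calibrated so the expected end/begin change over a mean 6-min CPR matches the reported per-metabolite mean fold changes (e.g. succinate FC̄ = 5.39) |

Damage class is assigned deterministically (seeded shuffle, exact
fraction), so the damaged count is not binomial. Baseline concentrations
for the shipped panel are order-of-magnitude plasma values (lactate
1.5 mmol/L, succinate 10 µmol/L, ...) — synthetic conventions, since no
absolute baselines are published for this design.

Spectra are rendered as concentration-weighted sums of Lorentzian lines
(half-width 0.004 ppm) at common literature chemical shifts (lactate
doublet ≈ 1.33 ppm, succinate singlet ≈ 2.41 ppm, ...), plus an optional
smooth broad baseline and additive Gaussian noise, clipped at zero. With
zero noise the integrated spectrum is exactly linear in concentration,
which the tests exploit.

What the generator does **not** emulate: peak shift/misalignment between
samples, baseline roll and phasing artefacts, J-coupling multiplet
structure, overlapping macromolecule background, hemodynamics, or
survival processes (damage class is an input label, not an outcome).
Passing tests therefore certify the statistical machinery, not robustness
to raw-spectrum artefacts, which the workflow assumes were handled during
acquisition.

## Preprocessing

Raw traces are integrated (trapezoid rule, so results are grid-step
invariant for smooth spectra) over half-open fixed-width bins [lo, hi),
default 0.01 ppm across 0.80–9.00 ppm. Bins overlapping an exclusion
interval (default water region 4.66–5.18 ppm) are dropped conservatively,
including straddlers; this leaves 768 of 820 bins. Further config-driven
region removal (e.g. drug signals) is available; the exact regions are a
study-specific choice. Rows are then normalised to a constant sum of 100
and columns mean-centered and Pareto-scaled ((x−mean)/√sd, sample sd with
n−1). Zero-variance columns are centered only and flagged. Inside
cross-validation all scaling parameters are re-estimated on each training
fold — leakage-free, which matters with n in the tens.

## Latent models

**NIPALS PCA** with a tightened stop (relative score change < 1e-14, up
to 20 000 iterations): power iteration stalls when leading eigenvalues
are close and the per-step change then underestimates the remaining
error, so PCA gets a much larger budget than PLS. Sign convention: first
nonzero loading element positive.

**NIPALS PLS2** regresses a design matrix Y (a ±1 class contrast and,
optionally, centered time) on X. X is deflated per component, Y is not;
B = W(PᵀW)⁻¹Qᵀ so Ŷ = XB. R²Y = 1 − SS_res/SS_tot on training Y.

**Post-transformation (ptPLS2).** The fitted A-dimensional score space is
rotated by G, the left singular vectors of TᵀY: columns with singular
value above 1e-8 of the largest span the predictive subspace (scores tp),
the rest the orthogonal one (to1, to2, ...). Because the scores are
orthogonal and Ŷ = T·diag(1/tᵀt)·TᵀY, the orthogonal scores satisfy
ToᵀY = 0 and hence have exactly zero correlation with every fitted
response column, while predictions are untouched — the module's defining
contract, enforced at 1e-8 in the acceptance suite. `n_predictive` may be
forced by the user (e.g. to drop a response direction judged
non-significant). The construction pins the published invariants
(equivalent predictions, predictive/orthogonal split); other published
rotations satisfying the same invariants would differ at most by a
rotation within each subspace.

**VIP**: VIP_j = √(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with
SSY_a = (t_aᵀt_a)(q_aᵀq_a); mean(VIP²) = 1 identically.

## Validation layer

- **Q²** by n-fold full cross-validation (default 7), reported
  cumulatively per component; folds are deterministic interleaved
  ("venetian blind", sample i → fold i mod n) or grouped by animal so
  repeated measures never straddle folds. Grouped folds are the honest
  choice for repeated measures and are used by the BSPC model; interleaved
  is the package default because it is reproducible without ids.
- **Component count**: add a component only while Q² improves by more
  than 0.01; floor A = 1 with a warning when even Q²(1) ≤ 0.
- **Permutation test**: Y rows permuted jointly (X untouched),
  p = (1 + #{null ≥ observed})/(1 + n_perm) — the add-one form, so the
  smallest attainable p is 1/(n_perm+1) and null p-values are
  super-uniform. With animal ids, whole response blocks are exchanged
  instead (requires equal per-animal counts); sample-level permutation is
  the default.
- **VIP selection**: thresholds {0.8, 0.9, 1.0, 1.1, 1.2} swept against
  the full-model VIP, each surviving subset refit and re-cross-validated;
  the full set is always a candidate, so the returned subset's Q² never
  falls below the full model's.
- **Stability selection**: 50 Monte-Carlo subsets, each sample included
  with probability 0.70; a variable scores in a subset when its VIP
  exceeds 1.0; the stable set collects variables selected in ≥ 80% of
  subsets (threshold configurable; degenerate subsets are redrawn, at
  most 10 times).

## BSPC

Animals traverse the asphyxial phase at different speeds, so each
animal's minutes are expanded linearly onto a common 10-minute scale
(m ↦ m·10/d; d = 10 is the identity). A PLS model fitted **only on
reference (no-damaged) animals** predicts expanded time from the spectral
profile; each reference animal's predicted-time trajectory is
interpolated onto a 0.5-min grid and the pointwise across-animal mean ±
k·sd (sample sd, k = 2 by default) give the control limits. Grid points
covered by fewer than two reference animals are dropped. The sd curves
are deliberately unsmoothed: the reference n is small and smoothing would
mask the degenerate collapse (identical references ⇒ zero-width limits)
that the tests check. All animals — reference and test — are projected;
a point is out of control outside the limits, and an animal is flagged
when at least 20% of its grid points are out (the per-point flags, the
fraction, and the first excursion time are all reported, so other rules
are easy to apply). The charted statistic is predicted time ("maturity")
versus expanded time, the classic chart for a PLS-on-time model;
score-space charts can be built from the same fitted model.

## Univariate layer

Mixed-effects models y = β₀ + β₁t + β₂·group (+ β₃·t·group) + b_i + ε
with a random intercept per animal, fitted by REML (statsmodels MixedLM);
Wald p-values use the normal approximation, and the reported R² is the
squared correlation of fitted vs observed (labelled as such — it is not a
marginal/conditional decomposition). Group coding (reference level = first
in sort order) is recorded in every fit.

The paired test is the Wilcoxon signed-rank test (zero differences
dropped, ties mid-ranked; exact enumeration for n ≤ 25 without ties,
else normal approximation with continuity correction); the unpaired test
is the Mann-Whitney U (exact for n ≤ 20 without ties, else tie-corrected
normal approximation). Both are delegated to scipy and verified against
full enumeration oracles in the tests. Fold change is the relative
increase (x_to − x_from)/x_from per animal — the only definition
consistent with the reported CPR succinate summary — summarised as
mean/min/max across animals; animals with non-positive baseline are
excluded with a warning. q-values are Benjamini-Hochberg step-up,
q_(i) = min_{j≥i}(p_(j)·m/j) clipped at 1.

## Numerical conventions

- NIPALS: PLS stop at relative score change < 1e-10 (≤ 10 000
  iterations); breakdown (zero weight) and non-convergence raise with the
  component index.
- Predictive-subspace rank tolerance: 1e-8 × largest singular value.
- Bin intervals half-open, last closed; constant width enforced at 1e-9.
- Sample (n−1) standard deviations everywhere.
- All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give byte-identical outputs, and fold assignment needs no seed at
  all.

## Problem sizes

The shipped analyses run on the default cohort: 20 animals, ~400 samples,
768 bins; permutation tests in the presets and the acceptance script use
199 permutations (p-floor 1/200) with the Q² statistic; the simulation
studies in the test suite use 50–200 replicates at n of 20–40 and p of
5–55. These sizes make the whole suite a desk-scale computation while
keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

- Exact rank tests switch to approximations in the presence of ties; with
  continuous synthetic data this path is exercised only by dedicated
  tests.
- The CPR begin-vs-end contrast has n = 2 per animal; with 10 animals its
  permutation p rarely reaches the floor — an honest small-sample
  property of the design, not a defect.
- Wald inference for mixed models uses the normal approximation; with
  very few animals, small-sample df corrections (not implemented) would
  be preferable.
- The ptPLS2 rotation is defined up to within-subspace rotations; score
  plots from other software may differ by such a rotation even though
  predictions and the predictive/orthogonal split agree.
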