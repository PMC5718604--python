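# Methods

## Problem and model

Amyloid-PET studies commonly quantify tracer uptake with the standardised
uptake value ratio (SUVR): the ratio of late-window activity in a cortical
target region to that in a reference region (cerebellar grey matter, CB, or
subcortical white matter, WM). SUVR is read out before the tracer reaches
equilibrium, so it inherits a dependence on cerebral blood flow: a change in
regional perfusion shifts the time course of tissue activity even when the
underlying amyloid load (binding) is unchanged. This package quantifies that
bias by simulation for the [18F]florbetapir-like kinetic regime.

Tissue kinetics follow the two-tissue compartment model with four rate
constants and a fractional blood volume (2TCM-4k-Vb):

    dC1/dt = K1 Cp(t) − (k2 + k3) C1 + k4 C2
    dC2/dt = k3 C1 − k4 C2
    C_tissue(t) = C1 + C2 + Vb · Cb(t)

with K1 (mL/min/mL) the plasma-to-tissue delivery rate (the flow surrogate),
k2 (1/min) the clearance back to plasma, k3/k4 (1/min) exchange with the
specifically bound compartment, Cp the metabolite-corrected plasma input and
Cb whole blood. Equivalently,

    C1 + C2 = Cp ⊗ K1 [θ1 e^(−α1 t) + θ2 e^(−α2 t)],

where α1,2 = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4 k2 k4)]/2,
θ1 = (k3+k4−α1)/(α2−α1), θ2 = 1−θ1. Macro-parameters: V_ND = K1/k2,
BP_ND = k3/k4, V_T = V_ND (1 + BP_ND).

A regional blood-flow change of ΔK1 % is modelled as a common scaling of K1
and k2 by (1 + ΔK1/100), which preserves V_ND, BP_ND and V_T exactly: only
the kinetic time scale changes, never the equilibrium. The SUVR bias is
ΔSUVR = 100 (SUVR_sim − SUVR_base)/SUVR_base, evaluated by default over the
50–60 min window on the default ΔK1 grid {±5, ±10, ±20, ±40}%. A
simultaneous equal change in target and reference ("global" change)
factorises exactly,

    ΔSUVR_global = 100 [(1 + ΔSUVR_target/100)(1 + ΔSUVR_ref/100) − 1],

because SUVR is a ratio of two independently scaled window means; the
package exploits this both as an implementation shortcut check and as a
machine-precision regression test.

## Numerical scheme

The plasma and whole-blood curves are treated as piecewise linear between
samples and zero before the first sample. Convolution with each exponential
mode is evaluated segment-exactly: a linear ramp against e^(−αt) has a
closed-form integral, accumulated recursively across segments. The only
error left in a simulated frame value is the frame-averaging quadrature
(composite Simpson on ≥20 subintervals per frame; PET frames report
time-averaged activity). Small α·Δt uses a truncated series for the
second-order kernel to avoid catastrophic cancellation, and α1 is recovered
from the eigenvalue product α1 α2 = k2 k4 rather than the subtractive
quadratic root, which keeps the irreversible limit k4 → 0 exact. The
repeated-eigenvalue point (k3 = 0, k2 = k4) degenerates to a single
exponential and is returned exactly.

An independent verification path (`tissue_response_ode`) integrates the
state equations with LSODA (rtol 1e−9) over the same interpolated input;
analytic and ODE routes agree to better than 0.1% of the curve scale across
the built-in regions and broad random parameter ranges. The residual
deviation is dominated by the ODE solver stepping across the input's
sampling kinks, not by the convolution.

Default frame schedule: 4×15 s, 8×30 s, 9×60 s, 2×180 s, 8×300 s (60 min
total), a typical dynamic amyloid protocol; only the 60-min duration is
constrained by the study design, so the schedule (and whether the time
course uses frame-wise or cumulative windows) is configurable. Units are
fixed: minutes, kBq/mL, rates 1/min; no radioactive-decay modelling.

## Synthetic inputs

Measured arterial data for this tracer are not publicly available, so the
input function is a declared synthetic surrogate: a Feng-type
tri-exponential bolus with linear rise for total plasma, a Hill-type parent
fraction 1/(1 + (t/T50)^h) for metabolite correction, and a constant
whole-blood/plasma ratio. The shipped parameter set
(`src/flowsuvr/data/default_aif.yaml`) was calibrated once against the
built-in average-HC kinetics and then frozen. Calibration targets, in
order of priority: (i) baseline SUVR^prec (ref CB) inside the plausible
amyloid-negative band 0.9–1.8 at 50–60 min; (ii) the qualitative sign
pattern of a −40% flow change (target SUVR up, CB-referenced SUVR down,
WM-referenced SUVR up); (iii) single-region −40% magnitudes within ±5
percentage points of +10.6 / −10.2 / +11.3 %; (iv) the WM SUV turnover — WM
late-window SUV rises with K1 up to roughly 0.4 mL/min/mL and falls beyond.
The shipped default achieves 1.77 for (i) and +8.5 / −10.8 / +10.1 % for
(iii), with the turnover between +40% and +80% K1 scaling.

Two caveats are intrinsic, not fixable by further tuning. First, the
built-in baseline rate constants are rounded to two decimals, which pins the
equilibrium volume ratios (e.g. precuneus BP_ND is exactly 1.0); under any
bolus-family input, matching the reference late-window SUVR levels of real
data for CB (≈1.34) and WM (≈0.55) simultaneously is then impossible — the
CB ratio pulls toward a sustained plasma tail and the WM ratio toward a
sharp bolus. The shipped input favours the flow-effect magnitudes and the
plausibility band over the absolute SUVR levels. Second, the constant
whole-blood/plasma ratio leaves the late whole-blood tail higher than
measured curves; this enters the tissue signal only through Vb ≈ 5% and
shifts baseline SUVRs by a few percent at most.

What passing tests therefore show about real data: the *structure* of the
flow bias (signs, approximate magnitudes, exact global factorisation, V_T
invariance, the inverse relation to binding) is reproduced; the *absolute*
SUVR levels and subject-level dispersions are not claims about any human
cohort.

## Cohorts

Per-subject regional parameters are drawn log-normally (positivity-
preserving, parameterised by arithmetic mean and CV; default CV 0.15 for
rates, 0.10 for Vb) around group means; per-subject input functions jitter
the bolus amplitudes (CV 0.10) with timing fixed. HC means are the built-in
averages. The aMCI/AD means are illustrative placeholders, clearly flagged
as such: target k3 ×1.5 / ×2 (amyloid-load surrogate) and delivery ×0.93 /
×0.85 with k2 co-scaled (V_ND preserved). The k3 scalings were chosen so the
disease target stays in the grey-matter regime, where a flow reduction still
raises the target SUV — raising k3 to ~3× the HC value tips the kinetics
into the white-matter-like trapping regime and flips the sign of the flow
effect, which is not the behaviour these groups are meant to emulate.
Sampling is bit-reproducible from a seed; group sizes default to 10/15/9.

TAC noise for fitting experiments is zero-mean Gaussian with per-frame SD
scale·√(value/duration) (count-statistics-like), clipped at zero; the
baseline study itself is noise-free by design.

## Fitting

`fit_2tcm` estimates (K1, k2, k3, k4, Vb) by bounded trust-region least
squares on frame-averaged residuals, frame-duration weighting by default
(uniform and inverse-variance selectable), 10 multi-starts log-uniform
within bounds (K1 ≤ 2, k2,k3,k4 ≤ 1, Vb ≤ 0.2; all rates > 0). Percent
standard errors come from the Jacobian-based covariance at the optimum.
Fits pinned at bounds are flagged, as are practically unidentifiable fits
where the two tissue eigenvalues collapse (relative gap < 1e−3). Noise-free
round trips recover all five parameters to machine-level accuracy for the
three built-in regions; at noise scale 0.05 the Monte-Carlo spread matches
the reported %SE to within a few tens of percent and K1 median bias stays
well under 1%.

## Statistics

The group comparison is a two-way fixed-effects ANOVA of ΔSUVR on
diagnostic group × ΔK1 (both categorical; ΔK1 has one level per grid point)
with interaction, followed by Tukey HSD on group. On per-subject sweep data
each subject contributes every ΔK1 level, so the independence assumption of
the fixed-effects model is violated and the resulting p-values are reported
as descriptive summaries, not calibrated inference — the cohort driver and
result sidecars say so explicitly. The type-I-error calibration experiment
instead draws an independent cohort for every (group, ΔK1) cell, which makes
the model assumptions hold by construction; under identical group
distributions the group main effect then rejects at 5–7% per 100 seeds
(nominal 5%; documented acceptance band 1–12/100). Residual deviation from
nominal is expected from heteroscedasticity across ΔK1 levels (the
between-subject spread of ΔSUVR grows with |ΔK1|).

The region scan correlates the target flow effect with V_T across four
synthetic targets whose V_T ∈ {3, 6, 9, 12} varies through binding (k3)
alone at common K1, k2, k4, Vb. The axis matters: varying V_T through
delivery (V_ND) instead *reverses* the correlation, because high-V_ND
regions equilibrate more slowly and are more flow-sensitive. With the
binding axis — the amyloid-load interpretation — the correlation is strongly
negative (r ≈ −1.0 at ΔK1 = −30%).

## Problem sizes

Defaults were chosen so the full test suite and every analysis driver run
comfortably on a single CPU: 8-point grids, 31-frame schedules, 50-replicate
recovery experiments, 100-seed calibration runs with 3 subjects per cell.
All are parameters, not constants.

## Known limitations

* The surrogate input is one fixed, declared curve family; flow-effect
  magnitudes shift by several percentage points across plausible input
  shapes (the sign pattern and factorisation do not).
* Rounded baseline rate constants pin the equilibrium ratios (see above).
* No image-domain effects: no partial volume, motion, scanner resolution or
  decay modelling; TACs are region-level and noise-free unless noise is
  requested.
* k3/k4 (amyloid change) and input-function changes co-varying with flow are
  out of scope; only K1/k2 co-scaling is simulated.
* The repeated-measures structure of per-subject sweeps is summarised, not
  modelled; a mixed-effects extension would be needed for calibrated
  subject-level inference.
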