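# Methods

This note documents the models implemented in `synthmpm`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
tests do and do not demonstrate about real data.

## Signal model and map estimation

**Ernst equation.** The ideally spoiled FLASH steady state is
S = PD·sin α·(1−E)/(1−cos α·E) with E = exp(−TR·R1). The default protocol is
a standard 3 T whole-brain MPM setting: TR/flip = 23.7 ms/6° for the PD- and
MT-weighted acquisitions, 18.7 ms/20° for the T1-weighted one; six
equidistant echoes 2.2–14.7 ms for every contrast and two extra PD-weighted
echoes at 17.2 and 19.7 ms; SE/STE transmit-field mapping at nominal angles
65–115° in 5° steps.

**Rational inversion.** R1 and PD\* are obtained from the echo-averaged PD-
and T1-weighted amplitudes with the dual-flip-angle rational approximation of
the Ernst equation, written in the effective flip angle ε = 2·tan(α/2):

    R1_app = ½ · (S_T1·ε_T1/TR_T1 − S_PD·ε_PD/TR_PD) / (S_PD/ε_PD − S_T1/ε_T1)

The half-angle-tangent form matters: with α used directly the inversion
deviates from exact numerical Ernst inversion by 0.6–1.6% over
T1 ∈ [0.5, 2.5] s at this protocol, while the ε form stays at ~0.01%
(`test_rational_inversion_matches_numerical_ernst_inversion`). Flip angles
are corrected voxel-wise by the measured transmit efficiency before
inversion.

**R2\*.** Ordinary (unweighted) least squares of ln S against TE on the
eight PD-weighted echoes; R2\* is the negated slope. Unweighted OLS on the
log signal is the simple, standard estimator; a noise-weighted variant is a
possible extension. Voxels with non-positive signal are flagged and
excluded; negative fitted rates are retained and flagged, never clamped, so
residual statistics stay unbiased.

**Echo averaging and PD\*.** The first six echoes of each contrast are
averaged for SNR. The averaged amplitude carries the common R2\* decay
factor of those echoes; since all three contrasts share the same echo times,
the factor cancels exactly in R1 and MTsat. For PD\* the averaged images are
divided by the mean decay factor computed from the fitted R2\*
(`decay_correction`, on by default), referring PD\* to TE = 0. PD\* remains
*effective*: no receive-field correction is attempted.

**Transmit field.** Per SE/STE pair, achieved flip = arccos(STE/SE); the
per-voxel efficiency is the least-squares slope through the origin of
achieved vs nominal angle over all valid pairs. Ratios beyond [−1, 1] by
more than 2% invalidate the pair (flagged, not clamped); within that band
they are clamped as noise.

**MT saturation.** MTsat is the semi-quantitative, protocol-referenced
fractional loss of steady-state longitudinal magnetization per TR caused by
the off-resonance pre-pulse, estimated as

    δ = (PD*·ε_c/S_MT − 1)·R1·TR_MT − ε_c²/2        (stored ×100, p.u.)

with ε_c the B1-corrected effective excitation angle. The spoiling-corrected
R1 enters this formula. A configurable empirical correction for residual
flip-angle dependence, δ_corr = δ·(1−C)/(1−C·f_T) with C = 0.4 by default,
is available (`correct_mtsat_b1`) and off by default in the pipeline because
the phantom's forward model has no residual flip-angle dependence to remove.

**Imperfect-spoiling correction.** RF spoiling (quadratic phase cycling,
50° increment by default) leaves a residual bias in the apparent T1 (−1.7%
at 20°/TR 18.7 ms for T1 = 1 s, T2 = 70 ms). The isochromat simulator
models one voxel as n isochromats uniformly dephased over 2π per TR (ideal
gradient spoiling), with rotation–relaxation–precession cycles and quadratic
RF phase; diffusion is omitted because the simulation's only purpose here is
the linear T1 correction, which the reduced model reproduces. Steady state
is declared when the per-pulse relative signal change stays below 1e-6 for
five consecutive pulses (cap 8000 pulses; non-convergence raises). Defaults:
200 isochromats (doubling changes the signal by <0.05%), a single
representative T2 of 70 ms. For each transmit efficiency on a 0.7–1.3 grid
(step 0.05), PD- and T1-weighted signals are simulated over a T1 grid of
0.5–3.0 s, inverted with the rational approximation, and
T1_true = A + B·T1_app is fitted by least squares; A and B are interpolated
linearly in efficiency at application time (nearest edge, with a warning,
outside the grid).

*Limitation:* the true-vs-apparent relationship has slight curvature, so the
linear correction leaves residual error that grows toward the short-T1 grid
edge and high efficiency — ~0.5% across tissue-range T1 (0.8–2.2 s) at
efficiencies 0.85–1.12, but ~2–3% at T1 ≈ 0.55 s with efficiency >1.2.
Brain-tissue T1 at 3 T is ≥0.8 s, which is the range the round-trip checks
use.

## Linear relaxometry model

The fit is plain OLS of R1 on [1, MTsat, R2\*] over a grey+white-matter mask
(phantom tissue labels in synthetic mode; user-supplied in real mode — no
segmentation is performed). No regularization, matching the model's original
formulation; rank deficiency (collinear MTsat/R2\*) raises rather than
returning a minimum-norm solution, because synthesis needs a unique triple.
Coefficients may also be supplied directly (`coefficient_source: values`)
for the population-derived mode; this is what the motion-correction
experiments use, since fitting β on data whose MT regressor is itself
corrupted would bias the fit. The residual map ε(r) is retained; the
measured-vs-synthetic comparison is also available as a percentage of the
pair mean (`residual_percent`).

Scenario logic is a fixed decision table: {MT} corrupted → synthesize MT
(optimal: the MT-weighted volume feeds only the MT map); {T1} → synthesize
R1; any set containing PD, or {T1, MT} → limited correction (every map is
affected); empty set → nothing to do.

## Digital phantom

The phantom emulates a head as concentric ellipsoidal shells (WM core, GM
shell, CSF rim) on a 32³ grid by default; the label field is
user-replaceable. Tissue values are plausible 3 T literature values, not
fitted to any dataset: WM R2\* 21 s⁻¹, MTsat 2 p.u., PD 700 a.u.; GM 15 s⁻¹,
1 p.u., 850; CSF 1 s⁻¹, 0.02 p.u., 1000. R1 is *constructed* from the
linear model with default β = (0.32, 0.22, 0.009) — giving WM R1 ≈ 0.95 s⁻¹,
GM ≈ 0.68 s⁻¹ — plus a Gaussian residual field of standard deviation
`residual_sigma` (default 0.01 s⁻¹, ~1% of WM R1), so the relaxometry fit
has an exact known ground truth; the derivation direction can be flipped to
construct MTsat from R1 instead. The transmit-efficiency field is a smooth
dome, default 1.08 − 0.30·ρ² with ρ the normalized distance from the grid
centre, spanning roughly 0.78–1.08 (set to unit efficiency for the
controlled recovery experiments).

**Forward model.** Each echo is the Ernst amplitude at the B1-scaled flip
angle times exp(−TE·R2\*). The MT-weighted stack is additionally attenuated
by g = k/(k + δ) with k = TR·R1 + ε²/2 — the multiplicative attenuation
implied by the same rational signal model that *defines* MTsat. This is a
deliberate design choice: MTsat is a protocol-referenced semi-quantitative
quantity, so generator and estimator share its definition, and end-to-end
recovery is limited only by the R1/PD\* chain (~0.002% noiseless) rather
than by a definitional mismatch. Simulating the pre-pulse physics (or an
exact per-TR saturation model, which the supplied estimator would recover
only to ~1.5–2.5%) is out of scope. Noise is complex Gaussian before the
magnitude operation (Rician; default σ = 1 a.u. against first-echo WM
signals of ~60 a.u., i.e. SNR ≈ 60), with a cheaper Gaussian-on-magnitude
option; SE/STE images get signed additive noise since STE is signed.

**Motion model.** Intra-scan motion is injected in k-space: the
phase-encode axis is split into 8 contiguous random segments, each receiving
a random translation (linear phase ramp, RMS = severity voxels) and constant
phase offset (RMS = 0.5·severity rad); the segment holding the k-space
centre stays clean, emulating the artefact-free shots of a partially
corrupted acquisition. Draws depend only on the plan seed, so error grows
monotonically with severity at fixed seed. Severity 1.0 — used by the
artefact-removal experiments — produces clearly visible ghosting (RMS map
error an order of magnitude above the noise floor); rigid-body trajectory
simulation is a non-goal. Severity calibration against "failed visual
inspection" of real scans is left to the user.

## What the phantom does and does not show

Passing the phantom tests shows that the estimation chain inverts its own
forward models correctly, that the linear-model machinery recovers known
coefficients, and that synthesis removes inconsistencies confined to one
weighted volume. The phantom does **not** emulate anatomy, receive-field
modulation, B0 off-resonance effects on the B1-mapping EPI data, flow,
partial-volume mixing at tissue boundaries, exchange-regime deviations from
the linear model, or real motion trajectories; real-data performance —
including the known GM/WM bias of synthetic maps — cannot be inferred from
these tests. All volumes are assumed co-registered (the phantom guarantees
it; registration of real data is the user's responsibility).

## Rating statistics

Forced-choice verdicts (k of n raters prefer the synthetic map) are tested
against chance 0.5 with an *exact* binomial tail — enumeration, not a normal
approximation — one-sided in the observed direction, α = 0.05. One-sided is
the deliberate choice: with five raters, a unanimous verdict has one-sided
p = 0.5⁵ = 0.03125 < 0.05 but two-sided p = 0.0625, and unanimous verdicts
are precisely the outcomes such a study calls significant. A split verdict
returns p = 1. The packaged study table (12 motion-affected datasets, 5
raters) yields: synthetic MT significantly preferred in participants 1, 3,
6, 9; synthetic R1 in 2 and 10; 50% of participants improved in exactly one
map; none in both.

## Numerical and interface choices

Internal units are SI (seconds, radians, s⁻¹) with MTsat in percent units —
stated once here to remove the ms/s ambiguity common in this area. Degenerate
voxels (zero R1-information denominator, non-positive MT signal, SE/STE
ratio out of domain) are flagged per-voxel in `aux["valid"]` and returned as
NaN, never silently filled. Maps travel as NIfTI-1 (RAS affine, 4-D echo
stacks) with BIDS-like JSON sidecars (`tr_s`, `fa_deg`, `te_s`, `contrast`,
`mt_pulse`); configuration is YAML; reports and coefficients are JSON. The
pipeline stages behind the CLI subcommands are the same functions
`run_pipeline` calls, so composed runs are bit-identical to `all`. Problem
sizes throughout (32³ phantom, 10-seed corruption experiments, 11-point T1
grids) are the package's default study conditions and run in seconds on a
laptop.
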