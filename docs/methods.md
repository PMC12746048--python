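# Methods

## The problem

In-vivo transit dosimetry flags treatment deliveries whose EPID transit
image disagrees with the predicted one. The comparison is a 2D gamma
analysis; the clinic must pick a gamma criterion and a passing-rate
tolerance. A criterion that is too strict floods the workflow with false
positives; one that is too lenient misses deliveries that change the target
dose by tens of percent. This package treats the choice as a classification
problem: simulate failure modes with known dosimetric impact, score each
with every candidate gamma metric, and use ROC analysis to find the
criterion and passing-rate cutoff that maximize sensitivity and specificity
for deviations above a chosen size.

## Gamma index

For reference dose Dᵣ and evaluated dose Dₑ on physically registered grids,

γ(r) = min over r′ of √( |r′ − r|²/δ² + (Dₑ(r′) − Dᵣ(r))²/ΔD² )

- δ is the distance-to-agreement tolerance (mm); ΔD the dose tolerance:
  `dose_diff_pct`·D_norm/100 with **global** normalization and
  `dose_diff_pct`·Dᵣ(r)/100 with **local**.
- D_norm is the **reference maximum** (commercial systems vary here; any
  report produced by this package states this convention).
- Reference points below `threshold_pct` (default 20%) of D_norm are
  excluded from the passing rate.
- A point **passes when γ ≤ pass_limit** (default 1.0). The ≤ convention
  matters only for exact-tie fixtures (uniform fields); it matches common
  clinical software and is configurable.
- The default metric set is the seven %/mm pairs (3/3, 5/3, 5/5, 7/5, 10/1,
  10/3, 10/5) × {global, local} = 14 metrics.

### Numerical search

The minimization samples the evaluated surface (bilinear interpolation in
physical coordinates) on a cartesian offset grid of step
min(pixel spacing, δ/10, 0.25 mm), restricted to the disc where the distance
term alone stays below a gamma ceiling of 2.0; values above the ceiling are
reported as the ceiling (they are far beyond any pass limit of interest).
The coarse pass is followed by a per-point refinement stage: four rounds of
a 5×5 stencil around the current best offset, halving the step each round.
The 0.25 mm cap and the refinement exist because the gamma objective is
nearly flat along iso-dose valleys: with a bare δ/10 step at δ = 5 mm the
coarse grid can land in the wrong basin along the valley, and greedy
refinement cannot recover. Every refinement sample updates **all** criteria
being evaluated in the same search group (the dose difference is
criterion-independent), so all criteria minimize over one common sample set
and exact per-offset orderings — notably γ_local ≥ γ_global per point —
carry over to the reported maps (`compute_gamma_many`,
`evaluate_criteria_set`).

`brute_force_gamma` is the validation oracle: an exhaustive scan of the
evaluated image bilinearly upsampled by a chosen factor, no truncation,
capped at the same ceiling. On random smooth fields the engine agrees with
the oracle within 0.02 per point and 0.5 percentage points in passing rate
(the oracle itself carries O(1/upsample²) discretization error; tests use
upsample 16–20). Fields with dose gradients far steeper than a blurred
clinical penumbra (≳15%/mm of the normalization dose) can exceed this
agreement at large δ.

Degenerate inputs: a zero reference maximum raises; a reference whose
included mask is empty raises "no evaluable points"; reference points whose
search disc partly leaves the evaluated extent are minimized over the
available region; points with no valid sample at all report the ceiling.
The gamma index is asymmetric in (reference, evaluated) and nothing in the
package assumes otherwise.

## Transit forward model

D(x, y) = k · MU · [A ⊛ G(σ)](x, y) · exp(−μ · t_eff(x, y))

- A is the fluence-weighted beam opening: the mean of the control-point
  apertures of a minimal plan model (MLC banks per 5 mm leaf row, jaws,
  collimator angle), rasterized with sub-pixel edge weighting — exact
  interval overlap at 0° and 8× supersampling when rotated.
- G(σ) is a Gaussian penumbra, σ = 3 mm by default.
- t_eff is the density-weighted water-equivalent thickness: a base
  thickness map modulated per named region by a column-average density
  multiplier (aerated lung ≈ 0.3, pleural fluid ≈ 0.95, tumor ≈ 1.05).
- μ = 0.005/mm water-equivalent (≈ 6 MV); k is calibrated per base plan so
  the **open-field** (jaws-only) transit image peaks at 100 dose units.
- Grid: 256×256 at 1.0 mm, plane-centered; the source–imager distance is
  metadata only (no magnification modeling).

These constants are simulator calibration choices, not measured values.

### Surrogate dosimetric label

Each scenario carries ΔDmean: the relative change of the forward model
evaluated at mid-depth (t_eff/2) averaged over the projected planning PTV,
with the erroneous value computed using the delivered beam and anatomy.
It is exactly linear in MU (a +2% MU error gives +2.0%) and monotone in
attenuation changes — sufficient for ROC labeling. It is *not* a TPS
dose-volume metric: it ignores scatter, build-up and depth-dose shape, so
its absolute values (e.g. +2.5% for a removed 10 mm bolus at mid-depth:
e^(0.005·5) − 1) can differ substantially from a planning-system ΔDmean for
failure modes dominated by build-up physics.

## The failure-mode suite (22 scenarios)

| mode | scenarios | construction | typical |ΔDmean| |
|---|---|---|---|
| linac hardware | 11 | modulated 5-segment head-and-neck beam; MLC gap ±1.0/±1.5 mm, central-third leaves +2/+5 mm, collimator ±1°, MU ±2%, and the fully retracted MLC at planned jaws and MU | ≤ ~5% (retracted MLC ≫ 20%) |
| breathing | 6 | lung anatomy whose lung + GTV translate with breathing phase (amplitude 25 mm, exhale-dwelling waveform); plans on inspiration and expiration CTs each delivered on the other extreme, the 30–60% phase average and the all-phase average (averages = displacement-weighted means of the phase thickness maps) | extremes 10–20%, partials ≤ ~5% on the exhale side |
| patient swap | 2 | two breast patients of deliberately contrasting habitus; each treated with the other's plan | > 20% |
| wrong CT | 2 | pleural-fluid zone toggled between fluid-filled and drained between planning and delivery | > 20% |
| bolus | 1 | 10 mm bolus slab over the PTV footprint removed at delivery | ~2.5% (mid-depth surrogate) |

The magnitudes were calibrated so the suite spans deviations below 5%
(ordinary linac errors), 5–20% (breathing extremes), and above 20%
(retracted MLC, swaps, wrong CT). The linac list uses the ten single-error
plans implied by the stated magnitude grids plus the retracted-MLC case;
multi-error combinations are not enumerated. "Central leaves" is the middle
third of the open leaf pairs (configurable) — a convention, since leaf-bank
anatomy varies.

Determinism: the suite is a pure function of (config, seed); per-scenario
sub-seeds come from CRC-32 of the scenario name XOR the master seed.

### What the generator does *not* emulate

No TPS dose calculation (collapsed-cone or otherwise), no EPID calibration
or scatter kernels, no 4D-CT reconstruction, no DVH metrics, no realistic
VMAT delivery dynamics (segments are static random modulations). Passing
tests therefore show that the *pipeline* — gamma engine, labeling, ROC
machinery — behaves correctly and that the qualitative detection ordering
holds on transit-like images; they do not validate absolute AUCs or optimal
cutoffs for any clinical system. On this synthetic suite the class
separation is cleaner than on real patient data (AUCs near 1.0 for the
strong criteria), because the forward model is noiseless and the anatomy
simple.

## ROC analysis

Scenarios are labeled positive when |ΔDmean| exceeds the studied threshold
(5, 10 or 20%). For a decision threshold τ on the passing rate, a scenario
is called positive iff rate < τ — **equality counts as negative**, which
differs from some ROC libraries (scikit-learn's orientation convention is
used as a cross-check only on tie-free data). Candidate thresholds are the
observed rates plus sentinels beyond both extremes. AUC is the trapezoid
over (FPR, TPR), identical to pair-counting Mann–Whitney with ½ credit for
ties (asserted to 1e-12 against the independent pair-count oracle). The
optimal cutoff is the argmax of Youden's J = sens + spec − 1 over the
observed candidates (not an interpolated midpoint); ties break toward
higher specificity and then lower threshold, minimizing false positives.
Group summaries report the arithmetic mean AUC of the seven criteria of a
normalization, half-up-rounded to 2 decimals; report tables show AUC to 2
decimals and passing rates to 1. No confidence intervals are computed.

Tolerance failures use the 95% passing-rate tolerance with strict <
(a rate exactly at the tolerance passes).

## Pipeline and sizes

The default study (22 scenarios × 14 metrics on 256×256 grids, ROC at three
thresholds) runs in a few minutes on one CPU; the long-format passing-rate
CSV is the single interchange artifact, so externally produced passing
rates can be fed straight into the ROC stage (`transitqa roc --rates …`).
Unit and property tests run on 12–32 px fields against the exhaustive
oracle; the oracle-equivalence suite uses 50 field pairs.

## Known limitations

- Local-normalization gamma near the 20% dose threshold is intrinsically
  ill-conditioned (tolerance shrinks with the local dose); values there are
  dominated by the ceiling.
- The surrogate label understates failure modes governed by build-up
  (bolus) and ignores all out-of-plane scatter.
- `resample_to` and the gamma search assume axis-aligned grids sharing the
  patient coordinate frame; no registration is performed.
- DICOM support is deliberately minimal: single-plane RT Dose, and RT Plan
  attributes limited to MLC/jaw positions, collimator angle and meterset.
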