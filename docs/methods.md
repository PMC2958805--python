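# Methods

## Model and assumptions

`runfuel` treats an endurance runner as an aerobic engine with two fuels
and two meaningfully sized carbohydrate tanks. The assumptions, in order of
importance:

1. **Speed-independent cost of running.** The metabolic power of level
   running grows linearly with speed over the whole aerobic range, so the
   energy cost per km is a constant, `C` (default 1 kcal·kg⁻¹·km⁻¹, net of
   basal metabolism; see *Numerical choices*). Total race energy is then
   `C·M·d`, independent of pace.
2. **Intensity-determined fuel mix, constant in time.** The carbohydrate
   fraction of energy expenditure, `f(i)`, depends only on relative
   intensity `i` = VO2/VO2max. A time-dependent drift of the mix at
   constant intensity is deliberately not modelled: the experimental
   evidence for it is weak, of order 10 % after 2–3 h, and largely
   attributable to drifting aerobic output rather than a changing mix.
3. **Two-reservoir glycogen accounting.** Only liver and leg-muscle
   glycogen count toward the reserve per kg body mass; plasma glucose
   (< 20 kcal) is negligible and excluded, and non-leg muscle glycogen is
   assumed inaccessible to the working legs. Fat reserves are energetically
   unbounded for this purpose (even 2 % nonessential body fat fuels > 4
   marathons) and never binding.
4. **Aerobic regime only.** Intensities and speeds above `i = 1`
   (`v > v_max`) are a hard error, not an extrapolation; anaerobic power
   sources are out of scope.
5. **Heart-rate fraction as intensity.** The fractional maximum heart rate
   `h` is identified one-to-one with `i` in the VO2max estimator; no
   nonlinear HR–VO2 relation is modelled.

## The substrate-partition curve and its provenance

`f(i)` is a quadratic through three anchors at `i` = 0.25, 0.65, 0.85 —
the three intensities of the classic tracer/calorimetry protocol in
trained subjects (Romijn et al. 1993) — shipped as a plain-text table with
a provenance header (`src/runfuel/data/substrate_anchors.tsv`). The source
publishes figures rather than fitted coefficients, so the anchor values
(`f_cho` = 0.15, 0.44, 0.69, with whole-body oxidation rates summing to
84/218/285 cal·kg⁻¹·min⁻¹ and their standard errors) were digitized once,
to a few percent accuracy, and committed; they were chosen so that the
fitted curve reproduces the standard worked examples of the downstream
model (the 1020 kcal/h power example and the 3:42:00 marathon walkthrough)
within their stated tolerances, which is the only observable constraint the
original fit leaves. They are **not** tunable parameters; downstream
agreement with published walkthrough numbers is expected at the
few-percent level, not exactly.

With three anchors the fit is exact interpolation (a 3×3 Vandermonde
solve); more anchors fall back to least squares. The fitted quadratic is
increasing and convex on the anchored domain. Evaluation clamps to [0, 1];
extrapolation with the same quadratic is allowed up to `i = 1` (the model's
own intensity range extends there) and below `i = 0.25` with a logged
warning (marathon-relevant intensities exceed 0.55, so this region is
informational only).

Measurement error in `f` is propagated from the standard errors of the fat
and carbohydrate oxidation rates, which are measured independently; their
contributions combine in quadrature with partial-derivative weights
(`∂f/∂x_cho = x_fat/S²`, `∂f/∂x_fat = −x_cho/S²`, `S = x_fat + x_cho`).
At the packaged anchors the relative error `|δf/f|` peaks at 5.3 % (low
intensity) and falls to 2.3 % at `i = 0.85`, inside the 5.5 % worst-case
budget used by the sensitivity module.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| running cost `C` | kcal·kg⁻¹·km⁻¹ | 1.0 | net cost of level running; individual variation ~5–7 % |
| energy per mol O2, CHO | kcal/mol | 686/6 ≈ 114.3 | glucose combustion, 6 mol O2/mol |
| energy per mol O2, fat | kcal/mol | 2398/23 ≈ 104.3 | palmitate combustion, 23 mol O2/mol |
| molar volume | L/mol | 22.4 | gas volumes at STP |
| glycosyl residue mass | g/mol | 180 | free-glucose convention; required for the standard reservoir arithmetic (1.8 kg liver × 270 mmol/kg → ≈88 g) to reproduce |
| CHO energy density | kcal/g | 4.0 | reservoir-accounting convention (88 g → ≈350 kcal) |
| fat energy density | kcal/g | 9.4 | adipose tissue |
| liver fraction | — | 0.025 | tightly regulated |
| liver glycogen | mmol/kg | 270 typical, 500 max (= 360 kcal/kg) | physiologic range |
| leg-muscle fraction | — | 0.214 (typical male) | population ranges 0.14–0.275 (men), 0.18–0.225 (women) |
| muscle glycogen | mmol/kg | 110 typical, 200 supercompensated (= 80 / 144 kcal/kg) | trained runners; loading protocols |
| max heart rate | bpm | 207 − 0.7·age (Tanaka); 220 − age (Fox) | meta-analysis-supported age formulas |

Two energy conventions coexist on purpose: oxidative stoichiometry uses
kcal per mole O2 (combustion enthalpies), reservoir accounting uses
4 kcal/g. Both are standard in the field and both are kept, explicitly, in
one `Stoichiometry` record.

## Numerical choices

- **`v_max` convention.** The mixture energy term in the maximum aerobic
  speed is evaluated at `i = 1`, which makes `i = v/v_max` exactly
  self-consistent; aerobic power at intermediate `i` uses `ρ(i)`, so the
  two power routes differ by the factor `ρ(i)/ρ(1)` by construction.
- **Clamping.** `f(i)` is clamped to [0, 1] after evaluation; the complement
  `1 − f` is taken after clamping, so `f_cho + f_fat = 1` holds to machine
  precision everywhere.
- **Degenerate inputs.** `f(i) = 0` makes the distance to the wall
  infinite; the sentinel is `math.inf`, documented, rather than an error.
  Zero total oxidation makes the partition undefined and raises.
- **Glycogen depletion (un-clipped).** The predicted post-race change in
  muscle glycogen density is a *maximal* change (all carbohydrate assigned
  to leg-muscle glycogen) and is returned raw, with a boolean flag when it
  exceeds the stored density, rather than truncated — truncation would hide
  exactly the mid-race depletion the flag reports.
- **Pace strings** round half-up to the nearest second. Exact arithmetic
  for a 3:42:00 marathon gives 8:28.0 per mile; one published rounding of
  the same quantity prints 8:29, so tests accept either string.
- **Error bounds are first order** (logarithmic differentiation); the
  finite-difference verifier allows O(ε²) curvature headroom.
- **Fueling schedules** carry no absorption kinetics; as a practical rule
  of thumb, midrace carbohydrate should be ingested ~30 minutes before it
  is needed. Station schedules must sum to the declared total.

## The synthetic cohort

`CohortSpec`/`sample_cohort` draw runner profiles independently and
uniformly within published population ranges — leg-muscle fraction
0.14–0.275 (men) and 0.18–0.225 (women), muscle glycogen 110–200 mmol/kg,
VO2max 35–60 ml·kg⁻¹·min⁻¹, mass 50–90 kg by default — deterministically
under a fixed seed. The literature gives ranges, not distributions, so
uniform is the default; a range-anchored truncated normal (mean at the
midpoint, sd a quarter of the width, clipped) is available via
`distribution="normal"`. The generator emulates marginal population ranges
only: it has no correlations between traits (real VO2max co-varies with
mass and muscularity), no training history, and no within-runner
variability of running economy. Tests passing on these cohorts therefore
demonstrate the model's structural properties (monotonicity, bounds,
determinism) across the physiologic envelope, not predictive accuracy for
any real population.

## Problem sizes

Everything in the package is desk-scale: property tests use 10³ random
draws (10⁴ for cohort range checks), figure tables are a few thousand rows,
and the full suite plus the acceptance script run in seconds.

## Known limitations

- Substrate partitioning is taken from cycling-protocol data applied to
  running, at a fixed post-warm-up state; inter-individual spread of the
  curve is summarized by a single relative-error budget.
- The effective glycogen reservoir may be smaller than the anatomic pool
  (performance can fade before stores reach zero), so wall distances are
  upper-end estimates.
- Running economy `C` varies ~5–7 % between runners and is not
  personalized; incline/terrain dependence is not modelled.
- Heart-rate-based VO2max estimation belongs to the extrapolation family
  of methods, which can deviate from spirometry by 10–20 % in unfavourable
  cases.
- No lactate kinetics, central fatigue, thermoregulation or
  gastric-emptying dynamics.
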