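# Methods

## Model structure

The model tracks 14 dependent metabolite concentrations (mM): the MVA-chain
intermediates HMG-CoA, MVA, MVP, MVPP and the cytosolic IPP/DMAPP pool; and
the MEP-chain intermediates DXP, MEP, CDP-ME, CDP-MEP, MEcPP, HMBPP and the
plastidic IPP/DMAPP pool.  Twenty-three reactions connect them: the two
biosynthetic chains, the IDI isomerases in both compartments, first-order
IPP/DMAPP exchange between cytosol and plastid, and two lumped bilinear
sinks representing all downstream terpenoid biosynthesis
(`r20 = k1·IPP_cyt·DMAPP_cyt`, consuming 4 IPP + 2 DMAPP per event in the
cytosol; `r21 = k1'·IPP_pl·DMAPP_pl`, consuming 3 IPP + 1 DMAPP in the
plastid).  Upstream metabolism is a black box: acetoacetyl-CoA, G3P and
pyruvate are clamped inputs.  All enzymatic rates use the saturating
formalism `v = V·s/(s + Km·(1 + Σ x/Ki))`; enzyme-activity symbols are
dimensionless and absorbed into the `Vmax` values.

The time unit is the **hour**.  The source tables nominally give rate
constants per second, but the 24-h forcing period and the multi-hour
relaxation transients of the reported dynamics are consistent only with
hours; a global `time_unit_scale` configuration factor (default 1) rescales
all rate-dimension constants if another unit is wanted.

## Parameter provenance

All binding, inhibition and saturation constants are the published values,
used verbatim (`provenance: printed` in the reference fixture).  Four groups
needed reconstruction (`derived` / `calibrated`):

* **Acetoacetyl-CoA = 0.350 mM.**  The published input table lists only
  Ac-CoA at 0.350; using that value for the HMGS substrate reproduces the
  reported chain flux (r1 = r2 = 0.0312 mM/h at HMG-CoA = 0.983 mM) to three
  significant figures.
* **θ = 4.711 (MVK inhibition load).**  The MVK rate law is inhibited by
  downstream prenyl diphosphates (FPP, GPP, GGPP, PhyPP) that are not state
  variables here; their combined load is lumped into a constant θ in the r3
  denominator, `MVA + Km3·(1 + MVP/Ki31 + θ)`.  θ is fixed by the
  MVK-dominated Jacobian eigenvalue (−891.95 /h ≈ −Vmax3/(Km3·(1+θ+MVP/Ki31)))
  and independently reproduces the reported MVA and MVP steady-state
  concentrations.  θ is held constant in all circadian variants: the
  downstream pools it summarizes are not modeled, so letting it oscillate
  would add an unconstrained degree of freedom.
* **DXP synthase (r10) rate form.**  The printed rate law saturates in
  pyruvate, but with Vmax13 = 0.20 mM/h the MEP chain cannot carry the
  ~1.2 mM/h flux that form implies, and the reported flux sensitivity to Km8
  (−0.920) is reproduced only if the saturating species has concentration
  0.006 mM — i.e. G3P.  We therefore use
  `r10 = Vmax8·(pyruvate/pyruvate_H)·G3P/(G3P + Km8·(1 + IPP_pl/Ki81 + DMAPP_pl/Ki82))`;
  the normalized pyruvate factor equals 1 at basal conditions and carries
  the circadian substrate scaling.  Hand check at the published state:
  ∂log r10/∂log Km8 = −0.9226 versus −0.920 reported.
* **Consumption constants k1, k1'.**  The printed values (2.0×10⁶ /
  1.6×10⁴) are irreconcilable with the published steady-state pools by ~8
  orders of magnitude (they imply a consumption of ~10⁵ mM/h against a
  production of ~0.03 mM/h).  `calibrate_consumption` instead fits k1 and
  k1' by least squares to the four published IPP/DMAPP steady-state balance
  equations, which are linear in these constants and decouple by
  compartment.  Reference values: k1 = 1.006 /mM/h, k1' = 0.695 /mM/h.  The
  fit cannot close the cytosolic balances exactly (residual norm 0.024
  mM/h); the residuals are part of the calibration report.
* **DMAPP exchange constants set to zero in the reference.**  With the
  printed first-order exchange constants (export 1 /h, import 0.1 /h)
  applied to DMAPP as well as IPP, the published plastid pools export ~0.20
  mM/h against a maximal MEP production of ~0.10 mM/h — no non-negative
  consumption constant admits the published steady state, and the solved
  state then misses the published MEP-chain concentrations by 20–90%.
  Setting the DMAPP exchange constants to zero (IPP exchange keeps its
  printed values) makes the plastid balances close almost exactly
  (residuals ~10⁻⁴ mM/h) and reproduces every published concentration to
  within ~5% and the six fastest Jacobian eigenvalues to within 0.5%.  The
  reference parameterization therefore exchanges only IPP between
  compartments; the printed DMAPP constants remain available as
  configuration overrides (`parameters: {k2p: 0.1, k3p: 1.0}`).
* **Plastid IDI and the DMAPP branch of HDR** are distinct named parameters
  (`Vmax6pl/Km6pl/Ki6pl`, `Vmax7pl/Km7pl`, `Vmax14p/Km14p`) initialized to
  their cytosolic/IPP-branch values, giving 52 enumerable kinetic
  parameters (14 metabolites × 52 parameters = 728 sensitivities).  The
  four downstream Ki constants lumped into θ stay in the parameter set with
  zero sensitivity.  Eight printed rapid-equilibrium constants (k4–k11)
  have no cognate reaction in the published rate tables and are not
  instantiated.

## Circadian forcing and regulatory variants

Light is `L(t) = ½[(1+tanh((τ−dawn)/T)) − (1+tanh((τ−dusk)/T)) +
(1+tanh((τ−period)/T))]` with `τ = t mod period` (the modulo form is
mathematically identical to the floor-based expression and avoids
large-argument overflow).  Period 24 h, dawn 0, twilight steepness T = 1 h
by default; `dusk` is the photoperiod control.  Note two structural features
of this profile: at dusk→0 the dawn and dusk fronts cancel but the
period-boundary front remains, leaving a ~0.5-amplitude midnight bump; at
dusk→24 a complementary midnight dip remains.  Forcing therefore never
vanishes entirely at the photoperiod extremes.

The three regulation modules multiply basal values by `L` (substrate
availability; consumption constants) or anti-phasically by `1−L`/`L`
(MVA-side / MEP-side `Vmax`, with both cytosolic IDI directions counted as
MVA-side and plastidic IDI as MEP-side).  `Km` and `Ki` are never modulated.
The eight on/off combinations map one-to-one onto Models A (none), B
(substrate), C (expression), D (consumption), BC, BD, CD and E (all three).

## Numerics

* **Steady state:** stiff relaxation (LSODA, rtol 1e-10, atol 1e-14, 2000 h)
  from 1 µM for all species, then damped Newton (step halving, residual
  decrease required, tolerance 1e-13 on max |dx/dt|) using the analytic
  Jacobian.  When a good initial guess is available Newton runs directly.
  Multi-start from log-uniform random guesses converges to the same state.
* **Jacobian:** assembled analytically as `N · ∂r/∂x` (stoichiometric matrix
  times per-flux partials); cross-checked against central finite differences
  in the tests.
* **Concentration sensitivities:** implicit differentiation
  `dx/dp = −J⁻¹ ∂f/∂p` at the steady state (one LU factorization reused for
  all 52 parameters), cross-checked against re-solved central differences to
  1e-3 absolute.  Sensitivities to parameters whose value is exactly zero
  are zero by the logarithmic convention.
* **Aggregate flux sensitivities:** stoichiometry-weighted production and
  consumption sums per metabolite, differentiated with concentrations held
  fixed at the steady state (relative step 1e-6 on log parameters).
* **Eigenvalue sensitivities:** central differences (relative step 1e-5)
  on re-solved steady states, with perturbed eigenvalues matched to the
  reference spectrum by maximal eigenvector overlap; ambiguous assignments
  (a symptom of crossings within the step) are flagged unreliable.
* **Circadian runs:** LSODA with rtol 1e-8 / atol 1e-12, 2000 stored samples
  per day (daily extrema resolved to well under 0.1%), 10 simulated days
  with day 10 analyzed — about six times the slowest relaxation time, so
  consecutive daily summaries agree to 1%.  Initial condition: the Model A
  steady state.  Oscillation size is the min/max ratio over one day.
  The default photoperiod sweep grid is 0.5–23.5 h in 0.5-h steps (the
  analysis scripts use a 1-h grid to keep runtimes at a few minutes).
* **Robustness ensemble:** 100 parameter sets, each parameter multiplied by
  an independent log-normal factor with σ = 0.1 on the natural-log scale
  (the standard choice for strictly positive kinetic constants), fixed seed
  20241114, drawn in a single block so results are independent of iteration
  order.

## What the fixtures emulate — and what they do not

The reference fixture *is* the published parameterization (plus the derived
values above); the toy chains are exact algebraic constructs, not biology.
Passing tests therefore demonstrate internal correctness of the solvers and
the faithful reproduction of the published steady-state regime — they say
nothing about parameter values in real tissue, about transcription-level
clock dynamics (CCA1/LHY/TOC1 are outside the model), or about downstream
terpenoid pathways, which enter only as the lumped sinks.

## Known limitations

* The published IPP/DMAPP pools cannot satisfy their own balance equations
  under any non-negative consumption constants (cytosolic residual ~0.02
  mM/h even after calibration), and the published sensitivity tables for
  the isomerase block are consistent only with the enormous printed k1/k1'
  values that the steady-state and eigenvalue tables exclude.  Under the
  single consistent parameterization used here, the isomerase-block
  concentration sensitivities reach |S| ≈ 3.9 and 63 of 728 entries exceed
  0.5 (reported as computed; the corresponding published count is 51 with
  a maximum below 3).
* Figure-level circadian claims are reproduced as directional properties;
  several depend on the consumption-constant regime and on the residual
  midnight forcing of the tanh light profile (e.g. amplitudes do not
  collapse fully to constants at photoperiod extremes, and the cytosolic
  IPP pool responds to the exchange knockout opposite to the plastid
  pools).  The analysis scripts print the measured values.
* The sensitivity analysis is local (first-order, around one steady state);
  no global sensitivity or bifurcation analysis is attempted.
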