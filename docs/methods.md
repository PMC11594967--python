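# Methods

## Model structure

The model is a hax-type DEB formulation for a holometabolous aquatic
insect.  State variables: reserve *E* (J), structure *V* (cm³), maturity
*E_H* (J), reproduction buffer *E_R* (J), plus an integrated cumulative
hazard for survival.  Stages and their flux rules:

| stage | feeding | allocation | terminating event |
|---|---|---|---|
| embryo | no | κ-rule, isomorph, s_M = 1 | E_H = E_Hb (birth) |
| L1–L3 | yes | κ-rule, V1-morph (s_M = L/L_b) | E_H = E_Hp (puberty) |
| L4 Phase I | yes | κ-rule, isomorph, s_M frozen; p̊_R → E_R | E_R/V = [E_Rj] |
| L4 Phase II | yes | p̊_C = p̊_S + p̊_J; p̊_G = 0; reserve refills | E/V = [E_m] (pupation) |
| pupa | no | κ-rule from V ≈ 0, E_H restarts at 0 | E_H = E_He (emergence) |
| imago | no | p̊_C = E v̊ s_M V^(−⅓); no growth/maturation | reserve cannot cover maintenance, or horizon |

At pupation the larval structure V_j is converted to reserve with
efficiency κ_V (≈10⁻⁶ for this species, i.e. effectively discarded), the
pupa restarts from a seed structure V_seed = 10⁻⁸ cm³ (configurable;
halving it moves the emergence age by <0.5%, asserted by test), and the
reproduction buffer is retained unchanged.  Egg number is
N_i = κ_R [E_Rj] V_j / E_0 with κ_R = 0.95, a conventional DEB
reproduction efficiency: κ_R is absent from the published parameter table
and enters only this formula, so it is exposed as a configurable parameter.

**Initial egg energy.**  E_0 is solved by bisection so that the scaled
reserve density e = E v̊ / ({p̊_Am} V) equals 1 at the birth event — the
abundant-food maternal condition, applied to every scenario (no maternal
effect).  The egg integration starts from a numerical seed volume
(10⁻¹² cm³); because the V → 0 asymptote grows at dL/dt = v̊/3 regardless
of reserve, the analytically exact time offset 3 V₀^⅓/v̊ is added back,
making the age at birth independent of the seed.

**Acceleration bookkeeping.**  s_M multiplies {p̊_Am} and v̊ together, so
the maximum reserve density [E_m] = {p̊_Am}/v̊ — and with it the pupation
reserve trigger — is invariant under acceleration.  After puberty s_M is
frozen at L_p/L_b for the rest of the cycle; re-applying the clamped
formula to the pupa, whose structural length restarts near zero, would
wrongly de-accelerate it.

## Forcing

Temperature enters through a single correction factor applied to every
rate parameter,

    c_T(T) = exp(T_A/T_ref − T_A/T) · u(T_ref)/u(T),
    u(T) = 1 + exp(T_AH/T_H − T_AH/T),

the three-parameter upper-bounded Arrhenius form, normalized at
T_ref = 293.15 K.  No lower thermal boundary is implemented (the
five-parameter form would need T_L, T_AL, which are not identified for this
species), so predictions below ~15 °C inherit extra uncertainty.  A single
c_T for all rates has a strong consequence used by the tests: at constant
temperature the whole trajectory is a pure time rescaling, so event ages
scale exactly as 1/c_T while lengths and energies at events are
temperature-independent.

Food acts through the scaled functional response f ∈ [0, 1) of Holling
type II; scenarios may also set f directly, including values above 1 for
rich-diet protocols.  Scenarios are constant or piecewise-linear in time
since hatch at constant temperature; the integrator restarts at every
breakpoint so no event root is bracketed across a derivative kink.  The
`declining_food_scenario` constructor reproduces the rearing protocol
inferred for growth experiments: f = 1 until puberty, then a linear decline
over 7.5 d to a ration-specific minimum (estimated at 1/0.58/0.25/0.12 for
the 0.6/0.3/0.15/0.1 mg larva⁻¹ d⁻¹ rations; packaged in
`species/functional_responses.csv`).

## Numerics

Integration uses LSODA with rtol 10⁻¹⁰ and per-state absolute tolerances;
every stage threshold is a terminal event located by root-finding on the
dense output (relative trigger residuals < 10⁻⁶ at the recorded events,
asserted by test; a fixed-step RK4 oracle at 10⁻⁴ d reproduces the puberty
age to 0.1%).  At abundant food the reserve density is already at [E_m]
when Phase II begins; a start-of-leg check (relative tolerance 10⁻⁹)
collapses Phase II to zero duration instead of hunting a root at a
machine-epsilon residual.  The default horizon is 200 d; unreachable
triggers terminate with an explicit status (`pupation_not_reached`), never
an exception.

**Survival.**  S(t) = exp(−∫h dt) with h = h_b + k_starv·max(0, 1 −
κ p̊_C/p̊_S), integrated alongside the state from birth.  In stages that do
not allocate by the κ-rule (L4 Phase II, imago) p̊_C in this formula is the
κ-rule mobilization *capacity* at the current state (for the imago, its own
mobilization against total maintenance); the literal Phase II flux
p̊_C = p̊_S + p̊_J would flag starvation even at abundant food.  Under ad
libitum food the hazard reduces exactly to the background rate.

**Instar partition.**  Dyar's law assigns the L1→L2 and L2→L3 molts to
structural-length thresholds L_b·s₁^q and L_b·(s₁s₂)^q, with the L3→L4
molt pinned at puberty by construction.  The exponent q maps the molt
constants to length ratios (q = ⅓ reads them as volume ratios, q = ½ as
surface ratios); q = ½ is the default because it reproduces the observed
instar-duration pattern (2.0/2.0/2.7 d at 21 °C) and it is exposed as an
argument since the exact convention behind s₁, s₂ is not fixed by the
parameter table.  The partition is diagnostic only — it never feeds back
into the dynamics.

## Observables

Physical length is V^⅓/δ_M with separate shape coefficients for alive
(δ_M1 = 0.083) and dead (δ_M2 = 0.067) measurements.  Weights combine
structure (wet density 1 g/cm³, dry fraction 0.17), reserve (4.345×10⁻⁵ g
dry per J, water fraction 0.70) and the reproduction buffer, which is
treated as pure dry mass — eggs of aquatic insects absorb water only after
laying, and this assumption is what makes the dry-weight fraction rise
through the fourth instar.  The composition coefficients follow common DEB
practice but are not identified by the core parameter set; weight-valued
predictions should be read as order-of-magnitude until these are calibrated
against weight data.  Oxygen consumption is provided only as an explicit
proxy (a configurable coefficient times the maintenance dissipation
p̊_S + p̊_J): a genuine respiration prediction needs chemical indices that
are out of scope.

## Calibration

The loss is the symmetric bounded form, Σ w (d−p)²/(d²+p²), summed over
all datasets with per-dataset weights divided by the dataset's point count;
it is scale-invariant, symmetric in data and prediction and bounded per
point by its weight.  MRE is the dataset-weighted mean of within-dataset
mean relative deviations |p−d|/|d| (zero-valued data excluded); SMSE the
analogous mean of symmetric squared deviations, bounded in [0, 1].
Estimation is simultaneous Nelder–Mead in log-parameter space (positivity
by construction) with jittered restarts (3 by default, deterministic given
the seed) and pseudo-data: the maintenance ratio k = k̊_J[E_G]/[p̊_M] is
kept near 1 with weight 0.1, which stabilises k̊_J and encodes the
observation that event lengths are nearly food-independent in insects.
κ_V (fitted near zero for this species) is held fixed by default rather
than estimated — it is practically unidentifiable.

## Synthetic data

The generator simulates a scenario, samples lengths/weights at design ages
and event ages/fecundity, and applies multiplicative lognormal noise with
unit mean and a chosen CV — all observables are positive and the source datasets
carry no stated error model, so this is the simplest unbiased choice.
It emulates designed rearing experiments (regular sampling, independent
errors); it does not emulate between-individual variability, censoring by
mortality, or shared measurement-session errors, so recovery tests
demonstrate identifiability under the stated noise model, not robustness to
those real-data features.  The default recovery study uses 10-point length
and wet-weight series plus puberty/pupation ages and fecundity at f = 1,
21 °C with CV = 0.05; from a 20%-perturbed start, {p̊_Am}, v̊, [p̊_M],
E_Hp and [E_Rj] are recovered within a few percent.

## Known limitations

* **Printed-precision sensitivity.**  E_Hb is published to one significant
  figure (0.003 J).  The embryo-anchored outputs (age at birth, structural
  length at birth, hence the acceleration factor L_p/L_b and the length at
  pupation) respond at the several-percent level within that rounding
  interval, while pupation- and emergence-time predictions are insensitive
  to it.  The packaged file keeps the printed value verbatim.
* No ageing module: the imago is simulated until reserve cannot cover
  maintenance or the horizon ends; imago lifespan is not a model output.
* No food-density bookkeeping of the rearing medium: scenarios act directly
  on f.
* Single-sex parameterisation except for the male assimilation override
  {p̊_Amm}; no sex-specific shape coefficients or thresholds.
* No gradual pupal decay of larval structure (instantaneous conversion
  only), and no egg-laying schedule within the imago stage.
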