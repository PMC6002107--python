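# Methods

## Model

The respiratory system is a volume–pressure analog of an electrical
circuit: an upper rigid airway (inertance I_u, flow-dependent Rohrer
resistance R_u), a collapsible middle airway (volume-dependent Poiseuille
resistance R_c, sigmoid pressure–volume curve), small peripheral airways
(resistance falling exponentially with lung inflation), an alveolar
compartment, lung tissue viscoelasticity (Kelvin–Voigt pair C_ve, R_ve)
and a softplus chest wall. Kirchhoff mesh sums over the three pressure
loops give four ODE states: total flow V̇, collapsible volume V_c, lung
elastic recoil P_el and viscoelastic pressure P_ve. Conservation
V_cw = V_A + V_c holds identically — the chest wall encloses lung plus
conducting airway.

Unit system: volumes ml, pressures cm H2O, flows L/s, resistances
cm H2O·s/L, inertance cm H2O·s²/L. The mixed ml/L convention follows how
these constants are conventionally quoted; all conversions live in the
right-hand side (factors of 1000 on dV_c/dt and dP_el/dt).

Alveolar compliance C_A = dV_A/dP_el is the exact closed-form derivative
of the recruitment-weighted lung curve (distension term plus
recruitment-slope term); tests pin it to a central finite difference at
1e-6 relative.

### Assumptions

- One aggregate compartment per structure; no abdominal/ribcage split, no
  paradoxical chest motion.
- Sinusoidal muscle driver with equal inspiratory/expiratory halves;
  amplitudes A_mus are fixed per condition (no neural feedback, no
  chemoreflex, no sighs).
- Recruitment is a static sigmoid in recoil pressure within a breath;
  its parameters change only between breaths.
- No surfactant/surface-tension biophysics; derecruitment is empirical.

## Parameterization

All mechanical constants are stored at their published nominal values for
a 1 kg extremely preterm infant (TLC 63 ml, RV 23 ml, k 0.07 /cm H2O,
β 0.01, γ 1, c_F 0.1, d_F 0.4 cm H2O, etc.). Derived constants are
enforced, never stored: b_w = (V_0 − RV)/ln 2 with V_0 = 35 ml (the
stored V_0 is authoritative; the ν = 0.25 "fraction of VC" description
would give 33 ml and is retained as documentation only), and the
recruitment lower asymptote α from F_rec(0) = β, i.e.
α = ((1 + e^(c_F/d_F))·β − γ)/e^(c_F/d_F) = −0.761 at nominal values.

Two chest-wall conditions: d_w = 0.48 (high compliance, dynamic
C_w ≈ 10 ml/cm H2O) and d_w = 2.4 (low, ≈ 3). Laryngeal braking
multiplies both Rohrer coefficients (R_u,m and K_u) by 10, gated on
instantaneous expiratory flow.

### Resting equilibrium (FRC)

FRC is found where lung recoil balances chest recoil. We solve the full
resting circuit: with no flow and a relaxed viscoelastic element,
P_tm = P_el and P_cw = −P_el, so the equilibrium condition is

    V_cw(−P_el) = V_A(P_el) + V_c(P_el)

solved by Brent's method in P_el (residual << 1e−6 cm H2O). This is
exactly the fixed point of the ODE system — including the
collapsible-airway (dead-space) volume of ~0.8–0.9 ml — rather than the
textbook two-curve construction, which ignores V_c and lands ~0.5 ml
higher. The full-circuit form reproduces the published low-compliance
pair (our 28.24 ml / 2.038 cm H2O vs 28.1 / 2.015) far better; the
published high-compliance pair (24.9 ml / 0.954 cm H2O) is not exactly
consistent with any reading of the published curves (the lung curve
gives 25.10 ml at 0.954), and we obtain 24.84 ml / 0.871 cm H2O.

A_mus calibration (to a target minute ventilation of 360 ml/min) is a
bisection on the full steady-state simulation, since tidal volume
depends on every nonlinearity; tolerance 0.5 ml/min. With the published
amplitudes our steady states sit within ~1–2 % of the published tidal
volumes (e.g. 5.91 vs 5.99 ml for the high-compliance baseline), with
the increased-resistance column matching to the printed precision.

## Breath integration

Each breath is integrated over one period [0, 1/f] with LSODA (odeint),
rtol 1e-6 / atol 1e-8, 201 output samples per breath, end conditions
seeding the next breath. The prescribed initial condition
V_c(0) = 0.0001 ml sits at the bottom of the collapsible sigmoid and
produces a stiff millisecond transient (R_c ~ 6×10⁷ at that volume);
LSODA's automatic stiff switching absorbs it, and steady-state metrics
use a 10-breath burn-in with convergence declared when successive tidal
volumes agree to 0.1 %. End-inspiration/end-expiration are the V_A
maximum/minimum instants of the sampled trace (resistive and
viscoelastic lags shift them off the driver phase); dynamic compliances
are EI-to-EE secants. At 201 samples the peak-sampling error in V_T is
~0.002 ml, well under the reported precision. The inner right-hand side
is a flat scalar function, JIT-compiled with numba when available
(pure-Python fallback is arithmetically identical; an engine test pins
it to the public constitutive functions).

## Progressive volume loss

After every (non-apneic) breath:

1. Tidal expansion ratio of the aerated lung u = (EILV − RV)/(EELV − RV).
2. Closed fraction at end-inspiration. Two variants appear deliberately:
   the γ update uses the fraction relative to the current ceiling,
   F_closed|rel = 1 − F_rec|EI/γ (required so that full permanence,
   p = 1, makes F_rec|EI the new γ); the pressure-compensation drift
   uses the absolute unrecruited fraction 1 − F_rec|EI, because the open
   units must carry the volume of every closed unit, permanently lost
   ones included. The two coincide for γ = 1. The relative form in the
   drift would make permanent closure *lengthen* survival, inverting the
   established ordering — that is why the absolute form is used.
3. Compensatory pressure factor s = (u′^⅓ − 1)/(u^⅓ − 1) with
   u′ = 1 + (u − 1)/(1 − F_closed): the same aggregate volume change
   shared among the open fraction, pressure scaling with the fractional
   radius increase. The canonical three-unit example (volumes double,
   one of three closes) gives 25 % → 35 % radius increases, s ≈ 1.37.
   An alternative reading — the ratio of end-expansion radii,
   s = (u′/u)^⅓ — is available behind `mode="radius_ratio"` but is not
   the default: it reproduces the same example only as 1.357/1.26 and
   degrades the low-compliance failure time badly.
4. c_F ← s·c_F, d_F ← s·d_F (the curve shifts right and broadens),
   γ ← γ(1 − p·F_closed|rel), α re-derived.

The loop is self-accelerating: a right-shifted curve recruits less at
the same effort, increasing the next shift. Failure is declared at the
first breath with V_T ≤ (1 − 0.9)·V_T,init, where V_T,init = 6 ml is the
nominal initial tidal volume implied by the 360 ml/min target at 60
breaths/min (an EELV-based criterion is configurable but cannot fall
90 % with RV > 0). Time to failure (TTF) is the cumulative simulated
time at that breath.

Variable-frequency mode recomputes f = V̇E,target/(60·V_T,ave) each
breath from a moving average of up to the last 60 tidal volumes (growing
from whatever history exists), capped at 3 breaths/s to avoid f → ∞ as
V_T collapses. An apneic event (default 20 s at the 2-minute mark) is
inserted as whole silent breaths (A_mus = 0); apneic breaths are
excluded from the drift, the failure test and the frequency average.
CPAP is a permanent P_ao step (default 5 cm H2O) armed when F_rec|EI
first falls below the trigger (0.90/0.95/0.97).

### Fidelity of the failure times

The breath-to-breath drift is specified only through the three-unit
worked example, and the failure time is exponentially sensitive to both
the rule's exact form and the steady-state end-inspiratory recoil
pressure (a 0.14 cm H2O difference scales TTF by ~1.4×). Under the
reading above, the orderings are robust and reproduced — high C_w fails
before low C_w in every matched pair, braking extends survival
many-fold, earlier CPAP strictly extends it, permanent closure shortens
it — but the absolute magnitudes deviate from the published table: our
untreated runs fail at 0.136 h (high C_w, published 0.30) and 3.33 h
(low, published 2.49); the braked high-C_w run fails at 21.1 h
(published 18.5) while the braked low-C_w run survives past 55 h
(published 24.7); CPAP-treated runs gain minutes rather than hours. No
single self-consistent reading of the drift rule that we tested
(fractional-increase vs radius-ratio scaling, distension-based vs
aerated-volume expansion ratios, relative vs absolute closed fractions)
reproduces all published magnitudes simultaneously; the default is the
reading that reproduces the worked example exactly and preserves every
ordering. The acceptance suite asserts the published magnitudes at their
stated tolerances and deliberately leaves them red where this
implementation cannot reach them.

## Stability analysis

Under a constant (non-oscillatory) muscle pressure the fixed point is
found by a hybrid-Powell root of the right-hand side (residual < 1e−8)
started from the static equilibrium; eigenvalues come from a central
finite-difference Jacobian with per-state steps max(1e−6, 1e−6·|y_i|)
(states span four orders of magnitude). At nominal parameters the
spectrum is real and negative (≈ −301, −140, −24, −5.8 s⁻¹ for the
high-compliance condition): collapsible-airway filling, flow, lung
emptying and viscoelastic relaxation, in that order. The sweep rescales
each tunable parameter by 2 and 10 and re-analyzes; no case
destabilizes. Exact row-scaling identities (det J ∝ 1/I_u, ∝ 1/C_ve)
serve as analytic oracles in the tests. The clamping guards on V_c and
V_cw are confirmed inactive at every equilibrium, so the finite
differences never straddle a kink.

## Numerical and design choices

- Inverse-curve guards: V_c is clamped to [1e−6, V_c,max − 1e−6] ml and
  V_cw to ≥ RV + 1e−9 ml before inversion inside the RHS; only the
  initial transient ever engages them.
- CPAP applies from the breath after its trigger breath (detection is a
  per-breath summary quantity).
- The c_w transition-point parameter is carried explicitly in the
  softplus argument (P_cw − c_w) with default 0, keeping every published
  symbol addressable.
- Determinism: the model has no stochastic component; identical
  configurations produce bit-identical breath tables (asserted in the
  tests). The acceptance script's `--seed` is recorded into the scenario
  for forward compatibility.
- Problem sizes: steady-state metrics use ≤ 40 breaths; failure runs
  integrate to their natural end (488–12,000 breaths for the untreated
  scenarios); the braking orderings are established with capped runs
  (5× the matched untreated failure time) rather than multi-hour
  integrations, which proves the ordering without the full horizon.

## Known limitations

- Published TTF magnitudes are only order-of-magnitude reproducible (see
  above); orderings are exact.
- The published high-C_w resting pair (FRC, P_el|FRC) is internally
  inconsistent with the published curves; we match FRC to 0.06 ml but
  sit 0.08 cm H2O below the quoted resting recoil pressure.
- The p = 0.1 permanent-closure runs shorten survival by much more than
  the published ~10 % (the γ feedback compounds under our drift
  reading).
- No recruitment recovery mechanism exists (no sighs, no time-dependent
  reopening), so CPAP can arrest but never reverse volume loss.
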