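"""The ODE core: one breath of the four-state respiratory circuit.

States (positive airflow is inspiratory, toward the alveoli):

* ``flow``  — total airflow at the airway opening, L/s
* ``V_c``   — collapsible-airway volume, ml
* ``P_el``  — lung elastic recoil pressure, cm H2O
* ``P_ve``  — viscoelastic (Kelvin-Voigt) pressure component, cm H2O

The right-hand side composes the constitutive laws through the mesh-loop
pressure algebra: the chest wall encloses lung plus collapsible airway
(``V_cw = V_A + V_c``), pleural pressure is chest recoil plus muscle
pressure, and alveolar flow follows from the small-airway loop::

    dflow/dt = (P_ao − P_u − R_u·flow)/I_u
    dV_c/dt  = flow − flow_A
    dP_el/dt = flow_A / C_A(P_el)
    dP_ve/dt = (flow_A − P_ve/R_ve) / C_ve

Each breath is integrated over one period [0, 1/f] with LSODA (stiff/
non-stiff switching — the prescribed initial condition V_c = 1e-4 ml sits
far down the collapsible sigmoid and produces a stiff millisecond
transient), and end conditions seed the next breath.

For speed the integrator uses a flattened scalar right-hand side
(:func:`_rhs_flat`); its agreement with the public constitutive functions
is covered by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import odeint

from . import constitutive as law
from .constitutive import VC_CLAMP, VCW_CLAMP
from .params import RecruitmentState, RespiratoryParameters

__all__ = ["StateVector", "DerivedPressures", "BreathSummary", "BreathTrace",
           "muscle_pressure", "compute_derived", "rhs", "integrate_breath",
           "BreathIntegrationError"]

TWO_PI = 2.0 * math.pi


class BreathIntegrationError(RuntimeError):
    """Raised when the ODE solver fails within a breath."""

    def __init__(self, message: str, breath_index: int | None = None):
        super().__init__(message)
        self.breath_index = breath_index


@dataclass(frozen=True)
class StateVector:
    """The four ODE states at one instant."""

    flow: float = 0.0       # L/s
    V_c: float = 1e-4       # ml
    P_el: float = 0.0       # cm H2O
    P_ve: float = 0.0       # cm H2O

    def as_array(self) -> np.ndarray:
        return np.array([self.flow, self.V_c, self.P_el, self.P_ve])

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "StateVector":
        y = np.asarray(y, dtype=float)
        if y.shape != (4,) or not np.all(np.isfinite(y)):
            raise ValueError("state must be 4 finite numbers")
        return cls(*y)


@dataclass(frozen=True)
class DerivedPressures:
    """Algebraic pressures, volumes and alveolar flow derived from a state.

    Fields may be scalars or arrays (one entry per trace sample)."""

    P_mus: np.ndarray   # respiratory muscle pressure, <= 0
    P_cw: np.ndarray    # chest-wall elastic recoil
    P_pl: np.ndarray    # pleural pressure
    P_tm: np.ndarray    # transmural pressure across the collapsible wall
    P_c: np.ndarray     # pressure inside the collapsible segment
    P_u: np.ndarray     # pressure at the upper/collapsible junction
    P_A: np.ndarray     # alveolar pressure
    P_l_dyn: np.ndarray  # dynamic transpulmonary pressure P_el + P_ve
    P_ao: np.ndarray    # airway-opening (CPAP) pressure
    V_A: np.ndarray     # alveolar volume, ml
    V_cw: np.ndarray    # chest-wall volume = V_A + V_c, ml
    flow_A: np.ndarray  # alveolar airflow, L/s


def muscle_pressure(t, A_mus: float, f: float):
    """Sinusoidal respiratory-muscle driving pressure, cm H2O.

    ``P_mus = A_mus·cos(2πft) − A_mus``: zero at the breath boundaries,
    peak inspiratory effort −2·A_mus at mid-breath.
    """
    t = np.asarray(t, dtype=float)
    out = A_mus * np.cos(TWO_PI * f * t) - A_mus
    return out[()] if out.ndim == 0 else out


def compute_derived(y, t, params: RespiratoryParameters, rec: RecruitmentState,
                    A_mus: float, f: float, P_ao: float = 0.0,
                    expiratory_multiplier: float = 1.0) -> DerivedPressures:
    """Derived pressures/volumes/flows for state(s) ``y`` at time(s) ``t``.

    ``y`` is a length-4 state or an (n, 4) trace array.  The computation
    follows the mesh loops: lung volume from recoil pressure, chest-wall
    pressure from total volume, pleural pressure from chest recoil plus
    muscle pressure, transmural pressure from the collapsible sigmoid, and
    alveolar flow from the small-airway pressure drop.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    flow, V_c, P_el, P_ve = y.T
    V_c = np.clip(V_c, VC_CLAMP, params.V_c_max - VC_CLAMP)

    V_A = law.lung_volume(P_el, params, rec)
    V_cw = V_A + V_c
    P_cw = law.chest_wall_pressure(
        np.maximum(V_cw, params.RV + VCW_CLAMP), params)
    P_mus = muscle_pressure(t, A_mus, f)
    P_pl = P_cw + P_mus
    P_tm = law.collapsible_pressure(V_c, params)
    P_c = P_tm + P_pl
    R_s = law.small_airway_resistance(V_A, params)
    flow_A = (P_tm - P_el - P_ve) / R_s
    P_u = P_c + law.collapsible_resistance(V_c, params) * flow
    P_A = P_el + P_ve + P_pl

    sq = (lambda a: a[0]) if y.shape[0] == 1 and np.isscalar(t) else (lambda a: a)
    bc = np.broadcast_to
    n = y.shape[0]
    return DerivedPressures(
        P_mus=sq(bc(np.atleast_1d(P_mus), (n,)).copy()),
        P_cw=sq(P_cw), P_pl=sq(bc(np.atleast_1d(P_pl), (n,)).copy()),
        P_tm=sq(P_tm), P_c=sq(bc(np.atleast_1d(P_c), (n,)).copy()),
        P_u=sq(P_u), P_A=sq(bc(np.atleast_1d(P_A), (n,)).copy()),
        P_l_dyn=sq(P_el + P_ve), P_ao=sq(np.full(n, float(P_ao))),
        V_A=sq(V_A), V_cw=sq(V_cw), flow_A=sq(flow_A))


# --------------------------------------------------------------------------
# Fast scalar right-hand side (hot path)
# --------------------------------------------------------------------------

def _rhs_flat(y, t, p):
    """Scalar RHS over a flat parameter tuple; see :func:`_pack`.

    Kept free of package types so it can be JIT-compiled (numba, when
    available) for the long breath-by-breath runs; the pure-Python path is
    identical."""
    (TLC, RV, VC_, k, b_w, c_w, d_w, c_c, d_c, V_c_max, K_c,
     R_s_m, R_s_d, K_s, I_u, R_u_m, K_u, R_ve, C_ve,
     alpha, gamma, c_F, d_F, A_mus, f, P_ao, mult) = p
    flow, V_c, P_el, P_ve = y

    ez = math.exp(-(P_el - c_F) / d_F)
    sig = 1.0 / (1.0 + ez)
    F_rec = alpha + (gamma - alpha) * sig
    e = math.exp(-k * P_el)
    V_A = VC_ * (1.0 - e) * F_rec + RV
    V_c = min(max(V_c, VC_CLAMP), V_c_max - VC_CLAMP)
    V_cw = max(V_A + V_c, RV + VCW_CLAMP)

    x = (V_cw - RV) / b_w
    P_cw = c_w + d_w * (x if x > 30.0 else math.log(math.expm1(x)))
    P_mus = A_mus * math.cos(TWO_PI * f * t) - A_mus
    P_pl = P_cw + P_mus
    P_tm = c_c - d_c * math.log(V_c_max / V_c - 1.0)
    R_s = R_s_d * math.exp(K_s * (V_A - RV) / (TLC - RV)) + R_s_m
    flow_A = (P_tm - P_el - P_ve) / R_s                   # L/s
    P_u = P_tm + P_pl + K_c * (V_c_max / V_c) ** 2 * flow
    m = mult if flow < 0.0 else 1.0
    R_u = m * (R_u_m + K_u * abs(flow))

    dF_rec = (gamma - alpha) * ez * sig * sig / d_F
    C_A = VC_ * k * e * F_rec + VC_ * (1.0 - e) * dF_rec  # ml/cm H2O

    return (
        (P_ao - P_u - R_u * flow) / I_u,       # dflow/dt, L/s^2
        1000.0 * (flow - flow_A),              # dV_c/dt, ml/s
        1000.0 * flow_A / C_A,                 # dP_el/dt, cm H2O/s
        (flow_A - P_ve / R_ve) / C_ve,         # dP_ve/dt, cm H2O/s
    )


try:  # optional JIT of the hot loop; bit-identical arithmetic either way
    from numba import njit as _njit

    _rhs_compiled = _njit(cache=False)(_rhs_flat)
except Exception:  # pragma: no cover - numba absent
    _rhs_compiled = _rhs_flat


def _pack(params: RespiratoryParameters, rec: RecruitmentState, A_mus: float,
          f: float, P_ao: float, expiratory_multiplier: float) -> tuple:
    return (params.TLC, params.RV, params.VC, params.k, params.b_w,
            params.c_w, params.d_w, params.c_c, params.d_c, params.V_c_max,
            params.K_c, params.R_s_m, params.R_s_d, params.K_s, params.I_u,
            params.R_u_m, params.K_u, params.R_ve, params.C_ve,
            rec.alpha, rec.gamma, rec.c_F, rec.d_F,
            A_mus, f, P_ao, expiratory_multiplier)


def rhs(t, y, params: RespiratoryParameters, rec: RecruitmentState,
        A_mus: float, f: float, P_ao: float = 0.0,
        expiratory_multiplier: float = 1.0) -> np.ndarray:
    """Time derivative of the state vector (public, solve_ivp signature)."""
    return np.array(_rhs_flat(
        np.asarray(y, dtype=float), float(t),
        _pack(params, rec, A_mus, f, P_ao, expiratory_multiplier)))


# --------------------------------------------------------------------------
# Breath integration and summary
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BreathTrace:
    """Dense output of one breath: times, states and derived signals."""

    t: np.ndarray               # s, within-breath time
    states: np.ndarray          # (n, 4): flow, V_c, P_el, P_ve
    derived: DerivedPressures

    @property
    def flow(self): return self.states[:, 0]
    @property
    def V_c(self): return self.states[:, 1]
    @property
    def P_el(self): return self.states[:, 2]
    @property
    def P_ve(self): return self.states[:, 3]


@dataclass(frozen=True)
class BreathSummary:
    """Per-breath derived metrics."""

    index: int
    V_T: float          # tidal volume EILV − EELV, ml
    EELV: float         # end-expiratory (minimum) lung volume, ml
    EILV: float         # end-inspiratory (maximum) lung volume, ml
    PIP: float          # peak lung elastic recoil over the breath, cm H2O
    F_rec_EI: float     # recruited fraction at end-inspiration
    C_L: float          # dynamic lung compliance, ml/cm H2O
    C_w_dyn: float      # dynamic chest-wall compliance, ml/cm H2O
    C_rs: float         # respiratory-system compliance (harmonic sum)
    f: float            # breath frequency, 1/s
    VE: float           # minute ventilation 60·f·V_T, ml/min
    R_rs_min: float     # min of R_u + R_c + R_s over the breath, cm H2O·s/L
    R_rs_max: float     # max of R_u + R_c + R_s over the breath
    P_ao: float         # airway-opening pressure held during the breath
    apneic: bool = False


def _summarize(trace: BreathTrace, rec: RecruitmentState,
               params: RespiratoryParameters, f: float, P_ao: float,
               expiratory_multiplier: float, index: int,
               apneic: bool = False) -> BreathSummary:
    d = trace.derived
    i_EI = int(np.argmax(d.V_A))
    i_EE = int(np.argmin(d.V_A))
    V_T = float(d.V_A[i_EI] - d.V_A[i_EE])

    dP_el = trace.P_el[i_EI] - trace.P_el[i_EE]
    dP_cw = d.P_cw[i_EI] - d.P_cw[i_EE]
    C_L = float((d.V_A[i_EI] - d.V_A[i_EE]) / dP_el) if dP_el != 0 else math.nan
    C_w = float((d.V_cw[i_EI] - d.V_cw[i_EE]) / dP_cw) if dP_cw != 0 else math.nan
    C_rs = (1.0 / (1.0 / C_L + 1.0 / C_w)
            if math.isfinite(C_L) and math.isfinite(C_w) else math.nan)

    R_u = law.upper_airway_resistance(trace.flow, params, expiratory_multiplier)
    R_c = law.collapsible_resistance(
        np.clip(trace.V_c, VC_CLAMP, None), params)
    R_s = law.small_airway_resistance(d.V_A, params)
    R_rs = R_u + R_c + R_s

    return BreathSummary(
        index=index, V_T=V_T, EELV=float(d.V_A[i_EE]), EILV=float(d.V_A[i_EI]),
        PIP=float(np.max(trace.P_el)),
        F_rec_EI=float(law.recruited_fraction(trace.P_el[i_EI], rec)),
        C_L=C_L, C_w_dyn=C_w, C_rs=C_rs, f=f, VE=60.0 * f * V_T,
        R_rs_min=float(np.min(R_rs)), R_rs_max=float(np.max(R_rs)),
        P_ao=P_ao, apneic=apneic)


def integrate_breath(state0: StateVector, params: RespiratoryParameters,
                     rec: RecruitmentState, A_mus: float, f: float,
                     P_ao: float = 0.0, expiratory_multiplier: float = 1.0,
                     rtol: float = 1e-6, atol: float = 1e-8,
                     points_per_breath: int = 201, index: int = 0,
                     apneic: bool = False,
                     ) -> tuple[BreathTrace, BreathSummary, StateVector]:
    """Integrate one breath over [0, 1/f] from ``state0``.

    Returns the dense trace, the per-breath summary and the end state
    (which seeds the next breath).
    """
    if f <= 0:
        raise ValueError("breathing frequency must be positive")
    t = np.linspace(0.0, 1.0 / f, points_per_breath)
    p = _pack(params, rec, A_mus, f, P_ao, expiratory_multiplier)
    y, info = odeint(_rhs_compiled, state0.as_array(), t, args=(p,),
                     rtol=rtol, atol=atol, full_output=True, mxstep=20_000)
    if info["message"] != "Integration successful.":
        raise BreathIntegrationError(
            f"breath {index}: {info['message']}", breath_index=index)

    derived = compute_derived(y, t, params, rec, A_mus, f, P_ao,
                              expiratory_multiplier)
    trace = BreathTrace(t=t, states=y, derived=derived)
    summary = _summarize(trace, rec, params, f, P_ao, expiratory_multiplier,
                         index, apneic)
    end = StateVector.from_array(y[-1])
    return trace, summary, end
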