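"""Static parameterization: the resting equilibrium (FRC), initial
conditions, dynamic-compliance metrics and driving-amplitude calibration.

Functional residual capacity is the volume at which the respiratory system
is in static balance.  At rest (no flow, no muscle pressure, relaxed
viscoelastic element) the circuit algebra reduces to ``P_tm = P_el`` and
``P_pl = P_cw = −P_el``, so the equilibrium condition is volume
conservation across the chest wall::

    V_cw(−P_el) = V_A(P_el) + V_c(P_el)

This is exactly the fixed point of the ODE system.  FRC is reported as the
alveolar volume at the root (the conventional "lung volume at rest"); the
corresponding chest-wall volume additionally contains the collapsible-
airway (dead-space) volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import constitutive as law
from .engine import BreathTrace, StateVector, integrate_breath
from .params import RecruitmentState, RespiratoryParameters

__all__ = ["EquilibriumResult", "compute_frc", "initial_conditions",
           "dynamic_compliances", "steady_state", "calibrate_amus",
           "ParameterizationError", "CalibrationError"]

# Physiological recoil-pressure search interval [cm H2O]
P_EL_RANGE = (1e-6, 40.0)


class ParameterizationError(RuntimeError):
    """No static equilibrium on the physiological pressure interval."""


class CalibrationError(RuntimeError):
    """Amplitude calibration failed to bracket the target ventilation."""


@dataclass(frozen=True)
class EquilibriumResult:
    """Static resting point of the respiratory system."""

    FRC: float                  # alveolar volume at rest, ml
    P_el_at_FRC: float          # lung recoil pressure at rest, cm H2O
    P_cw_at_FRC: float          # chest recoil at rest (= −P_el), cm H2O
    V_c_at_FRC: float           # collapsible-airway volume at rest, ml
    V_cw_at_FRC: float          # chest-wall volume at rest, ml
    residual: float             # |P_el + P_cw| at the reported root


def compute_frc(params: RespiratoryParameters,
                rec: RecruitmentState | None = None,
                include_collapsible: bool = True,
                xtol: float = 1e-10) -> EquilibriumResult:
    """Locate the resting equilibrium by root finding in recoil pressure.

    Solves ``V_cw(−P_el) − V_A(P_el) − V_c(P_el) = 0`` for ``P_el`` on the
    physiological interval with Brent's method (residual refined far below
    1e−6 cm H2O).  ``include_collapsible=False`` drops the ``V_c`` term,
    giving the textbook two-curve (lung vs chest wall) construction; the
    full-circuit form is the default because it is the true fixed point of
    the dynamics.
    """
    rec = rec or RecruitmentState()

    def imbalance(P_el: float) -> float:
        V = law.lung_volume(P_el, params, rec)
        if include_collapsible:
            V += law.collapsible_volume(P_el, params)
        return law.chest_wall_volume(-P_el, params) - V

    lo, hi = P_EL_RANGE
    if imbalance(lo) * imbalance(hi) > 0:
        raise ParameterizationError(
            "no static equilibrium for P_el in "
            f"[{lo}, {hi}] cm H2O — check the compliance parameters")
    P_el = brentq(imbalance, lo, hi, xtol=xtol)
    V_A = float(law.lung_volume(P_el, params, rec))
    V_c = float(law.collapsible_volume(P_el, params)) if include_collapsible else 0.0
    P_cw = float(law.chest_wall_pressure(V_A + V_c, params)) if include_collapsible \
        else float(law.chest_wall_pressure(V_A, params))
    return EquilibriumResult(FRC=V_A, P_el_at_FRC=float(P_el),
                             P_cw_at_FRC=P_cw, V_c_at_FRC=V_c,
                             V_cw_at_FRC=V_A + V_c,
                             residual=abs(P_el + P_cw))


def initial_conditions(eq: EquilibriumResult,
                       V_c0: float = 1e-4) -> StateVector:
    """Initial ODE state: no flow, relaxed viscoelastic element, lung at
    its resting recoil pressure, and a nearly collapsed conducting airway
    (V_c = 0.0001 ml) as prescribed for the published runs."""
    return StateVector(flow=0.0, V_c=V_c0, P_el=eq.P_el_at_FRC, P_ve=0.0)


# --------------------------------------------------------------------------
# Dynamic (breathing) metrics
# --------------------------------------------------------------------------

def dynamic_compliances(trace: BreathTrace) -> tuple[float, float, float]:
    """Dynamic lung, chest-wall and respiratory-system compliance from one
    breath of traces, ml/cm H2O.

    Secant slopes between the end-inspiratory (V_A maximum) and
    end-expiratory (V_A minimum) instants::

        C_L = ΔV_A/ΔP_el,  C_w = ΔV_cw/ΔP_cw,  C_rs = (1/C_L + 1/C_w)⁻¹
    """
    d = trace.derived
    i_EI = int(np.argmax(d.V_A))
    i_EE = int(np.argmin(d.V_A))
    dP_el = trace.P_el[i_EI] - trace.P_el[i_EE]
    dP_cw = d.P_cw[i_EI] - d.P_cw[i_EE]
    if dP_el == 0 or dP_cw == 0:
        raise ValueError("degenerate breath: zero pressure excursion")
    C_L = float((d.V_A[i_EI] - d.V_A[i_EE]) / dP_el)
    C_w = float((d.V_cw[i_EI] - d.V_cw[i_EE]) / dP_cw)
    return C_L, C_w, 1.0 / (1.0 / C_L + 1.0 / C_w)


def steady_state(params: RespiratoryParameters, rec: RecruitmentState,
                 A_mus: float, f: float = 1.0, P_ao: float = 0.0,
                 expiratory_multiplier: float = 1.0,
                 burn_in: int = 10, max_breaths: int = 40,
                 vt_rtol: float = 1e-3, **solver):
    """Breathe with fixed parameters until periodically steady.

    Integrates at least ``burn_in`` breaths (the prescribed V_c(0) =
    1e-4 ml transient distorts the first ones), then continues until
    successive tidal volumes agree to ``vt_rtol`` (0.1 %).  Returns
    ``(trace, summary)`` of the final, converged breath.
    """
    eq = compute_frc(params, rec)
    state = initial_conditions(eq)
    prev_VT = math.inf
    for i in range(max_breaths):
        trace, summary, state = integrate_breath(
            state, params, rec, A_mus, f, P_ao, expiratory_multiplier,
            index=i, **solver)
        if i + 1 >= burn_in and abs(summary.V_T - prev_VT) <= vt_rtol * max(
                summary.V_T, 1e-12):
            return trace, summary
        prev_VT = summary.V_T
    return trace, summary


def calibrate_amus(params: RespiratoryParameters, rec: RecruitmentState,
                   target_VE: float, f: float = 1.0,
                   expiratory_multiplier: float = 1.0,
                   bracket: tuple[float, float] = (0.1, 20.0),
                   tol_VE: float = 0.5, max_iter: int = 60) -> float:
    """Driving amplitude A_mus [cm H2O] whose steady-state minute
    ventilation matches ``target_VE`` [ml/min], by bisection.

    Minute ventilation increases monotonically with the driving amplitude,
    so plain bisection on the steady-state simulation (no analytic
    shortcut: V_T depends on every nonlinearity) converges to the 0.5
    ml/min tolerance.
    """
    def ve(A: float) -> float:
        _, s = steady_state(params, rec, A, f,
                            expiratory_multiplier=expiratory_multiplier)
        return s.VE

    lo, hi = bracket
    if target_VE <= 0:
        return lo
    ve_lo, ve_hi = ve(lo), ve(hi)
    if not (ve_lo <= target_VE <= ve_hi):
        raise CalibrationError(
            f"target VE={target_VE} not bracketed by amplitudes {bracket} "
            f"(VE range [{ve_lo:.1f}, {ve_hi:.1f}] ml/min)")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        v = ve(mid)
        if abs(v - target_VE) <= tol_VE:
            return mid
        if v < target_VE:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
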