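"""Constitutive pressure-volume and pressure-flow laws of the airways,
lung and chest wall.

Every function here is pure and accepts scalars or numpy arrays.  The three
resistance laws (Rohrer upper airway, Poiseuille collapsible segment,
exponential small airways) and the three compliance curves (collapsible
sigmoid, chest-wall softplus, lung distension × recruitment) together
define the nonlinear mechanics; the ODE engine composes them.
"""

from __future__ import annotations

import numpy as np

from .params import RecruitmentState, RespiratoryParameters

__all__ = [
    "upper_airway_resistance", "collapsible_resistance",
    "small_airway_resistance", "collapsible_volume", "collapsible_pressure",
    "chest_wall_volume", "chest_wall_pressure", "recruited_fraction",
    "recruited_fraction_slope", "lung_volume", "alveolar_compliance",
]

# Guard margins used when inverting the sigmoid / softplus curves inside
# the ODE right-hand side (the initial V_c = 1e-4 ml sits near the lower
# asymptote of the collapsible sigmoid).
VC_CLAMP = 1e-6       # ml
VCW_CLAMP = 1e-9      # ml


# --------------------------------------------------------------------------
# Resistances
# --------------------------------------------------------------------------

def upper_airway_resistance(flow, params: RespiratoryParameters,
                            expiratory_multiplier: float = 1.0):
    """Rohrer resistance of the upper rigid airway, cm H2O·s/L.

    ``R_u = m·(R_u_m + K_u·|flow|)`` with the laminar term ``R_u_m`` and
    turbulent term ``K_u·|flow|``.  The multiplier ``m`` models laryngeal
    braking (grunting) and applies only while flow is expiratory
    (negative); it must be ≥ 1.
    """
    if expiratory_multiplier < 1.0:
        raise ValueError("expiratory multiplier must be >= 1")
    flow = np.asarray(flow, dtype=float)
    if not np.all(np.isfinite(flow)):
        raise ValueError("non-finite flow")
    base = params.R_u_m + params.K_u * np.abs(flow)
    out = np.where(flow < 0, expiratory_multiplier * base, base)
    return out[()] if out.ndim == 0 else out


def collapsible_resistance(V_c, params: RespiratoryParameters):
    """Poiseuille-type resistance of the collapsible segment, cm H2O·s/L.

    ``R_c = K_c·(V_c_max/V_c)²`` — for a constant-length cylinder the
    resistance scales as radius⁻⁴, i.e. volume⁻²; minimum ``K_c`` is
    attained at full distension ``V_c = V_c_max``.
    """
    V_c = np.asarray(V_c, dtype=float)
    if np.any(V_c <= 0):
        raise ValueError("collapsible volume must be positive")
    out = params.K_c * (params.V_c_max / V_c) ** 2
    return out[()] if out.ndim == 0 else out


def small_airway_resistance(V_A, params: RespiratoryParameters):
    """Small peripheral airway resistance, cm H2O·s/L.

    Decaying exponential of relative lung inflation with a finite value
    ``R_s_d + R_s_m`` at residual volume and ≈ ``R_s_m`` at TLC::

        R_s = R_s_d · exp(K_s·(V_A − RV)/(TLC − RV)) + R_s_m,  K_s < 0
    """
    V_A = np.asarray(V_A, dtype=float)
    rel = (V_A - params.RV) / (params.TLC - params.RV)
    out = params.R_s_d * np.exp(params.K_s * rel) + params.R_s_m
    return out[()] if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Collapsible airway sigmoid
# --------------------------------------------------------------------------

def collapsible_volume(P_tm, params: RespiratoryParameters):
    """Collapsible-airway volume from transmural pressure, ml.

    Sigmoid ``V_c = V_c_max / (1 + exp(−(P_tm − c_c)/d_c))`` with maximal
    compliance at its midpoint ``P_tm = c_c``.
    """
    P_tm = np.asarray(P_tm, dtype=float)
    out = params.V_c_max / (1.0 + np.exp(-(P_tm - params.c_c) / params.d_c))
    return out[()] if out.ndim == 0 else out


def collapsible_pressure(V_c, params: RespiratoryParameters):
    """Inverse of :func:`collapsible_volume`: transmural pressure, cm H2O.

    Defined for ``0 < V_c < V_c_max`` strictly; callers integrating the
    ODE must clamp first.
    """
    V_c = np.asarray(V_c, dtype=float)
    if np.any(V_c <= 0) or np.any(V_c >= params.V_c_max):
        raise ValueError("V_c outside (0, V_c_max): clamp before inverting")
    out = params.c_c - params.d_c * np.log(params.V_c_max / V_c - 1.0)
    return out[()] if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Chest wall softplus
# --------------------------------------------------------------------------

def chest_wall_volume(P_cw, params: RespiratoryParameters):
    """Chest-wall volume from its recoil pressure, ml.

    Softplus curve ``V_cw = RV + b_w·ln(1 + exp((P_cw − c_w)/d_w))``:
    volume tends to RV for large negative recoil (the floppy infant chest
    offers no outward recoil) and grows with slope ``b_w/d_w`` for large
    positive recoil.  The transition point ``c_w`` defaults to 0.
    """
    P_cw = np.asarray(P_cw, dtype=float)
    x = (P_cw - params.c_w) / params.d_w
    # log1p(exp(x)) computed stably on both tails
    soft = np.where(x > 30, x, np.log1p(np.exp(np.minimum(x, 30.0))))
    out = params.RV + params.b_w * soft
    return out[()] if out.ndim == 0 else out


def chest_wall_pressure(V_cw, params: RespiratoryParameters):
    """Inverse of :func:`chest_wall_volume`: recoil pressure, cm H2O.

    Requires ``V_cw > RV`` strictly.
    """
    V_cw = np.asarray(V_cw, dtype=float)
    if np.any(V_cw <= params.RV):
        raise ValueError("V_cw must exceed RV to invert the softplus")
    x = (V_cw - params.RV) / params.b_w
    # inverse softplus: ln(e^x − 1), stable for large x where it -> x
    inv = np.where(x > 30, x, np.log(np.expm1(np.minimum(x, 30.0))))
    out = params.c_w + params.d_w * inv
    return out[()] if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Alveolar recruitment and lung volume
# --------------------------------------------------------------------------

def recruited_fraction(P_el, rec: RecruitmentState):
    """Fraction of alveoli recruited at recoil pressure ``P_el``.

    Sigmoid ``F_rec = α + (γ − α)/(1 + exp(−(P_el − c_F)/d_F))`` whose
    lower asymptote α is pinned so that ``F_rec(0) = β``; supremum γ.
    """
    P_el = np.asarray(P_el, dtype=float)
    out = rec.alpha + (rec.gamma - rec.alpha) / (
        1.0 + np.exp(-(P_el - rec.c_F) / rec.d_F))
    return out[()] if out.ndim == 0 else out


def recruited_fraction_slope(P_el, rec: RecruitmentState):
    """d F_rec / d P_el, 1/cm H2O."""
    P_el = np.asarray(P_el, dtype=float)
    ez = np.exp(-(P_el - rec.c_F) / rec.d_F)
    out = (rec.gamma - rec.alpha) * ez / (rec.d_F * (1.0 + ez) ** 2)
    return out[()] if out.ndim == 0 else out


def lung_volume(P_el, params: RespiratoryParameters, rec: RecruitmentState):
    """Alveolar (lung) volume from elastic recoil pressure, ml.

    Product of the distension of open units and the recruited fraction,
    offset by residual volume::

        V_A = VC·(1 − exp(−k·P_el)) · F_rec(P_el) + RV

    so that ``V_A(0) = RV`` exactly and ``V_A → TLC`` as ``P_el → ∞``
    when γ = 1.
    """
    P_el = np.asarray(P_el, dtype=float)
    V_el = params.VC * (1.0 - np.exp(-params.k * P_el))
    out = V_el * recruited_fraction(P_el, rec) + params.RV
    return out[()] if out.ndim == 0 else out


def alveolar_compliance(P_el, params: RespiratoryParameters,
                        rec: RecruitmentState):
    """Alveolar compliance C_A = dV_A/dP_el, ml/cm H2O (closed form)."""
    P_el = np.asarray(P_el, dtype=float)
    e = np.exp(-params.k * P_el)
    out = (params.VC * params.k * e * recruited_fraction(P_el, rec)
           + params.VC * (1.0 - e) * recruited_fraction_slope(P_el, rec))
    return out[()] if out.ndim == 0 else out
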