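"""Parameter containers for the preterm-infant respiratory mechanics model.

Two kinds of state are distinguished:

* :class:`RespiratoryParameters` — mechanical constants of the airways,
  lung tissue and chest wall that stay fixed for the duration of a
  simulation (resistances, inertance, compliance-curve shape constants,
  lung volumes, viscoelastic constants).
* :class:`RecruitmentState` — the parameters of the alveolar recruitment
  sigmoid, which drift from breath to breath as the lung derecruits.

Unit conventions used throughout the package: volumes in ml, pressures in
cm H2O, flows in L/s, resistances in cm H2O·s/L, inertance in cm H2O·s²/L,
compliances in ml/cm H2O except the viscoelastic compliance ``C_ve`` which
is kept in L/cm H2O as conventionally quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = ["RespiratoryParameters", "RecruitmentState", "alpha_from_constraint"]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class RespiratoryParameters:
    """Fixed mechanical constants of the respiratory system.

    Defaults describe a spontaneously breathing ~1 kg extremely preterm
    infant.  The chest-wall slope parameter ``d_w`` and the upper-airway
    resistance pair ``(R_u_m, K_u)`` are the quantities varied between
    simulated conditions; everything else is held fixed.
    """

    # Lung volumes [ml]
    TLC: float = 63.0
    RV: float = 23.0

    # Chest wall (softplus pressure-volume curve)
    nu: float = 0.25          # documented fraction of VC for relaxation volume
    V0: float = 35.0          # chest-wall relaxation volume at P_cw = 0 [ml]
    c_w: float = 0.0          # transition point [cm H2O]
    d_w: float = 0.48         # slope parameter [cm H2O]; 0.48 high C_w, 2.4 low

    # Lung tissue elasticity
    k: float = 0.07           # [1/cm H2O]

    # Collapsible airway (sigmoid pressure-volume curve and resistance)
    c_c: float = 4.4          # [cm H2O]
    d_c: float = 4.4          # [cm H2O]
    V_c_max: float = 2.5      # [ml], estimate of dead space
    K_c: float = 0.1          # [cm H2O·s/L]

    # Small peripheral airways
    R_s_m: float = 12.0       # minimum resistance [cm H2O·s/L]
    R_s_d: float = 20.0       # resistance excursion [cm H2O·s/L]
    K_s: float = -15.0        # dimensionless, < 0

    # Upper rigid airway
    I_u: float = 0.33         # inertance [cm H2O·s²/L]
    R_u_m: float = 20.0       # laminar resistance [cm H2O·s/L]
    K_u: float = 60.0         # turbulent coefficient [cm H2O·s/L]

    # Viscoelastic tissue (Kelvin-Voigt element)
    C_ve: float = 0.005       # [L/cm H2O]
    R_ve: float = 20.0        # [cm H2O·s/L]

    def __post_init__(self) -> None:
        if not self.TLC > self.RV > 0:
            raise ValueError("require TLC > RV > 0")
        for name in ("V_c_max", "d_c", "d_w", "K_c", "R_s_m", "R_s_d",
                     "I_u", "R_u_m", "K_u", "C_ve", "R_ve", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.K_s >= 0:
            raise ValueError("K_s must be negative")
        if not self.RV < self.V0 < self.TLC:
            raise ValueError("V0 must lie between RV and TLC")

    # Derived constants -------------------------------------------------
    @property
    def VC(self) -> float:
        """Vital capacity TLC − RV [ml]."""
        return self.TLC - self.RV

    @property
    def b_w(self) -> float:
        """Chest-wall slope scale (V0 − RV)/ln 2 [ml], pinned so that the
        softplus curve passes through the relaxation volume at P_cw = 0."""
        return (self.V0 - self.RV) / LN2

    # Glossary aliases --------------------------------------------------
    @property
    def a_w(self) -> float:
        """Chest-wall lower asymptote, identically RV [ml]."""
        return self.RV

    @property
    def a_c(self) -> float:
        """Collapsible-airway lower asymptote [ml]."""
        return 0.0

    @property
    def b_c(self) -> float:
        """Collapsible-airway upper asymptote, identically V_c_max [ml]."""
        return self.V_c_max

    def with_(self, **changes: float) -> "RespiratoryParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def alpha_from_constraint(beta: float, gamma: float,
                          c_F: float, d_F: float) -> float:
    """Lower asymptote of the recruitment sigmoid.

    Solves ``F_rec(0) = beta`` for alpha, i.e.::

        alpha + (gamma - alpha)/(1 + exp(c_F/d_F)) = beta

    giving ``alpha = ((1 + E)·beta − gamma)/E`` with ``E = exp(c_F/d_F)``.
    With the nominal recruitment parameters (beta=0.01, gamma=1,
    c_F=0.1, d_F=0.4) this evaluates to −0.76.
    """
    if d_F <= 0:
        raise ValueError("d_F must be positive")
    E = math.exp(c_F / d_F)
    return ((1.0 + E) * beta - gamma) / E


@dataclass(frozen=True)
class RecruitmentState:
    """Parameters of the recruited-fraction sigmoid F_rec(P_el).

    ``alpha`` is always derived from ``(beta, gamma, c_F, d_F)`` through
    the constraint that the recruited fraction at zero recoil pressure
    equals ``beta``; it is never set independently.
    """

    c_F: float = 0.1          # mean opening pressure [cm H2O]
    d_F: float = 0.4          # heterogeneity / slope [cm H2O]
    gamma: float = 1.0        # maximum recruitable fraction, in (0, 1]
    beta: float = 0.01        # baseline recruited fraction at P_el = 0
    alpha: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.beta < self.gamma <= 1.0):
            raise ValueError("require 0 < beta < gamma <= 1")
        if self.c_F <= 0 or self.d_F <= 0:
            raise ValueError("c_F and d_F must be positive")
        object.__setattr__(
            self, "alpha",
            alpha_from_constraint(self.beta, self.gamma, self.c_F, self.d_F))

    def evolved(self, *, c_F: float | None = None, d_F: float | None = None,
                gamma: float | None = None) -> "RecruitmentState":
        """New state with drifted curve parameters; alpha is recomputed."""
        return RecruitmentState(
            c_F=self.c_F if c_F is None else c_F,
            d_F=self.d_F if d_F is None else d_F,
            gamma=self.gamma if gamma is None else gamma,
            beta=self.beta,
        )
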