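"""Equilibrium and local-stability analysis under constant muscle pressure.

With the sinusoidal driver replaced by a constant (non-oscillatory) muscle
pressure the system has a fixed point; its local stability is read off the
eigenvalues of the Jacobian of the right-hand side there.  The sweep
re-runs the analysis with individual parameters scaled by set multiples
(2 and 10) to probe robustness of the stable spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .engine import StateVector, rhs
from .equilibrium import compute_frc, initial_conditions
from .params import RecruitmentState, RespiratoryParameters
from .scenarios import ScenarioConfig

__all__ = ["StabilityReport", "find_equilibrium", "jacobian",
           "eigenvalues_at", "stability_sweep", "SWEEP_PARAMETERS"]

#: Tunable mechanical constants included in the default sweep.
SWEEP_PARAMETERS = ("k", "d_w", "d_c", "K_c", "R_s_m", "R_s_d",
                    "I_u", "R_u_m", "K_u", "C_ve", "R_ve")


@dataclass(frozen=True)
class StabilityReport:
    """Equilibrium, spectrum and verdict for one parameter setting."""

    equilibrium: StateVector
    eigenvalues: np.ndarray                    # 4 complex values
    parameter_scaling: dict[str, float] = field(default_factory=dict)
    residual: float = 0.0                      # ||rhs|| at the equilibrium
    converged: bool = True

    @property
    def stable(self) -> bool:
        return self.converged and bool(np.all(self.eigenvalues.real < 0))


def _rhs_vec(y, params, rec, P_mus_const, P_ao):
    # constant driver: fold P_mus into the amplitude at t=T/2 phase by
    # using A_mus = -P_mus/2 and evaluating at the cosine trough
    A = -P_mus_const / 2.0
    f = 1.0
    return rhs(0.5, y, params, rec, A, f, P_ao=P_ao)


def find_equilibrium(params: RespiratoryParameters, rec: RecruitmentState,
                     constant_Pmus: float = 0.0, P_ao: float = 0.0,
                     tol: float = 1e-11) -> tuple[StateVector, float, bool]:
    """Fixed point of the dynamics under a constant muscle pressure ≤ 0.

    Starts a damped Newton (hybrid Powell) search from the static-FRC
    state with the collapsible airway at its pressure-consistent volume.
    Returns ``(state, residual_norm, converged)``.
    """
    if constant_Pmus > 0:
        raise ValueError("constant muscle pressure must be <= 0")
    eq = compute_frc(params, rec)
    x0 = initial_conditions(eq, V_c0=eq.V_c_at_FRC).as_array()
    sol = root(_rhs_vec, x0, args=(params, rec, constant_Pmus, P_ao),
               method="hybr", tol=tol)
    res = float(np.linalg.norm(_rhs_vec(sol.x, params, rec,
                                        constant_Pmus, P_ao)))
    return StateVector.from_array(sol.x), res, bool(sol.success and res < 1e-8)


def jacobian(y: np.ndarray, params: RespiratoryParameters,
             rec: RecruitmentState, constant_Pmus: float = 0.0,
             P_ao: float = 0.0, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the constant-driver RHS.

    Per-state steps ``max(rel_step, rel_step·|y_i|)`` accommodate states
    spanning several orders of magnitude (flow ~0.02 L/s vs V_c ~1 ml).
    """
    y = np.asarray(y, dtype=float)
    J = np.empty((4, 4))
    for j in range(4):
        h = max(rel_step, rel_step * abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (_rhs_vec(yp, params, rec, constant_Pmus, P_ao)
                   - _rhs_vec(ym, params, rec, constant_Pmus, P_ao)) / (2 * h)
    return J


def eigenvalues_at(params: RespiratoryParameters, rec: RecruitmentState,
                   constant_Pmus: float = 0.0, P_ao: float = 0.0,
                   scaling: dict[str, float] | None = None) -> StabilityReport:
    """Equilibrium + Jacobian spectrum for one parameter setting."""
    state, res, ok = find_equilibrium(params, rec, constant_Pmus, P_ao)
    lam = np.linalg.eigvals(
        jacobian(state.as_array(), params, rec, constant_Pmus, P_ao))
    return StabilityReport(equilibrium=state, eigenvalues=lam,
                           parameter_scaling=dict(scaling or {}),
                           residual=res, converged=ok)


def stability_sweep(scenario: ScenarioConfig,
                    multiples: tuple[float, ...] = (2.0, 10.0),
                    parameters: tuple[str, ...] = SWEEP_PARAMETERS,
                    constant_Pmus: float = 0.0) -> list[StabilityReport]:
    """Stability reports at nominal parameters and with each tunable
    parameter scaled by each multiple.  Per-case failures are recorded
    (``converged=False``) and the sweep continues."""
    rec = scenario.recruitment()
    base = scenario.parameters()
    reports = [eigenvalues_at(base, rec, constant_Pmus)]
    for name in parameters:
        for m in multiples:
            scaled = base.with_(**{name: getattr(base, name) * m})
            try:
                reports.append(eigenvalues_at(scaled, rec, constant_Pmus,
                                              scaling={name: m}))
            except Exception:  # pragma: no cover - diagnostic path
                reports.append(StabilityReport(
                    equilibrium=StateVector(math.nan, math.nan, math.nan,
                                            math.nan),
                    eigenvalues=np.full(4, np.nan, dtype=complex),
                    parameter_scaling={name: m}, residual=math.inf,
                    converged=False))
    return reports
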