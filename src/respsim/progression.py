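"""Breath-to-breath progression: recruitment-curve drift, interventions
and whole-simulation orchestration to failure.

The progressive volume-loss mechanism: alveoli that remain unrecruited at
end-inspiration impose a compensatory over-expansion on the open ones.  If
the aerated lung expands by a factor ``u`` over the breath, each open unit's
radius grows by ``u^⅓ − 1``; when a fraction ``F_closed`` of units is
closed, the same aggregate volume change must be carried by the rest, whose
radius increase — and hence required distending pressure — grows by the
factor returned by :func:`pressure_scale_factor`.  That factor multiplies
the mean opening pressure ``c_F`` and heterogeneity ``d_F`` of the
recruitment sigmoid each breath, shifting the compliance curve right;
optionally a fraction ``p`` of the closed units is lost permanently,
lowering the recruitable ceiling γ.  The feedback is self-accelerating:
a right-shifted curve recruits less at the same effort, closing more units
on the next breath, until tidal volume collapses ("failure", defined as a
90 % loss of the initial tidal volume).
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import BreathSummary, BreathTrace, StateVector, integrate_breath
from .equilibrium import compute_frc, initial_conditions
from .params import RecruitmentState, RespiratoryParameters
from .scenarios import ScenarioConfig

__all__ = ["gamma_update", "radius_expansion", "pressure_scale_factor",
           "update_recruitment", "next_frequency", "run_simulation",
           "SimulationResult"]

logger = logging.getLogger(__name__)


def gamma_update(gamma: float, F_rec_EI: float, p: float) -> float:
    """Maximum recruitable fraction for the next breath.

    ``γ_next = γ·(1 − p·F_closed)`` with ``F_closed = 1 − F_rec_EI/γ`` the
    fraction of recruitable units left closed at end-inspiration and ``p``
    the fraction of those lost permanently.  Limits: ``p = 0`` leaves γ
    unchanged; ``p = 1`` makes the end-inspiratory recruited fraction the
    new ceiling (γ_next = F_rec_EI).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("permanent fraction p must lie in [0, 1]")
    if not 0.0 < F_rec_EI <= gamma <= 1.0 + 1e-12:
        raise ValueError(
            f"inconsistent recruitment state: F_rec_EI={F_rec_EI}, gamma={gamma}")
    F_closed = 1.0 - F_rec_EI / gamma
    return gamma * (1.0 - p * F_closed)


def radius_expansion(u: float) -> float:
    """Fractional radius increase of a spherical unit whose volume grows by
    the factor ``u``: ``u^⅓ − 1`` (e.g. 26 % for a volume doubling)."""
    if u <= 1.0:
        raise ValueError("expansion ratio u must exceed 1")
    return u ** (1.0 / 3.0) - 1.0


def pressure_scale_factor(u: float, F_closed: float,
                          mode: str = "fractional_increase") -> float:
    """Compensatory distending-pressure scale factor s ≥ 1.

    With a fraction ``F_closed`` of units closed, the open units must carry
    the whole tidal volume change, raising their per-unit expansion from
    ``u`` to ``u′ = 1 + (u − 1)/(1 − F_closed)``.  The required distending
    pressure scales with the radius increase:

    * ``mode="fractional_increase"`` (default): s = (u′^⅓ − 1)/(u^⅓ − 1),
      the ratio of fractional radius increases.  For the canonical
      three-unit example (volumes double, one unit closes: u = 2,
      F_closed = ⅓) the radius increase grows from ≈ 25 % to ≈ 35 % and
      s ≈ 1.37.
    * ``mode="radius_ratio"``: s = (u′/u)^⅓, the ratio of end-expansion
      radii — a gentler reading retained for comparison.

    Both give s = 1 when nothing is closed and increase strictly with
    ``F_closed``.
    """
    if not 0.0 <= F_closed < 1.0:
        raise ValueError("F_closed must lie in [0, 1)")
    rho0 = radius_expansion(u)          # validates u > 1
    u_comp = 1.0 + (u - 1.0) / (1.0 - F_closed)
    if mode == "fractional_increase":
        return radius_expansion(u_comp) / rho0
    if mode == "radius_ratio":
        return (u_comp / u) ** (1.0 / 3.0)
    raise ValueError(f"unknown pressure-scale mode {mode!r}")


def update_recruitment(rec: RecruitmentState, breath: BreathSummary,
                       params: RespiratoryParameters, p: float = 0.0,
                       mode: str = "fractional_increase") -> RecruitmentState:
    """Recruitment curve for the breath after ``breath``.

    The tidal expansion ratio of the aerated lung,
    ``u = (EILV − RV)/(EELV − RV)``, and the closed fraction set the
    compensatory pressure factor ``s``; then ``c_F ← s·c_F``,
    ``d_F ← s·d_F``, γ is updated for permanent closure and the lower
    asymptote α is re-derived.

    Two closed fractions appear deliberately: the pressure compensation
    uses the *absolute* unrecruited fraction ``1 − F_rec_EI`` (open units
    must make up the volume of every closed unit, permanently lost ones
    included), whereas the γ update uses the fraction relative to the
    current ceiling (so that p = 1 makes F_rec_EI the new γ).  With a
    fully recruitable lung (γ = 1) the two coincide; for p > 0 the
    absolute form is what makes permanent closure accelerate failure.
    """
    if breath.EELV <= params.RV:
        raise ValueError("degenerate breath: EELV at or below residual volume")
    F_rec_EI = breath.F_rec_EI
    if F_rec_EI > rec.gamma:
        if F_rec_EI > rec.gamma + 1e-9:
            raise ValueError(
                f"F_rec_EI={F_rec_EI} exceeds gamma={rec.gamma}")
        F_rec_EI = rec.gamma
    F_closed_abs = min(1.0 - F_rec_EI, 1.0 - 1e-12)
    u = (breath.EILV - params.RV) / (breath.EELV - params.RV)
    if u > 1.0 and F_closed_abs > 0.0:
        s = pressure_scale_factor(u, F_closed_abs, mode)
    else:
        s = 1.0
    return rec.evolved(c_F=s * rec.c_F, d_F=s * rec.d_F,
                       gamma=gamma_update(rec.gamma, F_rec_EI, p))


def next_frequency(vt_history: Sequence[float], target_VE: float,
                   window: int = 60, cap: float = 3.0,
                   min_VT: float = 0.01) -> float:
    """Breathing frequency [1/s] maintaining the target minute ventilation.

    ``f = target_VE / (60 · V_T,ave)`` with ``V_T,ave`` the moving average
    of up to the last ``window`` tidal volumes (shorter histories average
    what is available).  Capped at ``cap`` to avoid unphysical rates as
    V_T collapses near failure.
    """
    if len(vt_history) == 0:
        raise ValueError("need at least one completed breath")
    vt_ave = float(np.mean(np.asarray(vt_history, dtype=float)[-window:]))
    if vt_ave <= min_VT:
        return cap
    return min(target_VE / (60.0 * vt_ave), cap)


# --------------------------------------------------------------------------
# Whole-simulation driver
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Outcome of a breath-by-breath simulation."""

    config: ScenarioConfig
    breaths: pd.DataFrame               # one row per BreathSummary + t_end
    TTF_hours: Optional[float]          # time to failure, or None
    failure_breath: Optional[int]       # 1-based index, or None
    cpap_breath: Optional[int] = None   # breath after which CPAP switched on
    apnea_breaths: tuple[int, int] | None = None   # 1-based inclusive range
    warnings: list[str] = field(default_factory=list)
    traces: list[tuple[int, BreathTrace]] = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return self.TTF_hours is not None


def run_simulation(scenario: ScenarioConfig,
                   trace_stride: int = 0) -> SimulationResult:
    """Run a scenario breath by breath until failure (or ``max_breaths``).

    Per breath: integrate the ODE over one period, summarize, test the
    failure criterion (V_T fallen by ``failure_fraction`` from the nominal
    initial tidal volume), arm CPAP when the end-inspiratory recruited
    fraction first drops below the trigger, drift the recruitment curve,
    and choose the next frequency.  An apneic episode (A_mus = 0) is
    inserted as whole silent breaths covering the configured window; those
    breaths are excluded from the drift, the failure test and the
    moving-average frequency rule.  ``trace_stride`` > 0 retains the dense
    trace of every such breath (plus the last one).

    Entirely deterministic: identical configs give identical breath tables.
    """
    params = scenario.parameters()
    rec = scenario.recruitment()
    eq = compute_frc(params, rec)
    state = initial_conditions(eq)

    f = scenario.initial_frequency
    vt_threshold = (1.0 - scenario.failure_fraction) * scenario.initial_tidal_volume
    P_ao = 0.0
    cpap_armed = scenario.cpap_trigger_frec is not None
    cpap_breath: Optional[int] = None
    apnea_start, apnea_duration = scenario.apnea or (math.inf, 0.0)
    apnea_remaining = 0
    apnea_done = scenario.apnea is None
    apnea_range: list[int] = []

    rows: list[dict] = []
    traces: list[tuple[int, BreathTrace]] = []
    vt_history: list[float] = []
    t_elapsed = 0.0
    TTF = None
    failure_breath = None
    warnings: list[str] = []

    for i in range(1, scenario.max_breaths + 1):
        if not apnea_done and apnea_remaining == 0 and t_elapsed >= apnea_start:
            apnea_remaining = max(int(math.ceil(apnea_duration * f)), 1)
        apneic = apnea_remaining > 0

        trace, summary, state = integrate_breath(
            state, params, rec, 0.0 if apneic else scenario.amplitude, f,
            P_ao=P_ao, expiratory_multiplier=scenario.expiratory_multiplier,
            rtol=scenario.rtol, atol=scenario.atol,
            points_per_breath=scenario.points_per_breath,
            index=i, apneic=apneic)
        t_elapsed += 1.0 / f
        row = asdict(summary)
        row["t_end"] = t_elapsed
        row["gamma"] = rec.gamma
        row["c_F"] = rec.c_F
        row["d_F"] = rec.d_F
        rows.append(row)
        if trace_stride > 0 and (i % trace_stride == 0):
            traces.append((i, trace))
        if i % 100 == 0:
            logger.info("breath %d: V_T=%.3f ml, F_rec|EI=%.5f, f=%.3f /s",
                        i, summary.V_T, summary.F_rec_EI, f)

        if apneic:
            apnea_range.append(i)
            apnea_remaining -= 1
            if apnea_remaining == 0:
                apnea_done = True
            continue

        if summary.V_T <= vt_threshold:
            TTF = t_elapsed / 3600.0
            failure_breath = i
            break

        if cpap_armed and P_ao == 0.0 and \
                summary.F_rec_EI < scenario.cpap_trigger_frec:
            P_ao = scenario.cpap_pressure
            cpap_breath = i
            logger.info("CPAP %g cm H2O from breath %d (F_rec|EI=%.4f)",
                        P_ao, i + 1, summary.F_rec_EI)

        if scenario.progression:
            rec = update_recruitment(rec, summary, params,
                                     p=scenario.permanent_fraction)

        vt_history.append(summary.V_T)
        if scenario.frequency_mode == "variable":
            f = next_frequency(vt_history, scenario.target_VE,
                               cap=scenario.max_frequency)

    else:
        warnings.append(
            f"no failure within {scenario.max_breaths} breaths "
            f"({t_elapsed / 3600.0:.2f} h simulated)")
        logger.warning(warnings[-1])

    if trace_stride > 0 and traces and traces[-1][0] != len(rows):
        traces.append((len(rows), trace))

    return SimulationResult(
        config=scenario, breaths=pd.DataFrame(rows), TTF_hours=TTF,
        failure_breath=failure_breath, cpap_breath=cpap_breath,
        apnea_breaths=(apnea_range[0], apnea_range[-1]) if apnea_range else None,
        warnings=warnings, traces=traces)
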