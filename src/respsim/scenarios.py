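"""Scenario configuration and the registry of published simulation setups.

A :class:`ScenarioConfig` bundles everything a whole-simulation run needs:
the chest-wall condition, the driving amplitude, interventions (laryngeal
braking, CPAP, apnea), the permanent-closure fraction, the frequency mode
and the failure criterion.  The registry exposes the fourteen named
simulations (``S1`` … ``S14``) spanning {no intervention, expiratory
braking, CPAP at 10/5/3 % recruitment loss} × {low, high chest-wall
compliance} × {fully recruitable, 10 % permanent closure per breath}.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .params import RecruitmentState, RespiratoryParameters

__all__ = ["ScenarioConfig", "SCENARIO_REGISTRY", "load_scenario",
           "AMUS_TABLE", "DW_TABLE"]

# Chest-wall slope parameter by condition [cm H2O]
DW_TABLE = {"high": 0.48, "low": 2.4}

# Driving-pressure amplitude by (condition, braking) [cm H2O]; each value
# was tuned to give an initial minute ventilation of 360 ml/min.
AMUS_TABLE = {
    ("high", False): 1.85,
    ("high", True): 3.2,
    ("low", False): 2.78,
    ("low", True): 3.8,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete configuration of one breath-by-breath simulation."""

    name: str = "custom"
    cw_condition: str = "high"             # {"high", "low"} chest-wall compliance
    braking: bool = False                  # laryngeal braking (grunting)
    braking_multiplier: float = 10.0       # expiratory R_u multiplier
    cpap_trigger_frec: Optional[float] = None   # F_rec|EI threshold, e.g. 0.9
    cpap_pressure: float = 5.0             # airway-opening pressure step [cm H2O]
    permanent_fraction: float = 0.0        # p, fraction of closed alveoli lost
    frequency_mode: str = "constant"       # {"constant", "variable"}
    apnea: Optional[Tuple[float, float]] = None  # (start [s], duration [s])
    target_VE: float = 360.0               # minute ventilation target [ml/min]
    initial_frequency: float = 1.0         # breaths/s (RR 60)
    failure_fraction: float = 0.9          # failure at V_T down by this fraction
    A_mus: Optional[float] = None          # None -> AMUS_TABLE lookup
    progression: bool = True               # breath-to-breath curve drift
    max_breaths: int = 200_000
    max_frequency: float = 3.0             # cap for the variable-f rule [1/s]
    # Solver settings
    rtol: float = 1e-6
    atol: float = 1e-8
    points_per_breath: int = 201
    random_seed: int = 0                   # unused: the model is deterministic

    def __post_init__(self) -> None:
        if self.cw_condition not in DW_TABLE:
            raise ValueError(f"cw_condition must be one of {set(DW_TABLE)}, "
                             f"got {self.cw_condition!r}")
        if self.frequency_mode not in ("constant", "variable"):
            raise ValueError(f"unknown frequency_mode {self.frequency_mode!r}")
        if self.cpap_trigger_frec is not None and not (
                0.0 < self.cpap_trigger_frec < 1.0):
            raise ValueError("cpap_trigger_frec must lie in (0, 1)")
        if not 0.0 <= self.permanent_fraction <= 1.0:
            raise ValueError("permanent_fraction must lie in [0, 1]")
        if self.braking_multiplier < 1.0:
            raise ValueError("braking_multiplier must be >= 1")
        if not 0.0 < self.failure_fraction <= 1.0:
            raise ValueError("failure_fraction must lie in (0, 1]")
        if self.initial_frequency <= 0:
            raise ValueError("initial_frequency must be positive")

    # ------------------------------------------------------------------
    def parameters(self) -> RespiratoryParameters:
        """Resolved mechanical constants for this scenario."""
        return RespiratoryParameters(d_w=DW_TABLE[self.cw_condition])

    def recruitment(self) -> RecruitmentState:
        """Initial recruitment curve (fully recruitable lung)."""
        return RecruitmentState()

    @property
    def amplitude(self) -> float:
        """Driving-pressure amplitude [cm H2O], from the tuned table unless
        overridden."""
        if self.A_mus is not None:
            return self.A_mus
        return AMUS_TABLE[(self.cw_condition, self.braking)]

    @property
    def expiratory_multiplier(self) -> float:
        return self.braking_multiplier if self.braking else 1.0

    @property
    def initial_tidal_volume(self) -> float:
        """Nominal initial V_T [ml] implied by the target minute ventilation
        and the initial frequency; the failure threshold refers to it."""
        return self.target_VE / (60.0 * self.initial_frequency)

    def with_(self, **changes) -> "ScenarioConfig":
        return replace(self, **changes)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if d["apnea"] is not None:
            d["apnea"] = list(d["apnea"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        if d.get("apnea") is not None:
            d["apnea"] = tuple(d["apnea"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _entry(num: int, cw: str, *, braking: bool = False,
           cpap: Optional[float] = None, p: float = 0.0) -> ScenarioConfig:
    return ScenarioConfig(name=f"S{num}", cw_condition=cw, braking=braking,
                          cpap_trigger_frec=cpap, permanent_fraction=p)


#: The fourteen published simulations (constant-frequency form; use
#: ``with_(frequency_mode="variable")`` / ``with_(apnea=(120.0, 20.0))``
#: for the other two repetitions of each).
SCENARIO_REGISTRY: dict[str, ScenarioConfig] = {
    cfg.name: cfg for cfg in [
        _entry(1, "low"),
        _entry(2, "low", p=0.1),
        _entry(3, "high"),
        _entry(4, "high", p=0.1),
        _entry(5, "low", braking=True),
        _entry(6, "low", braking=True, p=0.1),
        _entry(7, "high", braking=True),
        _entry(8, "high", braking=True, p=0.1),
        _entry(9, "low", cpap=0.90),
        _entry(10, "low", cpap=0.90, p=0.1),
        _entry(11, "high", cpap=0.90),
        _entry(12, "high", cpap=0.90, p=0.1),
        _entry(13, "high", cpap=0.95),
        _entry(14, "high", cpap=0.97),
    ]
}


def load_scenario(name_or_path: str | Path) -> ScenarioConfig:
    """Resolve a scenario by registry name (``"S3"``) or YAML file path.

    A file may either define a scenario from scratch or override fields of
    a registry entry via a ``base`` key.
    """
    key = str(name_or_path)
    if key in SCENARIO_REGISTRY:
        return SCENARIO_REGISTRY[key]
    path = Path(name_or_path)
    if not path.exists():
        raise ValueError(
            f"unknown scenario {key!r}: not a registry name "
            f"({', '.join(SCENARIO_REGISTRY)}) and no such file")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    base = data.pop("base", None)
    if base is not None:
        if base not in SCENARIO_REGISTRY:
            raise ValueError(f"unknown base scenario {base!r}")
        merged = SCENARIO_REGISTRY[base].to_dict()
        merged.update(data)
        merged.setdefault("name", f"{base}+{path.stem}")
        return ScenarioConfig.from_dict(merged)
    data.setdefault("name", path.stem)
    return ScenarioConfig.from_dict(data)
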