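"""Output writers: breath tables, state traces, result summaries, figures.

All tabular output is plain CSV (header row, ``.`` decimal separator, no
locale dependence); scalar results and metadata go to JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import BreathTrace
from .progression import SimulationResult

__all__ = ["trace_frame", "write_outputs", "stability_report_dict"]

TRACE_COLUMNS = ["t", "flow", "V_c", "P_el", "P_ve", "V_A", "V_cw",
                 "P_A", "P_pl", "P_tm", "P_mus", "flow_A"]


def trace_frame(trace: BreathTrace, t_offset: float = 0.0,
                breath: int | None = None) -> pd.DataFrame:
    """One breath's dense trace as a tidy DataFrame."""
    d = trace.derived
    df = pd.DataFrame({
        "t": trace.t + t_offset, "flow": trace.flow, "V_c": trace.V_c,
        "P_el": trace.P_el, "P_ve": trace.P_ve, "V_A": d.V_A,
        "V_cw": d.V_cw, "P_A": d.P_A, "P_pl": d.P_pl, "P_tm": d.P_tm,
        "P_mus": d.P_mus, "flow_A": d.flow_A})
    if breath is not None:
        df.insert(0, "breath", breath)
    return df


def write_outputs(result: SimulationResult, out_dir: str | Path,
                  figures: bool = False) -> dict[str, Path]:
    """Write ``breaths.csv``, ``result.json`` and, if traces were retained,
    ``traces.csv`` (plus optional figures) to ``out_dir``.

    Returns a name → path map of everything written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    breaths_path = out / "breaths.csv"
    result.breaths.to_csv(breaths_path, index=False)
    written["breaths"] = breaths_path

    meta = {
        "scenario": result.config.to_dict(),
        "TTF_hours": result.TTF_hours,
        "failure_breath": result.failure_breath,
        "n_breaths": int(len(result.breaths)),
        "cpap_breath": result.cpap_breath,
        "apnea_breaths": list(result.apnea_breaths)
        if result.apnea_breaths else None,
        "warnings": result.warnings,
    }
    result_path = out / "result.json"
    result_path.write_text(json.dumps(meta, indent=2) + "\n")
    written["result"] = result_path

    if result.traces:
        frames = []
        durations = 1.0 / result.breaths["f"].to_numpy()
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        for idx, trace in result.traces:
            frames.append(trace_frame(trace, t_offset=starts[idx - 1],
                                      breath=idx))
        traces_path = out / "traces.csv"
        pd.concat(frames, ignore_index=True).to_csv(traces_path, index=False)
        written["traces"] = traces_path

    if figures:
        written.update(_write_figures(result, out))
    return written


def _write_figures(result: SimulationResult, out: Path) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: dict[str, Path] = {}
    br = result.breaths

    fig, ax1 = plt.subplots(figsize=(7, 4))
    hours = br["t_end"].to_numpy() / 3600.0
    ax1.plot(hours, br["EELV"], color="tab:blue", label="EELV")
    ax1.set_xlabel("time [h]")
    ax1.set_ylabel("EELV [ml]", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(hours, br["V_T"], color="tab:red", label="V_T")
    ax2.set_ylabel("V_T [ml]", color="tab:red")
    ax1.set_title(f"{result.config.name}: breath-to-breath volumes")
    fig.tight_layout()
    p = out / "volumes.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written["volumes_figure"] = p

    if result.traces:
        fig, ax = plt.subplots(figsize=(6, 4))
        for idx, trace in result.traces[:6]:
            ax.plot(trace.P_el, trace.derived.V_A, lw=0.8,
                    label=f"breath {idx}")
        ax.set_xlabel("P_el [cm H2O]")
        ax.set_ylabel("V_A [ml]")
        ax.set_title("tidal pressure-volume loops")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out / "pv_loops.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["pv_figure"] = p
    return written


def stability_report_dict(report) -> dict:
    """JSON-serializable view of a StabilityReport."""
    return {
        "equilibrium": asdict(report.equilibrium),
        "eigenvalues": [[lam.real, lam.imag] for lam in report.eigenvalues],
        "parameter_scaling": report.parameter_scaling,
        "residual": report.residual,
        "converged": report.converged,
        "stable": report.stable,
    }
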