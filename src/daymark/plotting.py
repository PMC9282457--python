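"""Patient time-series display: biomarkers, raw averages and sobriety.

One figure per patient with three stacked panels sharing the treatment-day
axis: wellbeing (raw subset average as points, smoothed index as a line),
motivation/self-confidence (same layout), and the sobriety index. Day
markers on the sobriety panel follow the monitoring convention: green
circle = no alcohol detected, red square = alcohol detected, black
diamond = all breathalyzer tests omitted.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .biomarker import BiomarkerSeries, raw_daily_value
from .data import DailyPanel

__all__ = ["plot_patient"]

_MARKERS = {
    "no_alcohol": dict(marker="o", color="tab:green", label="no alcohol detected"),
    "alcohol_detected": dict(marker="s", color="tab:red", label="alcohol detected"),
    "all_omitted": dict(marker="D", color="black", label="all tests omitted"),
}


def plot_patient(
    panel: DailyPanel,
    biomarkers: dict[str, BiomarkerSeries],
    sobriety: np.ndarray,
    out_path: str,
) -> str:
    """Render the three-panel clinical-course figure to ``out_path``.

    ``biomarkers`` must contain "WeBe-i" and "MotSC-i" series aligned to
    the panel; ``sobriety`` is the per-day sobriety index. Raises on an
    empty panel. Returns the output path.
    """
    if panel.n_days == 0:
        raise ValueError("cannot plot an empty panel")
    days = np.arange(panel.n_days)
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(10, 7))

    for ax, name in zip(axes[:2], ("WeBe-i", "MotSC-i")):
        series = biomarkers[name]
        raw = np.array(
            [
                raw_daily_value(panel.values.iloc[t], series.question_subset)
                for t in range(panel.n_days)
            ]
        )
        ax.plot(days, series.values, lw=1.5, label=name)
        ax.plot(days, raw, ".", ms=4, alpha=0.6, label=f"{name[:-2]} (daily average)")
        ax.set_ylim(-2, 102)
        ax.set_ylabel(name)
        ax.legend(loc="lower left", fontsize=8)

    ax = axes[2]
    ax.plot(days, sobriety, lw=1.5, color="tab:blue", label="sobriety index")
    for status, style in _MARKERS.items():
        sel = np.array([s == status for s in panel.status])
        if sel.any():
            y = np.where(np.isnan(sobriety[sel]), 0.0, sobriety[sel])
            ax.plot(days[sel], y, linestyle="none", ms=4, **style)
    ax.set_ylim(-2, 102)
    ax.set_ylabel("sobriety")
    ax.set_xlabel("treatment day")
    ax.set_xlim(0, panel.n_days - 1)
    ax.legend(loc="lower left", fontsize=8)

    fig.suptitle(f"patient {panel.patient_id}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
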