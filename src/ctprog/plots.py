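"""Plot helpers: Kaplan-Meier curves, time-dependent ROC, calibration.

Thin matplotlib wrappers over the evalstats results; every function writes a
PNG and returns the figure so callers can customize further.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from ctprog.evalstats import KMCurve  # noqa: E402


def _step_xy(curve: KMCurve, t_max: float):
    x = np.concatenate([[0.0], np.repeat(curve.times, 2), [t_max]])
    s = np.concatenate([[1.0], curve.survival])
    y = np.concatenate([[1.0], np.repeat(s[:-1], 2)[1:], [s[-1], s[-1]]])
    return x, y


def plot_km(curves: dict[str, KMCurve], out: str | Path, title: str = "Overall survival"):
    """Kaplan-Meier step curves, one per named group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    t_max = max((float(c.times[-1]) for c in curves.values() if len(c.times)), default=1.0)
    for name, curve in curves.items():
        ax.plot(*_step_xy(curve, t_max), label=f"{name} (n={curve.n})")
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return fig


def plot_time_dependent_roc(scores, times, events, horizon: float, out: str | Path):
    """Empirical ROC of cases (event by horizon) vs controls (surviving past it)."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    cases = (times <= horizon) & (events == 1)
    controls = times > horizon
    thresholds = np.concatenate([[np.inf], np.sort(scores)[::-1], [-np.inf]])
    tpr = [(scores[cases] > th).mean() if cases.any() else 0.0 for th in thresholds]
    fpr = [(scores[controls] > th).mean() if controls.any() else 0.0 for th in thresholds]
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC at {horizon:.0f} days")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return fig


def plot_calibration(bins: list[dict], out: str | Path, horizon: float):
    """Observed (KM) vs mean predicted survival per prediction bin."""
    pred = [b["mean_predicted"] for b in bins]
    obs = [b["km_observed"] for b in bins]
    lo = [b["ci"][0] for b in bins]
    hi = [b["ci"][1] for b in bins]
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.errorbar(pred, obs, yerr=[np.subtract(obs, lo), np.subtract(hi, obs)],
                fmt="o-", capsize=3)
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("mean predicted survival")
    ax.set_ylabel("observed (KM) survival")
    ax.set_title(f"Calibration at {horizon:.0f} days")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return fig
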