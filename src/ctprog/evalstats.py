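"""Survival evaluation suite.

Harrell's concordance index with a normal-approximation CI, IPCW (Uno-type)
cumulative/dynamic time-dependent AUC, the Kaplan-Meier product-limit estimator,
the two-group log-rank test with a Cox-based hazard ratio, median-cutoff risk
stratification (higher score = higher risk; a score exactly at the cutoff is
low-risk), a nomogram point-scale for a fitted Cox model, calibration curves, and
the deep-model versus size-based-progression stratifier comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ctprog.clinical import ConvergenceError, CoxFit, fit_cox


def _validate(scores_or_none, times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if scores_or_none is None:
        return times, events
    scores = np.asarray(scores_or_none, dtype=float)
    if not (len(scores) == len(times) == len(events)):
        raise ValueError("length mismatch")
    return scores, times, events


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def harrell_c(scores, times, events) -> tuple[float, float, tuple[float, float]]:
    """Harrell's C over comparable pairs (higher score = higher risk).

    A pair (i, j) with t_i < t_j and an event for i is concordant when
    s_i > s_j; tied scores earn half credit. Returns (c, se, (lo, hi)) with a
    Noether-type normal-approximation 95% CI.
    """
    scores, times, events = _validate(scores, times, events)
    if len(scores) < 2 or events.sum() == 0:
        raise ValueError("need >= 2 subjects and >= 1 event")
    ti = times[:, None]
    comparable = (ti < times[None, :]) & (events[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    si = scores[:, None]
    concordant = (comparable & (si > scores[None, :])).sum()
    tied = (comparable & (si == scores[None, :])).sum()
    c = (concordant + 0.5 * tied) / n_comp
    se = float(np.sqrt(c * (1 - c) / n_comp))
    ci = (max(0.0, c - 1.96 * se), min(1.0, c + 1.96 * se))
    return float(c), se, ci


# ---------------------------------------------------------------------------
# time-dependent AUC
# ---------------------------------------------------------------------------

def _censoring_km(times, events):
    """KM estimate of the censoring survival G(t) (events flipped)."""
    curve = km_estimate(times, 1 - events)
    return curve


def time_dependent_auc(scores, times, events, horizon: float, *,
                       ipcw: bool = True) -> float:
    """Cumulative-cases / dynamic-controls AUC at ``horizon``.

    Cases are subjects with an event by the horizon, controls those still under
    observation past it. With ``ipcw`` (default) pairs are weighted by inverse
    probabilities of censoring from the KM estimate of the censoring
    distribution (Uno-type estimator, mirroring timeROC); without censoring the
    estimate reduces exactly to the Mann-Whitney statistic of the binary label
    t <= horizon.
    """
    scores, times, events = _validate(scores, times, events)
    if not (times.min() <= horizon <= times.max()):
        raise ValueError("horizon outside the observed time range")
    cases = (times <= horizon) & (events == 1)
    controls = times > horizon
    if cases.sum() == 0 or controls.sum() == 0:
        raise ValueError("need at least one case and one control at the horizon")
    if ipcw:
        G = _censoring_km(times, events)
        w_case = 1.0 / np.maximum(G.survival_at(times[cases], left_limit=True), 1e-12)
        w_ctrl = np.full(controls.sum(), 1.0 / max(G.survival_at(horizon), 1e-12))
    else:
        w_case = np.ones(cases.sum())
        w_ctrl = np.ones(controls.sum())
    sc = scores[cases][:, None]
    st = scores[controls][None, :]
    wmat = w_case[:, None] * w_ctrl[None, :]
    wins = ((sc > st) + 0.5 * (sc == st)) * wmat
    return float(wins.sum() / wmat.sum())


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate: right-continuous step function with S(0) = 1."""

    times: np.ndarray       # unique event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    var_factor: np.ndarray  # Greenwood cumulative sum at each step
    n: int

    def survival_at(self, t, left_limit: bool = False):
        t = np.asarray(t, dtype=float)
        side = "left" if left_limit else "right"
        idx = np.searchsorted(self.times, t, side=side) - 1
        s = np.concatenate([[1.0], self.survival])
        return s[idx + 1] if np.ndim(t) else float(s[idx + 1])

    @property
    def median(self) -> float | None:
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else None

    def ci_at(self, t) -> tuple[float, float]:
        """Greenwood 95% CI on the plain scale."""
        s = self.survival_at(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        vf = self.var_factor[idx] if idx >= 0 else 0.0
        se = s * np.sqrt(vf)
        return (max(0.0, s - 1.96 * se), min(1.0, s + 1.96 * se))


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``curve.median`` is the smallest observed time with S(t) <= 0.5, or None if
    the curve never reaches 0.5.
    """
    times, events = _validate(None, times, events)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    n = len(t)
    uniq = np.unique(t[e == 1])
    surv, var_acc = [], []
    s = 1.0
    acc = 0.0
    for ut in uniq:
        at_risk = np.sum(t >= ut)
        d = np.sum((t == ut) & (e == 1))
        s *= 1.0 - d / at_risk
        if at_risk > d:
            acc += d / (at_risk * (at_risk - d))
        surv.append(s)
        var_acc.append(acc)
    return KMCurve(times=uniq, survival=np.array(surv),
                   var_factor=np.array(var_acc), n=n)


# ---------------------------------------------------------------------------
# log-rank + hazard ratio
# ---------------------------------------------------------------------------

def logrank_and_hr(times, events, groups) -> tuple[float, float, tuple[float, float]]:
    """Two-group log-rank test and Cox hazard ratio (high vs low).

    ``groups`` may be any two-level labelling. The HR numerator group is the one
    labelled "high" when that label is present, otherwise the second level in
    sorted order. Returns (p, hr, (lo, hi)); the CI is the Wald interval on
    log(HR) from the univariate Cox fit on the group indicator.
    """
    times, events = _validate(None, times, events)
    groups = np.asarray(groups)
    levels = sorted(np.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if "high" in levels:
        indicator = (groups == "high").astype(float)
    else:
        indicator = (groups == levels[1]).astype(float)

    # log-rank: observed minus expected events in group 1, hypergeometric variance
    uniq = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for ut in uniq:
        at_risk = times >= ut
        n_t = at_risk.sum()
        n1 = indicator[at_risk].sum()
        d = ((times == ut) & (events == 1)).sum()
        d1 = ((times == ut) & (events == 1) & (indicator == 1)).sum()
        o_minus_e += d1 - d * n1 / n_t
        if n_t > 1:
            var += d * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d) / (n_t - 1)
    if var == 0:
        p = 1.0
    else:
        chi2 = o_minus_e**2 / var
        p = float(stats.chi2.sf(chi2, df=1))

    if np.all(indicator == indicator[0]):
        raise ValueError("one group is empty")
    try:
        fit = fit_cox(indicator.reshape(-1, 1), times, events, covariate_names=["group"])
        beta = fit.coefficients["group"]
        se = fit.se["group"]
        hr = float(np.exp(beta))
        with np.errstate(over="ignore"):
            ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    except ConvergenceError:
        # complete separation of the groups: the HR estimate diverges in the
        # direction of the observed excess of events
        hr = float("inf") if o_minus_e > 0 else 0.0
        ci = (0.0, float("inf"))
    return p, hr, ci


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def stratify(scores, cutoff: float) -> np.ndarray:
    """Label "high" iff score > cutoff (strict), else "low"."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores = np.asarray(scores, dtype=float)
    return np.where(scores > cutoff, "high", "low")


# ---------------------------------------------------------------------------
# nomogram
# ---------------------------------------------------------------------------

@dataclass
class Nomogram:
    """Point-scale view of a Cox model.

    Each covariate's observed contribution range beta_j * x_j maps to points;
    100 points equal the largest single-covariate contribution range. Total
    points relate affinely to the linear predictor, so survival read off the
    point scale equals the direct Cox prediction.
    """

    fit: CoxFit
    mins: dict[str, float]
    unit: float       # linear-predictor change per point
    lp_offset: float  # lp at zero total points
    horizons: list[float] = field(default_factory=list)

    def points(self, x: dict[str, float] | pd.Series) -> float:
        total = 0.0
        for c in self.fit.covariates:
            total += (self.fit.coefficients[c] * float(x[c]) - self.mins[c]) / self.unit
        return total

    def lp_from_points(self, total_points: float) -> float:
        return self.lp_offset + total_points * self.unit

    def survival_from_points(self, total_points: float, horizon: float) -> float:
        return float(self.fit.survival(horizon, self.lp_from_points(total_points)))

    def table(self) -> pd.DataFrame:
        rows = []
        for c in self.fit.covariates:
            beta = self.fit.coefficients[c]
            rows.append({"covariate": c, "coefficient": beta,
                         "points_per_unit": beta / self.unit,
                         "min_contribution": self.mins[c]})
        return pd.DataFrame(rows)


def nomogram(fit: CoxFit, horizons: list[float], X: pd.DataFrame) -> Nomogram:
    """Build the point scale from a fitted Cox model and observed covariate data."""
    if not fit.covariates:
        raise ValueError("fit has no covariates")
    for h in horizons:
        fit.cumhaz_at(h)  # raises beyond support
    contrib = {c: fit.coefficients[c] * X[c].to_numpy(dtype=float)
               for c in fit.covariates}
    ranges = {c: v.max() - v.min() for c, v in contrib.items()}
    max_range = max(ranges.values())
    if max_range <= 0:
        raise ValueError("all covariates constant; nomogram undefined")
    unit = max_range / 100.0
    mins = {c: float(v.min()) for c, v in contrib.items()}
    return Nomogram(fit=fit, mins=mins, unit=unit,
                    lp_offset=float(sum(mins.values())), horizons=list(horizons))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibration_curve(predicted_surv_probs, times, events, horizon: float,
                      n_bins: int = 3) -> list[dict]:
    """Observed (KM) vs mean predicted survival at ``horizon`` by prediction bin.

    Predictions are quantile-binned; empty bins trigger a warning-free reduction
    of the bin count. Each element reports mean predicted survival, the KM
    estimate at the horizon, and its Greenwood 95% CI.
    """
    p = np.asarray(predicted_surv_probs, dtype=float)
    times, events = _validate(None, times, events)
    if len(p) < n_bins * 5:
        raise ValueError("need at least 5 subjects per bin")
    bins = np.zeros(len(p), dtype=int)
    edges = np.array([p.min(), p.max()])
    while n_bins > 1:
        cand = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
        if len(cand) < 3:  # (near-)constant predictions: single bin
            break
        cand_bins = np.clip(np.searchsorted(cand, p, side="right") - 1,
                            0, len(cand) - 2)
        if all((cand_bins == b).sum() >= 2 for b in range(len(cand) - 1)):
            bins, edges = cand_bins, cand
            break
        n_bins -= 1
    out = []
    for b in range(max(1, len(edges) - 1)):
        sel = bins == b
        km = km_estimate(times[sel], events[sel])
        obs = km.survival_at(horizon)
        out.append({
            "mean_predicted": float(p[sel].mean()),
            "km_observed": float(obs),
            "ci": km.ci_at(horizon),
            "n": int(sel.sum()),
        })
    return out


# ---------------------------------------------------------------------------
# stratifier comparison
# ---------------------------------------------------------------------------

def compare_stratifiers(scores, cutoff: float, progression_labels, times,
                        events) -> dict[str, dict[str, float]]:
    """Risk stratification by the model score vs the size-based progression call.

    Runs the log-rank/HR analysis under each grouping of the same patients and
    reports both side by side (no between-HR significance test).
    """
    scores, times, events = _validate(scores, times, events)
    prog = np.asarray(progression_labels).astype(int)
    model_groups = stratify(scores, cutoff)
    size_groups = np.where(prog == 1, "high", "low")
    out = {}
    for name, groups in (("model", model_groups), ("size_based", size_groups)):
        p, hr, ci = logrank_and_hr(times, events, groups)
        out[name] = {"hr": hr, "p": p, "ci_low": ci[0], "ci_high": ci[1],
                     "n_high": int((groups == "high").sum())}
    return out


# ---------------------------------------------------------------------------
# bundled evaluation
# ---------------------------------------------------------------------------

@dataclass
class SurvEval:
    """Evaluation bundle for one score vector on one cohort split."""

    c_index: float
    c_index_ci: tuple[float, float]
    auc_t: dict[float, float]
    km_low: KMCurve | None
    km_high: KMCurve | None
    hr: float
    hr_ci: tuple[float, float]
    logrank_p: float
    cutoff: float
    group_labels: np.ndarray


def evaluate_scores(scores, times, events, horizons: list[float],
                    cutoff: float) -> SurvEval:
    """C-index, AUC(t) at each horizon, and cutoff-based stratification."""
    scores, times, events = _validate(scores, times, events)
    c, _, ci = harrell_c(scores, times, events)
    auc = {}
    for h in horizons:
        try:
            auc[h] = time_dependent_auc(scores, times, events, h)
        except ValueError:
            auc[h] = float("nan")
    labels = stratify(scores, cutoff)
    if len(np.unique(labels)) == 2:
        p, hr, hr_ci = logrank_and_hr(times, events, labels)
        km_low = km_estimate(times[labels == "low"], events[labels == "low"])
        km_high = km_estimate(times[labels == "high"], events[labels == "high"])
    else:
        p, hr, hr_ci = 1.0, float("nan"), (float("nan"), float("nan"))
        km_low = km_high = None
    return SurvEval(c_index=c, c_index_ci=ci, auc_t=auc, km_low=km_low,
                    km_high=km_high, hr=hr, hr_ci=hr_ci, logrank_p=p,
                    cutoff=cutoff, group_labels=labels)
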