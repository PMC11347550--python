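"""Clinical Cox scoring (CLN) and bivariate-Cox fusion (RadCLN-S / RadCLN-D).

The clinical model is a seven-covariate Cox proportional-hazards regression whose
linear predictor is the clinical risk score; the published coefficients of the
original cohort are shipped as :data:`PUBLISHED_CLINICAL_COEFFS` so the printed
formula

    Score = 0.3747*Differentiation + 0.1593*NASH|NAFLD - 0.1801*Surgery
            + 0.6732*PVTT - 0.8235*EBRT + 0.6482*TAE|TACE - 0.4497*RFA|MWA

is reproducible as arithmetic. Fusion combines a radiological and a clinical
score through a bivariate Cox model fitted on the training split only; the
published fusion coefficients (9.8834, 0.5300) are shipped likewise. Fitting is
Newton-Raphson on the Breslow partial likelihood.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ctprog.phantom import CLINICAL_COVARIATES, ClinicalRecord
from ctprog.survnet.model import RiskScore

#: Coefficients of the published clinical risk formula, ordinal differentiation first.
PUBLISHED_CLINICAL_COEFFS: dict[str, float] = {
    "differentiation": 0.3747,
    "nash_nafld": 0.1593,
    "surgery": -0.1801,
    "pvtt": 0.6732,
    "ebrt": -0.8235,
    "tae_tace": 0.6482,
    "rfa_mwa": -0.4497,
}

#: Coefficients of the published bivariate fusion formula.
PUBLISHED_FUSION_COEFFS: dict[str, float] = {
    "radiological": 9.8834,
    "clinical": 0.5300,
}


class ConvergenceError(RuntimeError):
    """Newton iterations failed to reach the gradient tolerance."""


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``baseline_cumhaz`` is the Breslow estimator as step points (times, values),
    non-decreasing with Lambda0(0) = 0; ``se`` holds per-coefficient standard
    errors from the inverse observed information (empty when the fit was supplied
    rather than estimated, e.g. the published coefficient sets).
    """

    coefficients: dict[str, float]
    baseline_cumhaz: tuple[np.ndarray, np.ndarray] = field(
        default_factory=lambda: (np.array([0.0]), np.array([0.0])))
    n: int = 0
    loglik: float = float("nan")
    se: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, beta in self.coefficients.items():
            if not np.isfinite(beta):
                raise ValueError(f"non-finite coefficient {name}")
        t, v = self.baseline_cumhaz
        if len(t) and (np.any(np.diff(v) < 0) or (len(v) and v[0] < 0)):
            raise ValueError("baseline cumulative hazard must be non-decreasing from 0")

    @property
    def covariates(self) -> list[str]:
        return list(self.coefficients)

    def linear_predictor(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.covariates].to_numpy(dtype=float)
        beta = np.array([self.coefficients[c] for c in self.covariates])
        return np.asarray(X, dtype=float) @ beta

    def cumhaz_at(self, t: float) -> float:
        times, vals = self.baseline_cumhaz
        idx = np.searchsorted(times, t, side="right") - 1
        if idx < 0:
            return 0.0
        if t > times[-1]:
            raise ValueError(f"horizon {t} beyond baseline-hazard support {times[-1]}")
        return float(vals[idx])

    def survival(self, t: float, lp: np.ndarray | float) -> np.ndarray:
        """S(t | x) = exp(-Lambda0(t))^exp(lp)."""
        return np.exp(-self.cumhaz_at(t) * np.exp(np.asarray(lp, dtype=float)))

    # -- JSON round trip -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        t, v = self.baseline_cumhaz
        payload = {
            "coefficients": self.coefficients,
            "baseline_cumhaz_times": t.tolist(),
            "baseline_cumhaz_values": v.tolist(),
            "n": self.n,
            "loglik": self.loglik,
            "se": self.se,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CoxFit":
        d = json.loads(Path(path).read_text())
        return cls(coefficients=d["coefficients"],
                   baseline_cumhaz=(np.asarray(d["baseline_cumhaz_times"]),
                                    np.asarray(d["baseline_cumhaz_values"])),
                   n=d["n"], loglik=d["loglik"], se=d.get("se", {}))


def published_clinical_fit() -> CoxFit:
    """The published seven-covariate clinical score as a CoxFit (coefficients only)."""
    return CoxFit(coefficients=dict(PUBLISHED_CLINICAL_COEFFS))


def published_fusion_fit() -> CoxFit:
    """The published bivariate fusion model as a CoxFit (coefficients only)."""
    return CoxFit(coefficients=dict(PUBLISHED_FUSION_COEFFS))


# ---------------------------------------------------------------------------
# Newton-Raphson Breslow Cox fitting
# ---------------------------------------------------------------------------

def _breslow_quantities(beta, X, times, events):
    """Log-likelihood, gradient and information of the Breslow partial likelihood."""
    order = np.argsort(times, kind="stable")
    Xo, to, eo = X[order], times[order], events[order]
    n, p = Xo.shape
    eta = Xo @ beta
    w = np.exp(eta - eta.max())
    # suffix sums over the risk set {j: t_j >= t_i}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xo)[::-1], axis=0)[::-1]
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = to[1:] != to[:-1]
    gid = np.cumsum(new_group) - 1
    gstart = np.flatnonzero(new_group)
    S0g = S0[gstart][gid]
    S1g = S1[gstart][gid]
    ev = eo.astype(bool)
    # S0g sums exp(eta - max), so each risk-set log-denominator is log(S0g) + max
    ll = float(np.sum(eta[ev] - (np.log(S0g[ev]) + eta.max())))
    xbar = S1g / S0g[:, None]
    grad = (Xo[ev] - xbar[ev]).sum(axis=0)
    # information: sum over events of S2/S0 - xbar xbar^T; S2 via suffix of w x x^T
    S2 = np.cumsum((w[:, None, None] * Xo[:, :, None] * Xo[:, None, :])[::-1], axis=0)[::-1]
    S2g = S2[gstart][gid]
    info = np.zeros((p, p))
    for i in np.flatnonzero(ev):
        info += S2g[i] / S0g[i] - np.outer(xbar[i], xbar[i])
    return ll, grad, info


def fit_cox(X: pd.DataFrame | np.ndarray, times, events, *,
            covariate_names: list[str] | None = None,
            max_iter: int = 100, tol: float = 1e-8,
            ridge: float = 0.0) -> CoxFit:
    """Maximum partial-likelihood Cox fit (Breslow ties, Newton-Raphson).

    Constant (zero-variance) covariates are dropped with a warning; failure to
    reach a gradient norm below ``tol`` in ``max_iter`` iterations (e.g. under
    separation) raises :class:`ConvergenceError`. A small ``ridge`` penalty
    (0.5 * ridge * ||beta||^2 subtracted from the log-likelihood) stabilizes
    fits on very small cohorts where a covariate may separate; the default is
    the unpenalized estimator.
    """
    if isinstance(X, pd.DataFrame):
        covariate_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and len(np.asarray(times)) != 1:
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    n, p = X.shape
    if covariate_names is None:
        covariate_names = [f"x{i}" for i in range(p)]
    if n < p + 1:
        raise ValueError("need n >= number of covariates + 1")
    if events.sum() == 0:
        raise ValueError("no events")

    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(covariate_names, keep) if not k]
        warnings.warn(f"dropping constant covariates: {dropped}")
        X = X[:, keep]
        covariate_names = [c for c, k in zip(covariate_names, keep) if k]
        if X.shape[1] == 0:
            raise ValueError("all covariates are constant; nothing to fit")

    beta = np.zeros(X.shape[1])
    ll = -np.inf
    converged = False

    def _quantities(b):
        ll_, g_, i_ = _breslow_quantities(b, X, times, events)
        if ridge > 0:
            ll_ -= 0.5 * ridge * float(b @ b)
            g_ = g_ - ridge * b
            i_ = i_ + ridge * np.eye(len(b))
        return ll_, g_, i_

    for _ in range(max_iter):
        ll_new, grad, info = _quantities(beta)
        if np.linalg.norm(grad) < tol:
            ll = ll_new
            converged = True
            break
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(len(beta)), grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        # step-halving to guarantee likelihood ascent
        for _half in range(30):
            cand = beta + step
            ll_cand, _, _ = _quantities(cand)
            if ll_cand >= ll_new - 1e-12:
                break
            step = step / 2
        beta = beta + step
        ll = ll_cand
        if np.abs(beta).max() > 30:
            raise ConvergenceError(
                "coefficient diverging (monotone likelihood / separation)")
    if not converged:
        _, grad, info = _quantities(beta)
        if np.linalg.norm(grad) >= np.sqrt(tol):
            raise ConvergenceError(
                f"Newton did not converge in {max_iter} iterations (|grad|={np.linalg.norm(grad):.3g})")
    ll, grad, info = _quantities(beta)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    if np.any(se > 100):
        raise ConvergenceError(
            "diverging standard error (monotone likelihood / separation)")

    # Breslow baseline cumulative hazard
    order = np.argsort(times, kind="stable")
    to, eo = times[order], events[order]
    w = np.exp(X[order] @ beta)
    S0 = np.cumsum(w[::-1])[::-1]
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = to[1:] != to[:-1]
    gid = np.cumsum(new_group) - 1
    gstart = np.flatnonzero(new_group)
    d_g = np.bincount(gid, weights=eo)
    t_g = to[gstart]
    increments = d_g / S0[gstart]
    mask = d_g > 0
    ch_times = np.concatenate([[0.0], t_g[mask]])
    ch_vals = np.concatenate([[0.0], np.cumsum(increments[mask])])

    return CoxFit(
        coefficients={c: float(b) for c, b in zip(covariate_names, beta)},
        baseline_cumhaz=(ch_times, ch_vals),
        n=n, loglik=float(ll),
        se={c: float(s) for c, s in zip(covariate_names, se)},
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def clinical_score(record: ClinicalRecord, fit: CoxFit) -> RiskScore:
    """Clinical linear predictor beta^T x (no intercept) for one patient."""
    missing = [c for c in fit.covariates if not hasattr(record, c)]
    if missing:
        raise ValueError(f"record lacks covariates {missing}")
    x = np.array([float(getattr(record, c)) for c in fit.covariates])
    beta = np.array([fit.coefficients[c] for c in fit.covariates])
    return RiskScore(patient_id=record.patient_id, score=float(beta @ x), variant="cln")


def clinical_scores(records: list[ClinicalRecord], fit: CoxFit) -> pd.DataFrame:
    rs = [clinical_score(r, fit) for r in records]
    return pd.DataFrame({"patient_id": [r.patient_id for r in rs],
                         "score": [r.score for r in rs], "variant": "cln"})


def fit_fusion(rad_scores: pd.DataFrame, clin_scores: pd.DataFrame,
               records: list[ClinicalRecord], *, ridge: float = 0.0) -> CoxFit:
    """Fit the bivariate (radiological, clinical) Cox fusion on a training split.

    A deep score that orders the training events perfectly makes the bivariate
    likelihood monotone; ``ridge`` > 0 keeps such fits finite on small cohorts.
    """
    merged = rad_scores.merge(clin_scores, on="patient_id", suffixes=("_rad", "_clin"))
    by_id = {r.patient_id: r for r in records}
    merged = merged[merged.patient_id.isin(by_id)]
    times = np.array([by_id[p].os_days for p in merged.patient_id])
    events = np.array([by_id[p].event for p in merged.patient_id])
    X = merged[["score_rad", "score_clin"]].to_numpy()
    return fit_cox(X, times, events, covariate_names=["radiological", "clinical"],
                   ridge=ridge)


def fuse(rad: RiskScore, clin: RiskScore, fusion_fit: CoxFit) -> RiskScore:
    """Combine one patient's radiological and clinical scores.

    score = beta_rad * rad + beta_clin * clin; the output variant is radcln_d or
    radcln_s according to the radiological input.
    """
    if rad.patient_id != clin.patient_id:
        raise ValueError("scores belong to different patients")
    if clin.variant != "cln":
        raise ValueError("clinical input must have variant 'cln'")
    if rad.variant not in ("rad_s", "rad_d"):
        raise ValueError("radiological input must have variant rad_s or rad_d")
    beta_r = fusion_fit.coefficients["radiological"]
    beta_c = fusion_fit.coefficients["clinical"]
    return RiskScore(patient_id=rad.patient_id,
                     score=float(beta_r * rad.score + beta_c * clin.score),
                     variant="radcln_d" if rad.variant == "rad_d" else "radcln_s")


def fuse_frames(rad_scores: pd.DataFrame, clin_scores: pd.DataFrame,
                fusion_fit: CoxFit) -> pd.DataFrame:
    """Vectorized :func:`fuse` over score tables sharing patient_id."""
    variants = set(rad_scores.variant)
    if len(variants) != 1:
        raise ValueError(f"mixed radiological variants: {sorted(variants)}")
    merged = rad_scores.merge(clin_scores, on="patient_id", suffixes=("_rad", "_clin"))
    score = (fusion_fit.coefficients["radiological"] * merged.score_rad
             + fusion_fit.coefficients["clinical"] * merged.score_clin)
    variant = "radcln_d" if variants == {"rad_d"} else "radcln_s"
    return pd.DataFrame({"patient_id": merged.patient_id, "score": score,
                         "variant": variant})
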