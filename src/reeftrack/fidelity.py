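"""Event-history site fidelity, residence times, and the daily-emigration model.

Site fidelity is the probability a tagged fish is still in the study area
after a horizon (a year, unless stated otherwise); residence times are the
survival-curve quantiles at S = 0.5, 0.4 and 0.01 (the last a population
replacement proxy). Emigration is the event; all other fates are
right-censored at the date they occur. Two estimators are provided — the
nonparametric product-limit (Kaplan–Meier) estimator and an intercept-only
right-censored Weibull — plus a binomial daily-emigration-probability GLM
with an atmospheric-pressure covariate, whose fitted regular/low-pressure
daily probabilities feed the closed-form projection

    S(t) = (1 − p_r)^(t − D_L) · (1 − p_l)^(D_L)

for a horizon of t days containing D_L low-pressure days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm

Z95 = float(norm.ppf(0.975))


# ---------------------------------------------------------------------------
# Event histories
# ---------------------------------------------------------------------------

def build_event_histories(fates: pd.DataFrame,
                          unknown_treatment: str = "censored",
                          recovery_days: int = 3,
                          gap_counts: pd.Series | None = None,
                          max_gaps: int = 1) -> pd.DataFrame:
    """One time-to-emigration row per eligible fish.

    Eligibility: the fish survived the tagging-recovery period (no CTR
    event) and had no more than ``max_gaps`` daily detection gaps (gap
    *count*, not length). ``unknown_treatment`` is either ``"censored"``
    or ``"emigrated"``; the latter counts unknown fates as events, probing
    sensitivity of fidelity estimates to fate uncertainty.
    """
    if unknown_treatment not in ("censored", "emigrated"):
        raise ValueError("unknown_treatment must be 'censored' or 'emigrated'")
    rows = []
    for _, r in fates.iterrows():
        if bool(r.get("ctr_flag", False)):
            continue
        time_days = float((pd.Timestamp(r["fate_date"]) - pd.Timestamp(r["tag_date"])).days)
        if time_days <= recovery_days:
            continue
        if gap_counts is not None and gap_counts.get(r["tag_id"], 0) > max_gaps:
            continue
        event = (r["fate"] == "emigrated"
                 or (r["fate"] == "unknown" and unknown_treatment == "emigrated"))
        rows.append({"tag_id": r["tag_id"], "time_days": time_days,
                     "event": bool(event), "fate_source": r["fate"],
                     "unknown_treatment": unknown_treatment})
    return pd.DataFrame(rows, columns=["tag_id", "time_days", "event",
                                       "fate_source", "unknown_treatment"])


# ---------------------------------------------------------------------------
# Survival curves
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurveResults:
    """A fitted survival curve with CIs and residence-time quantiles."""
    estimator: str
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_events: int
    n_subjects: int
    params: dict = field(default_factory=dict)
    param_cov: np.ndarray | None = None

    def survival_at(self, t: float) -> float:
        if self.estimator == "weibull":
            k, lam = self.params["shape"], self.params["scale"]
            return float(np.exp(-((t / lam) ** k)))
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        if self.estimator == "weibull":
            return _weibull_surv_ci(t, self.params, self.param_cov)
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        return float(self.ci_lower[idx]), float(self.ci_upper[idx])

    def quantile(self, q: float) -> float:
        """Residence time at survival level q (first crossing); NaN when the
        curve never reaches q (the analogue of a '-' table entry)."""
        if self.estimator == "weibull":
            k, lam = self.params["shape"], self.params["scale"]
            return float(lam * (-np.log(q)) ** (1.0 / k))
        below = np.nonzero(self.survival <= q)[0]
        return float(self.times[below[0]]) if len(below) else float("nan")

    def summary(self) -> str:
        s365 = self.survival_at(365.0)
        lo, hi = self.ci_at(365.0)
        lines = [f"Survival curve ({self.estimator}), {self.n_subjects} fish, "
                 f"{self.n_events} emigration events",
                 f"  annual site fidelity S(365) = {s365:.3f} ({lo:.3f}-{hi:.3f})"]
        for q, label in ((0.5, "50%"), (0.4, "40%"), (0.01, "1%")):
            t = self.quantile(q)
            lines.append(f"  {label} residence: " + ("-" if np.isnan(t) else f"{t:.0f} d"))
        if self.params:
            lines.append("  parameters: " +
                         ", ".join(f"{k}={v:.4g}" for k, v in self.params.items()))
        return "\n".join(lines)


class KaplanMeier:
    """Product-limit estimator for right-censored emigration times.

    S(t) = prod_{t_i <= t} (1 − d_i / n_i), variance by Greenwood's
    formula, CIs on the log(−log S) scale.
    """

    def __init__(self, histories: pd.DataFrame):
        self.histories = histories

    def fit(self, alpha: float = 0.05) -> SurvivalCurveResults:
        t = self.histories["time_days"].to_numpy(dtype=float)
        e = self.histories["event"].to_numpy(dtype=bool)
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        event_times = np.unique(t[e])
        n = len(t)
        surv, var_sum, times, ss, lo, hi = 1.0, 0.0, [], [], [], []
        z = float(norm.ppf(1 - alpha / 2))
        for ti in event_times:
            n_i = int((t >= ti).sum())
            d_i = int(((t == ti) & e).sum())
            surv *= 1.0 - d_i / n_i
            if n_i > d_i:
                var_sum += d_i / (n_i * (n_i - d_i))
            times.append(ti)
            ss.append(surv)
            if 0.0 < surv < 1.0:
                se_loglog = np.sqrt(var_sum) / abs(np.log(surv))
                lo.append(surv ** np.exp(z * se_loglog))
                hi.append(surv ** np.exp(-z * se_loglog))
            else:
                lo.append(surv)
                hi.append(surv)
        return SurvivalCurveResults(
            estimator="product_limit", times=np.asarray(times),
            survival=np.asarray(ss), ci_lower=np.asarray(lo),
            ci_upper=np.asarray(hi), n_events=int(e.sum()), n_subjects=n)


def product_limit(histories: pd.DataFrame) -> SurvivalCurveResults:
    return KaplanMeier(histories).fit()


def _weibull_surv_ci(t, params, cov):
    if cov is None:
        s = float(np.exp(-((t / params["scale"]) ** params["shape"])))
        return (s, s)
    k, lam = params["shape"], params["scale"]
    # parameters were optimized as (log k, log lam); delta method on
    # log cumulative hazard  log H = k (log t − log lam)
    logH = k * (np.log(t) - np.log(lam))
    grad = np.array([k * (np.log(t) - np.log(lam)), -k])  # d logH / d(log k, log lam)
    var = float(grad @ cov @ grad)
    se = np.sqrt(max(var, 0.0))
    H_lo, H_hi = np.exp(logH - Z95 * se), np.exp(logH + Z95 * se)
    return (float(np.exp(-H_hi)), float(np.exp(-H_lo)))


class WeibullSurvival:
    """Intercept-only right-censored Weibull model, S(t) = exp(−(t/λ)^k)."""

    def __init__(self, histories: pd.DataFrame):
        self.histories = histories

    def fit(self) -> SurvivalCurveResults:
        t = self.histories["time_days"].to_numpy(dtype=float)
        e = self.histories["event"].to_numpy(dtype=bool)
        if e.sum() < 2:
            raise ValueError("need at least 2 emigration events for a Weibull fit")
        t = np.maximum(t, 1e-8)

        def nll(theta):
            k, lam = np.exp(theta)
            z = (t / lam) ** k
            ll = (np.sum(np.log(k / lam) + (k - 1) * np.log(t[e] / lam) - z[e])
                  + np.sum(-z[~e]))
            return -ll

        x0 = np.array([0.0, np.log(np.median(t[e]) * 2.0)])
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000})
        if not res.success:
            raise RuntimeError(
                f"Weibull fit did not converge ({res.message}); check that the "
                "cohort has enough emigration events")
        k, lam = np.exp(res.x)
        cov = _numerical_hessian_inv(nll, res.x)
        grid = np.linspace(0.0, max(t.max() * 1.5, 365.0), 200)[1:]
        surv = np.exp(-((grid / lam) ** k))
        ci = np.array([_weibull_surv_ci(g, {"shape": k, "scale": lam}, cov)
                       for g in grid])
        return SurvivalCurveResults(
            estimator="weibull", times=grid, survival=surv,
            ci_lower=ci[:, 0], ci_upper=ci[:, 1],
            n_events=int(e.sum()), n_subjects=len(t),
            params={"shape": float(k), "scale": float(lam),
                    "loglik": -float(res.fun)},
            param_cov=cov)


def fit_weibull(histories: pd.DataFrame) -> SurvivalCurveResults:
    return WeibullSurvival(histories).fit()


def _numerical_hessian_inv(f, x, h=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------
# Pressure-day classification
# ---------------------------------------------------------------------------

def classify_pressure_days(environment: pd.DataFrame,
                           percentile: float = 0.5) -> pd.DataFrame:
    """Label each date low-pressure iff its (daily median) pressure falls
    strictly below the given percentile of all daily medians."""
    daily = (environment.groupby("date")["atm_pressure_mbar"].median()
             .rename("pressure").reset_index())
    threshold = float(np.percentile(daily["pressure"], percentile))
    daily["is_low"] = daily["pressure"] < threshold
    daily["threshold_mbar"] = threshold
    return daily


# ---------------------------------------------------------------------------
# Daily-emigration-probability GLM (binomial logit, hand-rolled IRLS)
# ---------------------------------------------------------------------------

@dataclass
class EmigrationGLMResults:
    params: np.ndarray
    cov: np.ndarray
    param_names: list
    loglik: float
    aic: float
    p_regular: float
    p_low: float
    p_regular_ci: tuple
    p_low_ci: tuple
    candidates: pd.DataFrame | None = None

    @property
    def ratio(self) -> float:
        """Fitted low:regular daily emigration probability ratio."""
        return self.p_low / self.p_regular

    def ratio_ci(self) -> tuple[float, float]:
        # delta method on log(p_l) − log(p_r); for small p this is the log
        # odds-ratio se corrected by the (1−p) factors
        g = np.array([(1 - self.p_low) - (1 - self.p_regular), (1 - self.p_low)])
        var = float(g @ self.cov @ g)
        lr = np.log(self.ratio)
        se = np.sqrt(max(var, 0.0))
        return (float(np.exp(lr - Z95 * se)), float(np.exp(lr + Z95 * se)))

    def summary(self) -> str:
        lo_r, hi_r = self.p_regular_ci
        lo_l, hi_l = self.p_low_ci
        out = ["Daily emigration probability (binomial logit GLM)",
               f"  regular-pressure days: p_r = {self.p_regular:.5f} "
               f"({lo_r:.5f}-{hi_r:.5f})",
               f"  low-pressure days:     p_l = {self.p_low:.5f} "
               f"({lo_l:.5f}-{hi_l:.5f})",
               f"  ratio p_l / p_r = {self.ratio:.1f}",
               f"  loglik = {self.loglik:.2f}, AIC = {self.aic:.2f}"]
        if self.candidates is not None:
            out.append("  covariate selection (AIC): " + ", ".join(
                f"{r.covariate}={r.aic:.1f}" for r in self.candidates.itertuples()))
        return "\n".join(out)


def _irls_binomial(X: np.ndarray, y: np.ndarray, n: np.ndarray,
                   max_iter: int = 100, tol: float = 1e-10):
    """Binomial-logit fit by iteratively reweighted least squares."""
    beta = np.zeros(X.shape[1])
    frac = np.clip((y + 0.5) / (n + 1.0), 1e-10, 1 - 1e-10)
    beta[:] = np.linalg.lstsq(X, logit(frac), rcond=None)[0]
    for _ in range(max_iter):
        eta = X @ beta
        p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        w = n * p * (1 - p)
        z = eta + (y - n * p) / np.maximum(w, 1e-12)
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    w = n * p * (1 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    from scipy.special import gammaln
    ll = float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
                      + y * np.log(p) + (n - y) * np.log1p(-p)))
    return beta, cov, ll


class EmigrationGLM:
    """E_i ~ Binom(n_i, p_i), logit(p_i) = β0 + β1·[low-pressure day].

    ``daily_counts`` needs ``n_at_risk``, ``emigrations`` and a boolean
    ``is_low`` column; optional continuous candidate covariates (e.g.
    temperature, tilt) can be screened by AIC via :meth:`select`.
    """

    def __init__(self, daily_counts: pd.DataFrame):
        self.daily = daily_counts.reset_index(drop=True)
        if self.daily["emigrations"].sum() == 0:
            raise ValueError("no emigration events: the GLM fit is degenerate")
        if (self.daily["emigrations"] > self.daily["n_at_risk"]).any():
            raise ValueError("emigrations exceed fish at risk on some day")

    def fit(self, candidates: dict[str, str] | None = None) -> EmigrationGLMResults:
        df = self.daily[self.daily["n_at_risk"] > 0]
        y = df["emigrations"].to_numpy(dtype=float)
        n = df["n_at_risk"].to_numpy(dtype=float)
        low = df["is_low"].to_numpy(dtype=float)
        if low.min() == low.max():
            raise ValueError("pressure covariate has no variation among days "
                             "with fish at risk; cannot separate p_l from p_r")
        X = np.column_stack([np.ones_like(low), low])
        beta, cov, ll = _irls_binomial(X, y, n)
        aic = 2 * 2 - 2 * ll

        cand_table = None
        if candidates:
            rows = [{"covariate": "atm_pressure(low)", "aic": aic, "loglik": ll}]
            for name, col in candidates.items():
                v = df[col].to_numpy(dtype=float)
                v = (v - v.mean()) / (v.std() or 1.0)
                Xc = np.column_stack([np.ones_like(v), v])
                try:
                    _, _, llc = _irls_binomial(Xc, y, n)
                    rows.append({"covariate": name, "aic": 4 - 2 * llc, "loglik": llc})
                except np.linalg.LinAlgError:
                    continue
            cand_table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)

        def marginal(is_low: float):
            xrow = np.array([1.0, is_low])
            eta = float(xrow @ beta)
            se = float(np.sqrt(max(xrow @ cov @ xrow, 0.0)))
            return (float(expit(eta)),
                    (float(expit(eta - Z95 * se)), float(expit(eta + Z95 * se))))

        p_r, ci_r = marginal(0.0)
        p_l, ci_l = marginal(1.0)
        return EmigrationGLMResults(
            params=beta, cov=cov, param_names=["intercept", "low_pressure"],
            loglik=ll, aic=aic, p_regular=p_r, p_low=p_l,
            p_regular_ci=ci_r, p_low_ci=ci_l, candidates=cand_table)


def fit_dep(daily_counts: pd.DataFrame,
            candidates: dict[str, str] | None = None) -> EmigrationGLMResults:
    return EmigrationGLM(daily_counts).fit(candidates=candidates)


# ---------------------------------------------------------------------------
# Fidelity projection
# ---------------------------------------------------------------------------

def project_fidelity(p_r: float, p_l: float, t: float, d_low: float) -> float:
    """Expected site fidelity S(t) = (1−p_r)^(t−D_L) · (1−p_l)^(D_L) after t
    days of which D_L are low-pressure days."""
    if not (0.0 < p_r < 1.0 and 0.0 < p_l < 1.0):
        raise ValueError("daily probabilities must lie in (0, 1)")
    if d_low < 0 or d_low > t:
        raise ValueError("D_L must satisfy 0 <= D_L <= t")
    return float((1.0 - p_r) ** (t - d_low) * (1.0 - p_l) ** d_low)
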