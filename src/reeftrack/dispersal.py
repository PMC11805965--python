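"""Per-fish maximum dispersal distances and censored dispersal-kernel fitting.

A fish's dispersal is the maximum distance between any two of its estimated
locations (4-h COAs plus recaptures and live glider detections outside the
array) over a tracking period of at least 100 days. Fish that left the
array and were never relocated carry only a within-array lower bound: their
distances are right-censored. Candidate kernels (Burr XII, Weibull,
lognormal, gamma, exponential) are fitted by censored maximum likelihood

    l = sum_uncensored log f(x) + sum_censored log S(x)

and ranked by AIC; the fitted survival function gives exceedance
probabilities P(X >= d) for distances of management interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

from ._util import haversine_m, max_pairwise_distance


# ---------------------------------------------------------------------------
# Maximum dispersal
# ---------------------------------------------------------------------------

def max_dispersal(locations: pd.DataFrame, fates: pd.DataFrame,
                  min_tracking_days: int = 100) -> pd.DataFrame:
    """One DispersalRecord per eligible fish.

    ``locations`` holds every estimated location (4-h COAs and relocations)
    with planar ``x_m``/``y_m`` and/or geographic ``lon``/``lat`` columns;
    when any of a fish's locations carries lon/lat, all pairwise distances
    involving it use the great-circle formula. ``fates`` supplies the fate
    used for the censoring flag: emigrated/unknown fish with no relocation
    outside the array are right-censored at their within-array maximum.
    """
    fate_by_tag = fates.set_index("tag_id")["fate"] if len(fates) else pd.Series(dtype=object)
    rows = []
    for tag, g in locations.groupby("tag_id"):
        g = g.sort_values("timestamp")
        span = (g["timestamp"].max() - g["timestamp"].min()).days
        if span < min_tracking_days:
            rows.append({"tag_id": tag, "max_distance_m": np.nan,
                         "censored": False, "tracking_days": span,
                         "included": False, "reason": "tracking < minimum"})
            continue
        if len(g) < 2:
            rows.append({"tag_id": tag, "max_distance_m": np.nan,
                         "censored": False, "tracking_days": span,
                         "included": False, "reason": "single location"})
            continue
        has_geo = "lon" in g and g["lon"].notna().any()
        if has_geo:
            d = _max_distance_mixed(g)
        else:
            d = max_pairwise_distance(g[["x_m", "y_m"]].to_numpy(dtype=float))
        fate = fate_by_tag.get(tag, "unknown")
        relocated_outside = ("source" in g
                             and g["source"].isin(["recapture", "glider"]).any())
        censored = fate in ("emigrated", "unknown") and not relocated_outside
        rows.append({"tag_id": tag, "max_distance_m": float(d),
                     "censored": bool(censored), "tracking_days": int(span),
                     "included": True, "reason": ""})
    return pd.DataFrame(rows, columns=["tag_id", "max_distance_m", "censored",
                                       "tracking_days", "included", "reason"])


def _max_distance_mixed(g: pd.DataFrame) -> float:
    """Max pairwise distance when some rows are geographic. Planar rows are
    compared planar among themselves; any pair touching a lon/lat row uses
    great-circle distance after projecting planar rows through the local
    reference (requires lon/lat for those rows too, else they are skipped)."""
    planar = g[g["lon"].isna() & g["x_m"].notna()] if "x_m" in g else g.iloc[0:0]
    geo = g[g["lon"].notna()]
    best = 0.0
    if len(planar) >= 2:
        best = max_pairwise_distance(planar[["x_m", "y_m"]].to_numpy(dtype=float))
    if len(geo) >= 2:
        lon = geo["lon"].to_numpy(dtype=float)
        lat = geo["lat"].to_numpy(dtype=float)
        dd = haversine_m(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
        best = max(best, float(dd.max()))
    if len(geo) and len(planar) and {"lon", "lat"} <= set(planar.columns) \
            and planar[["lon", "lat"]].notna().all(axis=None):
        lon1 = planar["lon"].to_numpy(float)[:, None]
        lat1 = planar["lat"].to_numpy(float)[:, None]
        lon2 = geo["lon"].to_numpy(float)[None, :]
        lat2 = geo["lat"].to_numpy(float)[None, :]
        best = max(best, float(haversine_m(lon1, lat1, lon2, lat2).max()))
    return best


# ---------------------------------------------------------------------------
# Kernel families
# ---------------------------------------------------------------------------

def _burr_logpdf(x, c, k, s):
    z = x / s
    return (np.log(c) + np.log(k) - np.log(s) + (c - 1) * np.log(z)
            - (k + 1) * np.log1p(z ** c))


def _burr_logsf(x, c, k, s):
    return -k * np.log1p((x / s) ** c)


@dataclass
class KernelFitResults:
    """A fitted dispersal kernel: parameters, censored loglik, AIC, S(x)."""
    family: str
    params: dict
    loglik: float
    n_params: int
    n_obs: int
    n_censored: int

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    def sf(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "burr":
            return np.exp(_burr_logsf(np.maximum(x, 0.0), p["c"], p["k"], p["scale"]))
        return _frozen(self.family, p).sf(x)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "burr":
            return np.exp(_burr_logpdf(np.maximum(x, 1e-300), p["c"], p["k"], p["scale"]))
        return _frozen(self.family, p).pdf(x)

    def exceedance(self, thresholds_m=(2000.0, 10_000.0, 200_000.0)) -> dict:
        """P(X >= d) for each threshold distance (meters)."""
        out = {}
        for d in thresholds_m:
            if d < 0:
                raise ValueError("threshold distance must be nonnegative")
            out[float(d)] = float(self.sf(d))
        return out

    def summary(self) -> str:
        pstr = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return (f"{self.family} dispersal kernel ({pstr})\n"
                f"  loglik = {self.loglik:.2f}, AIC = {self.aic:.2f} "
                f"({self.n_obs} fish, {self.n_censored} censored)")


def _frozen(family: str, p: dict):
    if family == "weibull":
        return stats.weibull_min(p["shape"], scale=p["scale"])
    if family == "lognormal":
        return stats.lognorm(p["sigma"], scale=np.exp(p["mu"]))
    if family == "gamma":
        return stats.gamma(p["shape"], scale=p["scale"])
    if family == "exponential":
        return stats.expon(scale=p["scale"])
    raise KeyError(family)


_FAMILY_NPARAMS = {"burr": 3, "weibull": 2, "lognormal": 2, "gamma": 2,
                   "exponential": 1}


def _nll_factory(family, x_unc, x_cen):
    if family == "burr":
        def nll(theta):
            c, k, s = np.exp(theta)
            ll = _burr_logpdf(x_unc, c, k, s).sum()
            if len(x_cen):
                ll += _burr_logsf(x_cen, c, k, s).sum()
            return -ll
        return nll

    def nll(theta):
        if family == "weibull":
            dist = stats.weibull_min(np.exp(theta[0]), scale=np.exp(theta[1]))
        elif family == "lognormal":
            dist = stats.lognorm(np.exp(theta[1]), scale=np.exp(theta[0]))
        elif family == "gamma":
            dist = stats.gamma(np.exp(theta[0]), scale=np.exp(theta[1]))
        else:  # exponential
            dist = stats.expon(scale=np.exp(theta[0]))
        ll = dist.logpdf(x_unc).sum()
        if len(x_cen):
            ll += dist.logsf(x_cen).sum()
        return -ll if np.isfinite(ll) else 1e12
    return nll


def _starts(family, x, rng):
    m, s = float(np.mean(np.log(x))), float(np.std(np.log(x)) + 1e-6)
    med = float(np.median(x))
    if family == "burr":
        base = [np.log(1.2), np.log(1.0), np.log(med)]
        yield np.array(base)
        for _ in range(5):
            yield np.array(base) + rng.normal(0, 0.7, 3)
    elif family == "weibull":
        yield np.array([0.0, np.log(med)])
        yield np.array([np.log(0.7), np.log(med * 1.5)])
    elif family == "lognormal":
        yield np.array([m, np.log(s)])
    elif family == "gamma":
        yield np.array([0.0, np.log(med)])
        yield np.array([np.log(0.5), np.log(med * 2)])
    else:
        yield np.array([np.log(np.mean(x))])


class DispersalKernel:
    """Censored maximum-likelihood dispersal-kernel fitting.

    Parameters: a DispersalRecord table (``max_distance_m``, ``censored``)
    with the non-included rows already filtered or flagged via ``included``.
    """

    FAMILIES = ("burr", "weibull", "lognormal", "gamma", "exponential")

    def __init__(self, records: pd.DataFrame, seed: int = 0):
        df = records
        if "included" in df:
            df = df[df["included"]]
        df = df.dropna(subset=["max_distance_m"])
        self.x_unc = df.loc[~df["censored"], "max_distance_m"].to_numpy(dtype=float)
        self.x_cen = df.loc[df["censored"], "max_distance_m"].to_numpy(dtype=float)
        self.x_unc = np.maximum(self.x_unc, 1e-6)
        self.x_cen = np.maximum(self.x_cen, 1e-6)
        self.seed = seed
        if len(self.x_unc) < 5:
            raise ValueError("need at least 5 uncensored dispersal records")

    def fit(self, family: str) -> KernelFitResults:
        rng = np.random.default_rng(self.seed)
        nll = _nll_factory(family, self.x_unc, self.x_cen)
        best = None
        x_all = np.concatenate([self.x_unc, self.x_cen])
        for x0 in _starts(family, x_all, rng):
            res = minimize(nll, x0, method="Nelder-Mead",
                           options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 8000})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"{family}: optimizer failed")
        theta = best.x
        if family == "burr":
            params = {"c": float(np.exp(theta[0])), "k": float(np.exp(theta[1])),
                      "scale": float(np.exp(theta[2]))}
        elif family == "weibull":
            params = {"shape": float(np.exp(theta[0])), "scale": float(np.exp(theta[1]))}
        elif family == "lognormal":
            params = {"mu": float(theta[0]), "sigma": float(np.exp(theta[1]))}
        elif family == "gamma":
            params = {"shape": float(np.exp(theta[0])), "scale": float(np.exp(theta[1]))}
        else:
            params = {"scale": float(np.exp(theta[0]))}
        return KernelFitResults(family=family, params=params,
                                loglik=-float(best.fun),
                                n_params=_FAMILY_NPARAMS[family],
                                n_obs=len(self.x_unc) + len(self.x_cen),
                                n_censored=len(self.x_cen))

    def fit_all(self, families=None) -> list:
        """Fit every candidate family; rank by AIC (best first)."""
        fits = []
        for fam in (families or self.FAMILIES):
            try:
                fits.append(self.fit(fam))
            except Exception as exc:  # noqa: BLE001 — a family may legitimately fail
                warnings.warn(f"kernel family {fam} skipped: {exc}", stacklevel=2)
        if not fits:
            raise RuntimeError("no kernel family could be fitted")
        return sorted(fits, key=lambda f: f.aic)


def fit_kernels(records: pd.DataFrame, seed: int = 0) -> list:
    return DispersalKernel(records, seed=seed).fit_all()


def ranked_fit_table(fits: list) -> pd.DataFrame:
    return pd.DataFrame([
        {"family": f.family, "loglik": f.loglik, "aic": f.aic,
         **{f"param_{k}": v for k, v in f.params.items()}}
        for f in fits
    ])
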