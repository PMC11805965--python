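"""Position-error calibration, filtering, detection range, and centers of activity.

The error filter follows standard practice for hyperbolic positioning
systems: positions from known-location (sync/reference) tags give measured
horizontal errors, summarized per unit HPE bin as 2DRMS

    2DRMS_i = 2 sqrt( (1/n_i) sum_j (dx_ij^2 + dy_ij^2) ),

which is regressed on mean HPE per bin (optionally per array region, with
the number of regions chosen by small-sample AIC); fish positions whose
predicted 2DRMS exceeds an accuracy threshold (default 20 m) are censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit


class CalibrationError(ValueError):
    pass


class SeparationError(ValueError):
    """The range trials are completely separated; the logistic fit is unbounded."""


# ---------------------------------------------------------------------------
# 2DRMS calibration
# ---------------------------------------------------------------------------

def compute_2drms_bins(calibration_positions: pd.DataFrame,
                       hpe_censor_quantile: float = 0.95,
                       min_bin_n: int = 3) -> pd.DataFrame:
    """Per-HPE-bin 2DRMS (meters) from known-location positions.

    The upper (1 − hpe_censor_quantile) tail of HPE values is censored
    before binning (floor(HPE), increment 1). Bins with fewer than
    ``min_bin_n`` observations are merged upward into the next bin (the
    topmost deficient bin merges downward); a lone bin is kept as is.
    """
    df = calibration_positions.dropna(subset=["known_x_m", "known_y_m"])
    if df.empty:
        raise CalibrationError("no known-location calibration positions available")
    cut = df["hpe"].quantile(hpe_censor_quantile)
    df = df[df["hpe"] <= cut]
    err2 = (df["x_m"] - df["known_x_m"]) ** 2 + (df["y_m"] - df["known_y_m"]) ** 2
    work = pd.DataFrame({"bin": np.floor(df["hpe"]).astype(int),
                         "hpe": df["hpe"], "err2": err2})
    groups = [
        {"bin": b, "hpe": g["hpe"].to_numpy(), "err2": g["err2"].to_numpy()}
        for b, g in work.groupby("bin", sort=True)
    ]
    merged: list[dict] = []
    pending: dict | None = None
    for g in groups:
        if pending is not None:
            g = {"bin": g["bin"],
                 "hpe": np.concatenate([pending["hpe"], g["hpe"]]),
                 "err2": np.concatenate([pending["err2"], g["err2"]])}
            pending = None
        if len(g["err2"]) < min_bin_n:
            pending = g
        else:
            merged.append(g)
    if pending is not None:
        if merged:
            last = merged[-1]
            last["hpe"] = np.concatenate([last["hpe"], pending["hpe"]])
            last["err2"] = np.concatenate([last["err2"], pending["err2"]])
        else:
            merged.append(pending)
    return pd.DataFrame({
        "hpe_bin": [g["bin"] for g in merged],
        "mean_hpe": [float(np.mean(g["hpe"])) for g in merged],
        "n": [len(g["err2"]) for g in merged],
        "twodrms_m": [2.0 * float(np.sqrt(np.mean(g["err2"]))) for g in merged],
    })


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept, and residual sum of squares."""
    if len(x) < 2:
        raise CalibrationError("need at least 2 HPE bins to fit a line")
    slope, intercept = np.polyfit(x, y, 1)
    rss = float(np.sum((y - (slope * x + intercept)) ** 2))
    return float(slope), float(intercept), rss


def _aicc(rss: float, n: int, k: int) -> float:
    # Gaussian-likelihood AIC with small-sample correction; k counts the
    # regression coefficients plus the error variance.
    rss = max(rss, 1e-12)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return float(aic)


@dataclass
class PositionErrorResults:
    """Fitted 2DRMS-vs-HPE line(s), one per retained array region."""
    lines: dict                  # region -> (slope, intercept)
    bins: pd.DataFrame           # per-region bin table used for the fit
    comparison: pd.DataFrame     # candidate partitions and their AICc
    partition: dict              # base region -> fitted group
    hpe_censor_quantile: float
    error_threshold_m: float = 20.0

    def predict_2drms(self, hpe, region=None) -> np.ndarray:
        region = region if region is not None else next(iter(self.lines))
        group = self.partition.get(region)
        if group is None:  # unseen region: nearest by name order, logged upstream
            group = next(iter(self.lines))
        slope, intercept = self.lines[group]
        return slope * np.asarray(hpe, dtype=float) + intercept

    def filter_positions(self, positions: pd.DataFrame,
                         threshold_m: float | None = None) -> "FilterReport":
        """Retain positions with predicted 2DRMS <= the accuracy threshold."""
        threshold = self.error_threshold_m if threshold_m is None else threshold_m
        region = positions["region"] if "region" in positions else pd.Series(
            next(iter(self.partition)), index=positions.index)
        groups = region.map(self.partition).fillna(next(iter(self.lines)))
        slopes = groups.map({g: v[0] for g, v in self.lines.items()}).to_numpy(float)
        inter = groups.map({g: v[1] for g, v in self.lines.items()}).to_numpy(float)
        predicted = slopes * positions["hpe"].to_numpy(float) + inter
        keep = predicted <= threshold
        retained = positions.loc[keep].reset_index(drop=True)
        return FilterReport(positions=retained,
                            retention=float(keep.mean()) if len(keep) else float("nan"),
                            threshold_m=float(threshold), n_in=len(positions),
                            n_out=int(keep.sum()))

    def summary(self) -> str:
        lines = ["Position-error calibration (2DRMS vs HPE)",
                 f"  HPE censor quantile: {self.hpe_censor_quantile}",
                 f"  threshold: {self.error_threshold_m} m"]
        for g, (s, b) in self.lines.items():
            lines.append(f"  region group {g}: 2DRMS = {s:.3f} * HPE + {b:.3f}")
        lines.append("  model comparison:")
        for _, row in self.comparison.iterrows():
            lines.append(f"    {row['partition']}: AICc = {row['aicc']:.2f}"
                         + ("  <- selected" if row["selected"] else ""))
        return "\n".join(lines)


@dataclass
class FilterReport:
    positions: pd.DataFrame
    retention: float
    threshold_m: float
    n_in: int
    n_out: int


class PositionErrorModel:
    """OLS of per-bin 2DRMS on mean HPE, with array-region model comparison.

    Parameters
    ----------
    calibration_positions : DataFrame
        ``positions``-schema rows for known-location tags. An optional
        ``region`` column assigns each row to a base array region.
    """

    def __init__(self, calibration_positions: pd.DataFrame,
                 hpe_censor_quantile: float = 0.95,
                 error_threshold_m: float = 20.0):
        self.calib = calibration_positions.copy()
        if "region" not in self.calib:
            self.calib["region"] = "all"
        self.hpe_censor_quantile = hpe_censor_quantile
        self.error_threshold_m = error_threshold_m

    def fit(self) -> PositionErrorResults:
        """Compare candidate region partitions on the same per-region bin
        table: the 1-region model is one line through all (region, bin)
        points, the k-region model one line per region; AICc decides."""
        regions = sorted(self.calib["region"].dropna().unique())
        frames = []
        for r in regions:
            frames.append(compute_2drms_bins(
                self.calib[self.calib["region"] == r],
                self.hpe_censor_quantile).assign(region=r))
        bins = pd.concat(frames, ignore_index=True)
        x_all = bins["mean_hpe"].to_numpy()
        y_all = bins["twodrms_m"].to_numpy()
        n_tot = len(bins)

        candidates = []
        s, b, rss = _ols_line(x_all, y_all)
        candidates.append({
            "partition": "1-region", "k_groups": 1,
            "aicc": _aicc(rss, n_tot, 3),
            "lines": {"pooled": (s, b)},
            "mapping": {r: "pooled" for r in regions},
            "bins": bins,
        })
        if len(regions) > 1:
            lines, mapping, rss_tot = {}, {}, 0.0
            try:
                for r in regions:
                    sub = bins[bins["region"] == r]
                    s, b, rss = _ols_line(sub["mean_hpe"].to_numpy(),
                                          sub["twodrms_m"].to_numpy())
                    lines[r] = (s, b)
                    mapping[r] = r
                    rss_tot += rss
                candidates.append({
                    "partition": f"{len(regions)}-region", "k_groups": len(regions),
                    "aicc": _aicc(rss_tot, n_tot, 2 * len(regions) + 1),
                    "lines": lines, "mapping": mapping, "bins": bins,
                })
            except CalibrationError:
                pass  # a region without enough bins: only the pooled model stands
        best = min(candidates, key=lambda c: c["aicc"])
        comparison = pd.DataFrame(
            {"partition": [c["partition"] for c in candidates],
             "k_groups": [c["k_groups"] for c in candidates],
             "aicc": [c["aicc"] for c in candidates],
             "selected": [c is best for c in candidates]})
        return PositionErrorResults(
            lines=best["lines"], bins=best["bins"], comparison=comparison,
            partition=best["mapping"],
            hpe_censor_quantile=self.hpe_censor_quantile,
            error_threshold_m=self.error_threshold_m)


# ---------------------------------------------------------------------------
# Detection-range model
# ---------------------------------------------------------------------------

@dataclass
class DetectionRangeResults:
    p0: float
    d50_m: float
    steepness: float
    loglik: float
    n_trials: int
    se: dict = field(default_factory=dict)
    trial_bins: pd.DataFrame | None = None

    def predict(self, distance_m):
        z = self.steepness * (np.asarray(distance_m, dtype=float) - self.d50_m)
        return self.p0 / (1.0 + np.exp(np.clip(z, -700, 700)))

    def summary(self) -> str:
        return ("Logistic detection-range model\n"
                f"  p0        = {self.p0:.4f}\n"
                f"  d50       = {self.d50_m:.1f} m (distance at p = p0/2)\n"
                f"  steepness = {self.steepness:.5f} /m\n"
                f"  loglik    = {self.loglik:.2f} on {self.n_trials} trials")


class DetectionRangeModel:
    """Maximum-likelihood logistic range curve from Bernoulli range trials.

    p(d) = p0 / (1 + exp(steepness (d − d50))); d50 is the 50% detection
    range (p = p0/2 there by construction).
    """

    def __init__(self, trials: pd.DataFrame):
        if not {"distance_m", "detected"} <= set(trials.columns):
            raise ValueError("trials must have columns distance_m, detected")
        self.trials = trials

    def fit(self) -> DetectionRangeResults:
        d = self.trials["distance_m"].to_numpy(dtype=float)
        y = self.trials["detected"].to_numpy(dtype=bool)
        if y.all() or (~y).all():
            raise SeparationError(
                "all range trials share one outcome; widen the distance span "
                "so that trials bracket the 50% range")

        def nll(theta):
            p0 = expit(theta[0])
            d50 = np.exp(theta[1])
            steep = np.exp(theta[2])
            p = np.clip(p0 / (1.0 + np.exp(np.clip(steep * (d - d50), -700, 700))),
                        1e-12, 1 - 1e-12)
            return -(np.log(p)[y].sum() + np.log1p(-p)[~y].sum())

        x0 = np.array([2.0, np.log(max(np.median(d), 1.0)), np.log(0.01)])
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 5000})
        if not res.success:
            raise SeparationError(f"range fit failed to converge: {res.message}")
        p0 = float(expit(res.x[0]))
        d50 = float(np.exp(res.x[1]))
        steep = float(np.exp(res.x[2]))
        bins = (self.trials.assign(bin=(d // 100 * 100).astype(int))
                .groupby("bin")["detected"].agg(trials="size", successes="sum")
                .reset_index())
        return DetectionRangeResults(p0=p0, d50_m=d50, steepness=steep,
                                     loglik=-float(res.fun), n_trials=len(d),
                                     trial_bins=bins)


def estimate_range(trials: pd.DataFrame) -> DetectionRangeResults:
    return DetectionRangeModel(trials).fit()


# ---------------------------------------------------------------------------
# Centers of activity
# ---------------------------------------------------------------------------

def remove_spurious_detections(detections: pd.DataFrame,
                               window_minutes: float = 60.0) -> pd.DataFrame:
    """Drop detections in complete isolation: no other detection of the same
    tag within ±window_minutes."""
    df = detections.sort_values(["tag_id", "timestamp"])
    ts = df["timestamp"]
    gap_prev = ts.groupby(df["tag_id"]).diff()
    gap_next = ts.groupby(df["tag_id"]).diff(-1).abs()
    win = pd.Timedelta(minutes=window_minutes)
    isolated = ((gap_prev.isna() | (gap_prev > win))
                & (gap_next.isna() | (gap_next > win)))
    return df.loc[~isolated].reset_index(drop=True)


def compute_coas(detections: pd.DataFrame, receivers: pd.DataFrame,
                 bin_minutes: int = 30, min_receivers: int = 3) -> pd.DataFrame:
    """Time-binned centers of activity.

    After spurious-detection removal, each (tag, bin) COA is the unweighted
    mean of the *distinct* detecting receivers' coordinates. Bins heard on
    fewer than ``min_receivers`` receivers are dropped — except on the tag's
    final detection date, where every bin with >= 1 receiver is retained
    (emigrating fish move fast and thin out their detections).
    """
    if 1440 % bin_minutes != 0:
        raise ValueError("bin_minutes must divide 1440 (a whole day)")
    det = remove_spurious_detections(detections)
    if det.empty:
        return pd.DataFrame(columns=["tag_id", "bin_start", "bin_minutes", "x_m",
                                     "y_m", "n_receivers", "mean_depth_m"])
    det = det.merge(receivers[["receiver_id", "x_m", "y_m"]], on="receiver_id",
                    how="inner")
    det["bin_start"] = det["timestamp"].dt.floor(f"{bin_minutes}min")
    # distinct receivers only for the coordinate mean
    uniq = det.drop_duplicates(["tag_id", "bin_start", "receiver_id"])
    coords = uniq.groupby(["tag_id", "bin_start"]).agg(
        x_m=("x_m", "mean"), y_m=("y_m", "mean"), n_receivers=("receiver_id", "size"))
    depth = det.groupby(["tag_id", "bin_start"])["depth_m"].mean().rename("mean_depth_m")
    coas = coords.join(depth).reset_index()
    last_date = det.groupby("tag_id")["timestamp"].max().dt.normalize()
    coas["final_date"] = coas["tag_id"].map(last_date)
    on_final = coas["bin_start"].dt.normalize() == coas["final_date"]
    keep = (coas["n_receivers"] >= min_receivers) | on_final
    coas = coas.loc[keep].drop(columns="final_date")
    coas["bin_minutes"] = bin_minutes
    return coas[["tag_id", "bin_start", "bin_minutes", "x_m", "y_m",
                 "n_receivers", "mean_depth_m"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Residence index and detection gaps
# ---------------------------------------------------------------------------

def residence_index(detections: pd.DataFrame) -> pd.DataFrame:
    """Per fish: RI = detection days / inclusive first-to-last day span."""
    days = detections.assign(date=detections["timestamp"].dt.normalize())
    out = []
    for tag, g in days.groupby("tag_id"):
        uniq = np.sort(g["date"].unique())
        dd = len(uniq)
        period = int((uniq[-1] - uniq[0]) / np.timedelta64(1, "D")) + 1
        out.append({"tag_id": tag, "detection_days": dd,
                    "period_days": period, "ri": dd / period})
    return pd.DataFrame(out)


def detection_gaps(detections: pd.DataFrame) -> pd.DataFrame:
    """Maximal runs of zero-detection days strictly inside each fish's
    detection period; one row per gap."""
    days = detections.assign(date=detections["timestamp"].dt.normalize())
    rows = []
    for tag, g in days.groupby("tag_id"):
        uniq = np.sort(g["date"].unique())
        diffs = np.diff(uniq) / np.timedelta64(1, "D")
        for i, d in enumerate(diffs):
            if d > 1:
                rows.append({"tag_id": tag,
                             "gap_start": pd.Timestamp(uniq[i]) + pd.Timedelta(days=1),
                             "gap_days": int(d) - 1})
    return pd.DataFrame(rows, columns=["tag_id", "gap_start", "gap_days"])
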