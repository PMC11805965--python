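"""Brownian-bridge space use, movement rates and long-distance movements.

Utilization distributions (UDs) are built from filtered positions as
Brownian bridges on a 10 x 10 m grid: between each pair of consecutive
positions no more than 60 min apart, the animal's location at intermediate
time fraction a is Gaussian with mean (1-a) z0 + a z1 and variance

    s^2(a) = a (1-a) T sigma_m^2 + ((1-a)^2 + a^2) delta^2,

where T is the pair's time span, sigma_m^2 the Brownian motion variance and
delta the telemetry location error (the accepted position-error threshold).
The bridge is integrated over a by midpoint quadrature; pairs are weighted
by the time interval they span; daily UDs average into a tracking-duration
UD (equal weight per day). Isopleths (50/90/95%) are the smallest sets of
cells holding the stated probability mass; "centroids" are 90%-isopleth
components of at least 100 m^2, and a space-use shift is the adoption of a
new centroid that does not overlap in time with any previously used one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize_scalar
from scipy.stats import spearmanr

from ._util import UnionFind

CELL_M = 10.0


# ---------------------------------------------------------------------------
# UD grid container
# ---------------------------------------------------------------------------

@dataclass
class UdGrid:
    origin: tuple            # (x0, y0) of the lower-left cell corner
    cell_m: float
    density: np.ndarray      # (ny, nx), integrates to 1 over the grid
    scale: str               # "daily" | "tracking_duration"
    tag_id: str = ""
    date: object = None

    @property
    def cell_area(self) -> float:
        return self.cell_m ** 2

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)

    def normalize(self) -> "UdGrid":
        m = self.density.sum() * self.cell_area
        if m > 0:
            self.density = self.density / m
        return self

    def cell_centers(self):
        ny, nx = self.density.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_m
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_m
        return xs, ys


def _snap(v: float, cell: float) -> float:
    return np.floor(v / cell) * cell


def _make_grid(xmin, xmax, ymin, ymax, cell, margin):
    x0 = _snap(xmin - margin, cell)
    y0 = _snap(ymin - margin, cell)
    nx = int(np.ceil((xmax + margin - x0) / cell)) + 1
    ny = int(np.ceil((ymax + margin - y0) / cell)) + 1
    return x0, y0, nx, ny


# ---------------------------------------------------------------------------
# Motion variance (leave-one-out bridge likelihood)
# ---------------------------------------------------------------------------

def estimate_motion_variance(positions: pd.DataFrame, error_sd: float,
                             max_triplets: int = 2000) -> float:
    """Per-fish Brownian motion variance sigma_m^2 (m^2/s) by leave-one-out
    likelihood on position triplets: every other position is predicted from
    the bridge over its neighbours and sigma_m^2 maximizes the product of
    those Gaussian predictive densities."""
    df = positions.sort_values("timestamp")
    t = df["timestamp"].astype("int64").to_numpy() / 1e9
    x = df["x_m"].to_numpy(dtype=float)
    y = df["y_m"].to_numpy(dtype=float)
    idx = np.arange(1, len(df) - 1, 2)
    if len(idx) > max_triplets:
        idx = idx[np.linspace(0, len(idx) - 1, max_triplets).astype(int)]
    if len(idx) == 0:
        return 0.0
    T = t[idx + 1] - t[idx - 1]
    ok = (T > 0) & (T < 6 * 3600)
    idx, T = idx[ok], T[ok]
    if len(idx) == 0:
        return 0.0
    a = (t[idx] - t[idx - 1]) / T
    mx = (1 - a) * x[idx - 1] + a * x[idx + 1]
    my = (1 - a) * y[idx - 1] + a * y[idx + 1]
    r2 = (x[idx] - mx) ** 2 + (y[idx] - my) ** 2

    def nll(log_s2):
        s2 = np.exp(log_s2)
        var = a * (1 - a) * T * s2 + ((1 - a) ** 2 + a ** 2 + 1.0) * error_sd ** 2
        return float(np.sum(np.log(var) + r2 / (2 * var)))

    res = minimize_scalar(nll, bounds=(np.log(1e-6), np.log(100.0)),
                          method="bounded")
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# Daily and tracking-duration UDs
# ---------------------------------------------------------------------------

def _accumulate_gaussian(density, x0, y0, cell, mux, muy, var, weight):
    """Add `weight` x a unit bivariate Gaussian (isotropic, variance `var`)
    onto the grid, evaluated on a +-4 sigma local window."""
    ny, nx = density.shape
    sd = np.sqrt(var)
    r = max(1, int(np.ceil(4 * sd / cell)))
    ci = int((mux - x0) / cell)
    cj = int((muy - y0) / cell)
    i0, i1 = max(0, ci - r), min(nx, ci + r + 1)
    j0, j1 = max(0, cj - r), min(ny, cj + r + 1)
    if i0 >= i1 or j0 >= j1:
        return
    xs = x0 + (np.arange(i0, i1) + 0.5) * cell
    ys = y0 + (np.arange(j0, j1) + 0.5) * cell
    gx = np.exp(-((xs - mux) ** 2) / (2 * var))
    gy = np.exp(-((ys - muy) ** 2) / (2 * var))
    density[j0:j1, i0:i1] += weight / (2 * np.pi * var) * np.outer(gy, gx)


def daily_ud(positions_for_day: pd.DataFrame, sigma_m2: float,
             error_sd: float = 20.0, cell_m: float = CELL_M,
             max_gap_minutes: float = 60.0, n_quad: int = 10,
             grid=None) -> UdGrid | None:
    """Brownian-bridge UD for one fish-day; None when no pair of positions
    within the 60-min gap limit exists (a no-UD day)."""
    df = positions_for_day.sort_values("timestamp")
    t = df["timestamp"].astype("int64").to_numpy() / 1e9
    x = df["x_m"].to_numpy(dtype=float)
    y = df["y_m"].to_numpy(dtype=float)
    dt = np.diff(t)
    eligible = (dt > 0) & (dt <= max_gap_minutes * 60.0)
    if not eligible.any():
        return None
    if grid is None:
        margin = 4 * error_sd + 4 * np.sqrt(max(sigma_m2, 0.0) * 3600) + 2 * cell_m
        x0, y0, nx, ny = _make_grid(x.min(), x.max(), y.min(), y.max(), cell_m, margin)
    else:
        x0, y0, nx, ny = grid
    density = np.zeros((ny, nx))
    alphas = (np.arange(n_quad) + 0.5) / n_quad  # midpoint quadrature
    for k in np.nonzero(eligible)[0]:
        T = dt[k]
        w = T / n_quad
        for a in alphas:
            mux = (1 - a) * x[k] + a * x[k + 1]
            muy = (1 - a) * y[k] + a * y[k + 1]
            var = a * (1 - a) * T * sigma_m2 + ((1 - a) ** 2 + a ** 2) * error_sd ** 2
            _accumulate_gaussian(density, x0, y0, cell_m, mux, muy, var, w)
    ud = UdGrid(origin=(x0, y0), cell_m=cell_m, density=density, scale="daily",
                tag_id=str(df["tag_id"].iloc[0]) if "tag_id" in df else "",
                date=df["timestamp"].iloc[0].normalize())
    return ud.normalize()


def _union_grid(uds: list, cell: float):
    x0 = min(u.origin[0] for u in uds)
    y0 = min(u.origin[1] for u in uds)
    x1 = max(u.origin[0] + u.density.shape[1] * cell for u in uds)
    y1 = max(u.origin[1] + u.density.shape[0] * cell for u in uds)
    nx = int(round((x1 - x0) / cell))
    ny = int(round((y1 - y0) / cell))
    return x0, y0, nx, ny


def tracking_ud(daily_uds: list, min_ud_days: int = 33,
                min_mean_positions: float = 18.0,
                daily_position_counts=None) -> UdGrid:
    """Tracking-duration UD: equal-weight average of the daily UD density
    surfaces on their union grid.

    Eligibility mirrors the data-quality floor: at least ``min_ud_days``
    estimable daily UDs and a mean of at least ``min_mean_positions`` daily
    positions (when counts are supplied). Ineligible fish raise
    :class:`IneligibleFishError` carrying the reason code.
    """
    uds = [u for u in daily_uds if u is not None]
    if len(uds) < min_ud_days:
        raise IneligibleFishError(f"only {len(uds)} UD-days < minimum {min_ud_days}")
    if daily_position_counts is not None and len(daily_position_counts):
        mean_pos = float(np.mean(daily_position_counts))
        if mean_pos < min_mean_positions:
            raise IneligibleFishError(
                f"mean daily positions {mean_pos:.1f} < minimum {min_mean_positions}")
    cell = uds[0].cell_m
    x0, y0, nx, ny = _union_grid(uds, cell)
    density = np.zeros((ny, nx))
    for u in uds:
        i0 = int(round((u.origin[0] - x0) / cell))
        j0 = int(round((u.origin[1] - y0) / cell))
        uy, ux = u.density.shape
        density[j0:j0 + uy, i0:i0 + ux] += u.density
    out = UdGrid(origin=(x0, y0), cell_m=cell, density=density,
                 scale="tracking_duration", tag_id=uds[0].tag_id)
    return out.normalize()


class IneligibleFishError(ValueError):
    """Fish does not meet the UD data-quality floor; reason in the message."""


# ---------------------------------------------------------------------------
# Contours and centroids
# ---------------------------------------------------------------------------

@dataclass
class Contour:
    level: float
    mask: np.ndarray
    area_m2: float
    grid: UdGrid


def contour(ud: UdGrid, level: float) -> Contour:
    """Smallest set of cells whose cumulative probability reaches `level`."""
    if not 0.0 < level < 1.0:
        raise ValueError("contour level must be in (0, 1)")
    flat = ud.density.ravel()
    order = np.argsort(flat)[::-1]
    mass = np.cumsum(flat[order]) * ud.cell_area
    k = int(np.searchsorted(mass, level - 1e-9)) + 1
    k = min(k, len(flat))
    mask = np.zeros_like(flat, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.density.shape)
    return Contour(level=level, mask=mask, area_m2=float(k * ud.cell_area), grid=ud)


@dataclass
class Centroid:
    label: int
    mask: np.ndarray
    area_m2: float
    first_day: object = None
    last_day: object = None
    day_counts: dict = field(default_factory=dict)


def find_centroids(ud_td: UdGrid, level: float = 0.90,
                   min_area_m2: float = 100.0) -> list:
    """Connected components of the 90% isopleth with area >= 100 m^2."""
    c = contour(ud_td, level)
    labeled, n = ndimage.label(c.mask, structure=np.ones((3, 3), dtype=int))
    out = []
    for lab in range(1, n + 1):
        m = labeled == lab
        area = float(m.sum() * ud_td.cell_area)
        if area >= min_area_m2:
            out.append(Centroid(label=lab, mask=m, area_m2=area))
    return out


def centroid_occupancy(centroids: list, ud_td: UdGrid,
                       daily_positions: pd.DataFrame) -> list:
    """Count daily positions inside each centroid; fills each centroid's
    active-day fields in place and returns the list."""
    x0, y0 = ud_td.origin
    cell = ud_td.cell_m
    ny, nx = ud_td.density.shape
    df = daily_positions.assign(date=daily_positions["timestamp"].dt.normalize())
    ii = ((df["x_m"] - x0) / cell).astype(int).clip(0, nx - 1)
    jj = ((df["y_m"] - y0) / cell).astype(int).clip(0, ny - 1)
    for c in centroids:
        inside = c.mask[jj, ii]
        days = df.loc[inside.to_numpy() if hasattr(inside, "to_numpy") else inside,
                      "date"]
        counts = days.value_counts().sort_index()
        c.day_counts = {d: int(v) for d, v in counts.items()}
        if len(counts):
            c.first_day, c.last_day = counts.index.min(), counts.index.max()
    return centroids


def detect_shifts(centroids: list) -> list:
    """Shift events: a centroid whose first active day strictly follows the
    last active day of every previously used centroid (no temporal overlap)."""
    used = [c for c in centroids if c.first_day is not None]
    used.sort(key=lambda c: c.first_day)
    shifts = []
    for i, c in enumerate(used[1:], start=1):
        prev_last = max(p.last_day for p in used[:i])
        if c.first_day > prev_last:
            shifts.append({"centroid": c.label, "shift_day": c.first_day})
    return shifts


# ---------------------------------------------------------------------------
# Movement rates
# ---------------------------------------------------------------------------

def movement_rates(positions: pd.DataFrame,
                   error_threshold_m: float = 20.0) -> pd.DataFrame:
    """Per-step distance (m), rate (m/s) and worst-case-corrected rate,
    where the corrected numerator is max(0, d − 2·error_threshold)."""
    out = []
    for tag, g in positions.sort_values("timestamp").groupby("tag_id"):
        t = g["timestamp"].astype("int64").to_numpy() / 1e9
        x = g["x_m"].to_numpy(dtype=float)
        y = g["y_m"].to_numpy(dtype=float)
        dt = np.diff(t)
        d = np.hypot(np.diff(x), np.diff(y))
        zero = dt <= 0
        if zero.any():
            warnings.warn(f"{tag}: skipped {int(zero.sum())} zero-interval step(s)",
                          stacklevel=2)
        dt_, d_ = dt[~zero], d[~zero]
        out.append(pd.DataFrame({
            "tag_id": tag,
            "t_start": g["timestamp"].iloc[:-1].to_numpy()[~zero],
            "distance_m": d_,
            "dt_s": dt_,
            "rate_mps": d_ / dt_,
            "corrected_rate_mps": np.maximum(0.0, d_ - 2 * error_threshold_m) / dt_,
        }))
    if not out:
        return pd.DataFrame(columns=["tag_id", "t_start", "distance_m", "dt_s",
                                     "rate_mps", "corrected_rate_mps"])
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Long-distance movements
# ---------------------------------------------------------------------------

def detect_ldm(locations: pd.DataFrame, window_h: float = 48.0,
               min_dist_m: float = 2000.0, source: str = "positions",
               array_hull_poly=None) -> pd.DataFrame:
    """Long-distance movements: any two locations of one fish more than
    ``min_dist_m`` apart within ``window_h`` hours. Qualifying pairs that
    share a location merge into a single event (one traverse is counted
    once); an event ending at the fish's final location outside/near the
    array edge is flagged emigration-associated."""
    events = []
    win_s = window_h * 3600.0
    for tag, g in locations.sort_values("timestamp").groupby("tag_id"):
        t = g["timestamp"].astype("int64").to_numpy() / 1e9
        x = g["x_m"].to_numpy(dtype=float)
        y = g["y_m"].to_numpy(dtype=float)
        n = len(t)
        uf = UnionFind(n)
        hit = np.zeros(n, dtype=bool)
        j_hi = 0
        for i in range(n):
            while j_hi < n and t[j_hi] - t[i] <= win_s:
                j_hi += 1
            if j_hi - i < 2:
                continue
            d = np.hypot(x[i + 1:j_hi] - x[i], y[i + 1:j_hi] - y[i])
            far = np.nonzero(d > min_dist_m)[0]
            for off in far:
                j = i + 1 + off
                uf.union(i, j)
                hit[i] = hit[j] = True
        if not hit.any():
            continue
        comps: dict[int, list] = {}
        for i in np.nonzero(hit)[0]:
            comps.setdefault(uf.find(int(i)), []).append(int(i))
        for members in comps.values():
            members = sorted(members)
            xy = np.column_stack([x[members], y[members]])
            from ._util import max_pairwise_distance
            ends_at_final = members[-1] == n - 1
            emig = False
            if ends_at_final and array_hull_poly is not None:
                from shapely.geometry import Point
                emig = not array_hull_poly.contains(Point(x[members[-1]],
                                                          y[members[-1]]))
            events.append({
                "tag_id": tag,
                "start": pd.Timestamp(t[members[0]], unit="s", tz="UTC"),
                "end": pd.Timestamp(t[members[-1]], unit="s", tz="UTC"),
                "start_x": x[members[0]], "start_y": y[members[0]],
                "end_x": x[members[-1]], "end_y": y[members[-1]],
                "max_distance_m": max_pairwise_distance(xy),
                "source": source,
                "emigration_associated": bool(emig or ends_at_final),
            })
    return pd.DataFrame(events, columns=[
        "tag_id", "start", "end", "start_x", "start_y", "end_x", "end_y",
        "max_distance_m", "source", "emigration_associated"])


# ---------------------------------------------------------------------------
# Habitat and correlation
# ---------------------------------------------------------------------------

def assign_habitat(points: pd.DataFrame, habitat_map) -> pd.Series:
    """Point-in-polygon habitat labels; anything outside named polygons is
    sand (with a warning when outside the map's bounding box entirely)."""
    labels = []
    bounds = None
    if habitat_map.polygons:
        xs = [p.bounds for p in habitat_map.polygons.values()]
        bounds = (min(b[0] for b in xs), min(b[1] for b in xs),
                  max(b[2] for b in xs), max(b[3] for b in xs))
    n_outside = 0
    for _, r in points.iterrows():
        if bounds and not (bounds[0] - 5000 <= r["x_m"] <= bounds[2] + 5000
                           and bounds[1] - 5000 <= r["y_m"] <= bounds[3] + 5000):
            n_outside += 1
        labels.append(habitat_map.label(r["x_m"], r["y_m"]))
    if n_outside:
        warnings.warn(f"{n_outside} point(s) far outside the habitat map; "
                      "labeled sand", stacklevel=2)
    return pd.Series(labels, index=points.index, name="habitat_label")


def habitat_summary(values: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Median of a per-fish metric (e.g. UD95 area) by habitat label."""
    df = pd.DataFrame({"value": values, "habitat_label": labels})
    return (df.groupby("habitat_label")["value"]
            .agg(n="size", median="median", mean="mean")
            .reset_index())


def rank_correlation(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman's rho; exact permutation p-value for small n (<= exact_max_n),
    the large-sample approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need paired samples of length >= 3")
    rho, p_approx = spearmanr(x, y)
    if n > exact_max_n:
        return float(rho), float(p_approx)
    ry = pd.Series(y).rank().to_numpy()
    rx = pd.Series(x).rank().to_numpy()
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(ry):
        r = np.corrcoef(rx, np.asarray(perm))[0, 1]
        if abs(r) >= obs - 1e-12:
            count += 1
        total += 1
    return float(rho), count / total
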