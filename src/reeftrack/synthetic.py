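"""Synthetic acoustic-telemetry study generator.

Emulates a high-density acoustic positioning study of a resident reef fish:
a grid receiver array (550–600 m spacing), tags with a 60–180 s random
interpulse delay, a logistic detection-range curve (50% range 346 m for
fish-spec tags, ~700 m for sync tags), Ornstein–Uhlenbeck residency around
habitat centroids with occasional shifts, daily competing risks of
emigration (elevated on low-atmospheric-pressure days), natural mortality
(tag goes stationary), predation (rapid shark-like run, then off array) and
capture removal (abrupt stop), and triangulated positions carrying an
HPE-proportional isotropic Gaussian error.

Every simulated fish carries its ground-truth track and fate, so each
downstream estimator can be validated against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from shapely.geometry import MultiPoint, Point, Polygon, box

from .io import HabitatMap
from ._util import child_rng

DAY_S = 86_400

FATES = ("survived", "emigrated", "mortality", "predated", "captured")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ArraySpec:
    n_rows: int = 8
    n_cols: int = 8
    spacing_m: float = 550.0


@dataclass
class RangeSpec:
    """Logistic detection-range curve p(d) = p0 / (1 + exp(steepness·(d − d50)))."""
    p0: float = 1.0
    d50_m: float = 346.0          # fish-spec (pressure-sensor) tag
    steepness: float = 0.005      # per meter; max range ~1.7 km
    sync_d50_m: float = 700.0     # receiver-internal sync tags


@dataclass
class MovementSpec:
    centroid_sd_m: float = 30.0       # stationary SD of the OU walk
    ou_tau_minutes: float = 60.0      # OU relaxation time
    step_minutes: float = 10.0
    shift_prob_per_day: float = 0.004
    n_centroids_max: int = 7
    emigration_speed_mps: float = 0.3
    predation_speed_mps: float = 1.5
    predation_run_hours: float = 4.0


@dataclass
class TransmissionSpec:
    delay_min_s: float = 60.0
    delay_max_s: float = 180.0


@dataclass
class HazardSpec:
    """Daily competing-risk hazards; all probabilities per fish-day."""
    base_emigration_per_day: float = 0.0004
    low_pressure_multiplier: float = 175.0
    mortality_per_day: float = 0.00023
    capture_per_day: float = 0.00026
    predation_per_day: float = 0.0001


@dataclass
class PressureSpec:
    low_day_prob: float = 0.005
    regular_mbar: float = 1018.0
    low_mbar: float = 1004.0


@dataclass
class PositionErrorSpec:
    """HPE ~ Gamma(shape, scale); true error SD = error_per_hpe_m · HPE."""
    hpe_shape: float = 2.0
    hpe_scale: float = 1.7
    error_per_hpe_m: float = 1.2


@dataclass
class DispersalSpec:
    """Burr XII kernel for emigrant destination distance (meters)."""
    scale_m: float = 1000.0
    c: float = 1.2
    k: float = 0.9
    recapture_prob: float = 0.4   # emigrant later recaptured off-array
    glider_prob: float = 0.25     # emigrant detected alive by the glider


@dataclass
class SimConfig:
    seed: int = 0
    n_fish: int = 85
    study_days: int = 942
    array: ArraySpec = field(default_factory=ArraySpec)
    range_model: RangeSpec = field(default_factory=RangeSpec)
    movement: MovementSpec = field(default_factory=MovementSpec)
    transmission: TransmissionSpec = field(default_factory=TransmissionSpec)
    hazards: HazardSpec = field(default_factory=HazardSpec)
    pressure: PressureSpec = field(default_factory=PressureSpec)
    position_error: PositionErrorSpec = field(default_factory=PositionErrorSpec)
    dispersal: DispersalSpec = field(default_factory=DispersalSpec)
    t0: str = "2021-01-01"
    depth_mean_m: float = 32.0
    depth_sd_m: float = 1.5
    depth_max_m: float = 38.0

    def __post_init__(self):
        for name in ("base_emigration_per_day", "mortality_per_day",
                     "capture_per_day", "predation_per_day"):
            v = getattr(self.hazards, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"hazard {name}={v} outside [0, 1]")
        if self.transmission.delay_min_s >= self.transmission.delay_max_s:
            raise ValueError("delay_min_s must be < delay_max_s")
        if self.range_model.d50_m <= 0:
            raise ValueError("d50_m must be positive")

    def to_flat_dict(self) -> dict:
        flat = {}
        for key, val in asdict(self).items():
            if isinstance(val, dict):
                flat.update({f"{key}.{k}": v for k, v in val.items()})
            else:
                flat[key] = val
        return flat

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "SimConfig":
        """Build a config from dotted key=value pairs (e.g. array.spacing_m)."""
        cfg = cls()
        for key, val in flat.items():
            if "." in key:
                group, attr = key.split(".", 1)
                sub = getattr(cfg, group)
                if not hasattr(sub, attr):
                    raise KeyError(f"unknown config key {key}")
                setattr(sub, attr, val)
            else:
                if not hasattr(cfg, key):
                    raise KeyError(f"unknown config key {key}")
                setattr(cfg, key, val)
        cfg.__post_init__()
        return cfg


def detection_probability(distance_m, range_spec: RangeSpec, d50=None):
    """p(d) = p0 / (1 + exp(steepness (d − d50))) — midpoint p0/2 at d50."""
    d50 = range_spec.d50_m if d50 is None else d50
    z = range_spec.steepness * (np.asarray(distance_m, dtype=float) - d50)
    return range_spec.p0 / (1.0 + np.exp(np.clip(z, -700, 700)))


# ---------------------------------------------------------------------------
# Array, habitat, environment
# ---------------------------------------------------------------------------

def simulate_array(config: SimConfig) -> pd.DataFrame:
    """Grid receiver array at the configured spacing, origin at (0, 0)."""
    a = config.array
    if a.n_rows < 2 or a.n_cols < 2:
        raise ValueError("array grid must be at least 2 x 2")
    if a.spacing_m <= 0:
        raise ValueError("spacing_m must be positive")
    t0 = pd.Timestamp(config.t0)
    rows = []
    for i in range(a.n_rows):
        for j in range(a.n_cols):
            rows.append({
                "receiver_id": f"R{i:02d}{j:02d}",
                "x_m": j * a.spacing_m,
                "y_m": i * a.spacing_m,
                "deploy_date": t0,
                "recover_date": t0 + pd.Timedelta(days=config.study_days),
                "station_name": f"st-{i}-{j}",
                "array_label": "synthetic",
                "habitat_label": "",
            })
    return pd.DataFrame(rows)


def simulate_habitat(config: SimConfig, receivers: pd.DataFrame) -> HabitatMap:
    """Habitat polygons aligned to the array: an AR patch, a ledge strip and
    a hard-bottom (HB) rectangle; everything else is sand."""
    x0, x1 = receivers.x_m.min(), receivers.x_m.max()
    y0, y1 = receivers.y_m.min(), receivers.y_m.max()
    w, h = x1 - x0, y1 - y0
    hb = box(x0 + 0.15 * w, y0 + 0.10 * h, x0 + 0.75 * w, y0 + 0.60 * h)
    ledge = box(x0 + 0.20 * w, y0 + 0.80 * h, x0 + 0.20 * w + 450.0, y0 + 0.80 * h + 60.0)
    ar_cx, ar_cy = x0 + 0.85 * w, y0 + 0.75 * h
    ar = box(ar_cx - 15.0, ar_cy - 15.0, ar_cx + 15.0, ar_cy + 15.0)
    return HabitatMap({"HB": hb, "ledge": ledge, "AR": ar})


def array_hull(receivers: pd.DataFrame) -> Polygon:
    return MultiPoint(list(zip(receivers.x_m, receivers.y_m))).convex_hull


def simulate_environment(config: SimConfig, rng=None) -> pd.DataFrame:
    """Daily pressure series with Bernoulli(low_day_prob) low-pressure days.

    The returned frame carries the ground-truth ``is_low_true`` column in
    addition to the ``environment`` schema columns.
    """
    rng = rng if rng is not None else child_rng(config.seed, "environment")
    p = config.pressure
    n = int(config.study_days)
    dates = pd.date_range(config.t0, periods=n, freq="D")
    is_low = rng.random(n) < p.low_day_prob
    pressure = np.where(
        is_low,
        p.low_mbar + rng.normal(0.0, 0.8, n),
        p.regular_mbar + rng.normal(0.0, 2.5, n),
    )
    temp = 22.0 + 4.0 * np.sin(2 * np.pi * (np.arange(n) % 365) / 365.0) + rng.normal(0, 0.4, n)
    tilt = np.abs(rng.normal(2.0, 1.0, n))
    return pd.DataFrame({
        "date": dates, "atm_pressure_mbar": pressure,
        "bottom_temp_C": temp, "tilt_deg": tilt, "is_low_true": is_low,
    })


# ---------------------------------------------------------------------------
# True tracks
# ---------------------------------------------------------------------------

@dataclass
class TrueTrack:
    tag_id: str
    tag_day: int                      # day index of tagging within the study
    times_s: np.ndarray               # seconds since study t0
    x: np.ndarray
    y: np.ndarray
    depth: np.ndarray
    fate: str
    fate_day: int                     # day index (from tagging) of the event
    centroids: list                   # [(start_day_from_tagging, x, y), ...]
    dest_xy: Optional[tuple] = None   # emigrant/predator off-array endpoint
    last_transmit_s: float = 0.0      # tag silent after this (capture)

    @property
    def dispersal_m(self) -> float:
        if self.dest_xy is None:
            return 0.0
        dx = self.dest_xy[0] - self.centroids[0][1]
        dy = self.dest_xy[1] - self.centroids[0][2]
        return float(np.hypot(dx, dy))


@dataclass
class TrueTrackSet:
    tracks: list
    t0: pd.Timestamp
    study_days: int
    config: SimConfig

    def fate_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"tag_id": t.tag_id, "fate": t.fate, "fate_day": t.fate_day,
             "tag_day": t.tag_day, "dispersal_m": t.dispersal_m}
            for t in self.tracks
        ])


def _ou_segment(rng, n, start, centroid, sd, phi):
    """AR(1)/discrete-OU path of length n starting at `start`, relaxing to
    `centroid` with per-step autocorrelation phi and stationary SD sd."""
    if n <= 0:
        return np.empty(0)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), n)
    # x_t − c = phi (x_{t−1} − c) + eps_t, run by linear filtering
    out, _ = lfilter([1.0], [1.0, -phi], eps, zi=[phi * (start - centroid)])
    return centroid + out


def _habitat_site(rng, receivers, habitat: HabitatMap):
    """A habitat-biased centroid location: AR, ledge, or a point in HB."""
    choice = rng.choice(["HB", "ledge", "AR"], p=[0.62, 0.21, 0.17])
    poly = habitat.polygons[choice]
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(100):
        x, y = rng.uniform(minx, maxx), rng.uniform(miny, maxy)
        if poly.contains(Point(x, y)):
            return x, y, choice
    return (minx + maxx) / 2, (miny + maxy) / 2, choice


def simulate_tracks(config: SimConfig, receivers: pd.DataFrame,
                    environment: pd.DataFrame,
                    habitat: Optional[HabitatMap] = None) -> TrueTrackSet:
    """Per-fish ground-truth tracks under daily competing risks.

    Each fish resides as an OU walk around its current centroid; centroids
    shift as Bernoulli(shift_prob_per_day) jumps to new habitat-biased
    locations. Daily hazards (emigration × low-pressure multiplier on low
    days, mortality, predation, capture) compete; the first event fixes the
    fate. Emigrating fish run off-array in a straight line; predated tags
    make a fast, vertically erratic run then leave; dead tags go stationary
    (depth SD < 0.25 m); captured tags stop transmitting instantly.
    """
    rng = child_rng(config.seed, "tracks")
    habitat = habitat if habitat is not None else simulate_habitat(config, receivers)
    mv = config.movement
    hz = config.hazards
    t0 = pd.Timestamp(config.t0)
    step_s = mv.step_minutes * 60.0
    steps_per_day = int(round(DAY_S / step_s))
    phi = float(np.exp(-mv.step_minutes / mv.ou_tau_minutes))
    is_low = environment["is_low_true"].to_numpy() if "is_low_true" in environment else (
        environment["atm_pressure_mbar"].to_numpy()
        < np.quantile(environment["atm_pressure_mbar"], 0.005))
    n_days = int(config.study_days)
    hull = array_hull(receivers)
    cx_arr, cy_arr = hull.centroid.x, hull.centroid.y
    array_radius = max(receivers.x_m.max() - receivers.x_m.min(),
                       receivers.y_m.max() - receivers.y_m.min()) / 2.0

    p_em = np.where(is_low[:n_days],
                    np.minimum(1.0, hz.base_emigration_per_day * hz.low_pressure_multiplier),
                    hz.base_emigration_per_day)

    tracks = []
    for i in range(config.n_fish):
        frng = child_rng(config.seed, "fish", i)
        tag_day = 0
        x0, y0, _ = _habitat_site(frng, receivers, habitat)

        # --- daily competing risks ------------------------------------
        fate, fate_day = "survived", n_days - tag_day
        for d in range(tag_day, n_days):
            u = frng.random(4)
            if u[0] < p_em[d]:
                fate, fate_day = "emigrated", d - tag_day
                break
            if u[1] < hz.mortality_per_day:
                fate, fate_day = "mortality", d - tag_day
                break
            if u[2] < hz.predation_per_day:
                fate, fate_day = "predated", d - tag_day
                break
            if u[3] < hz.capture_per_day:
                fate, fate_day = "captured", d - tag_day
                break

        # --- resident path up to the event ----------------------------
        n_steps = max(1, fate_day * steps_per_day)
        shift_days = np.nonzero(frng.random(fate_day) < mv.shift_prob_per_day)[0][
            : mv.n_centroids_max - 1]
        seg_bounds = [0] + [int(d * steps_per_day) for d in shift_days if d > 0] + [n_steps]
        centroids = [(0, x0, y0)]
        xs, ys = [], []
        cur_x, cur_y = x0, y0
        cen_x, cen_y = x0, y0
        for s0, s1 in zip(seg_bounds[:-1], seg_bounds[1:]):
            if s0 > 0:
                cen_x, cen_y, _ = _habitat_site(frng, receivers, habitat)
                centroids.append((int(s0 // steps_per_day), cen_x, cen_y))
                # relocate quickly to the new centroid before resuming OU
                cur_x, cur_y = cen_x, cen_y
            seg_x = _ou_segment(frng, s1 - s0, cur_x, cen_x, mv.centroid_sd_m, phi)
            seg_y = _ou_segment(frng, s1 - s0, cur_y, cen_y, mv.centroid_sd_m, phi)
            if len(seg_x):
                cur_x, cur_y = seg_x[-1], seg_y[-1]
            xs.append(seg_x)
            ys.append(seg_y)
        x = np.concatenate(xs) if xs else np.array([x0])
        y = np.concatenate(ys) if ys else np.array([y0])
        n_steps = len(x)

        depth_eps = frng.normal(0, config.depth_sd_m * 0.35, n_steps)
        depth, _ = lfilter([1.0], [1.0, -0.95], depth_eps, zi=[0.0])
        depth = np.clip(config.depth_mean_m + depth, 0.0, config.depth_max_m)
        times = (tag_day * DAY_S) + np.arange(n_steps) * step_s

        dest_xy = None
        last_transmit_s = times[-1] if len(times) else tag_day * DAY_S

        if fate in ("emigrated", "predated"):
            speed = mv.emigration_speed_mps if fate == "emigrated" else mv.predation_speed_mps
            ex, ey = x[-1], y[-1]
            theta = frng.uniform(0, 2 * np.pi)
            # head outward from the array center
            vx, vy = ex - cx_arr, ey - cy_arr
            norm = np.hypot(vx, vy)
            if norm < 1.0:
                vx, vy = np.cos(theta), np.sin(theta)
                norm = 1.0
            run_len = array_radius + 2500.0
            if fate == "predated":
                # shark-like phase: fast correlated cruise inside the array,
                # then a directed exit
                n_cruise = max(2, int(mv.predation_run_hours * 3600 / step_s))
                heading = frng.uniform(0, 2 * np.pi) + np.cumsum(
                    frng.normal(0, 0.5, n_cruise))
                step_len = speed * step_s
                cx = ex + np.cumsum(step_len * np.cos(heading))
                cy = ey + np.cumsum(step_len * np.sin(heading))
                xspan = (receivers.x_m.min(), receivers.x_m.max())
                yspan = (receivers.y_m.min(), receivers.y_m.max())
                cx = _reflect(cx, *xspan)
                cy = _reflect(cy, *yspan)
                n_exit = max(2, int(run_len / step_len))
                frac = np.arange(1, n_exit + 1) / n_exit
                run_x = np.concatenate([cx, cx[-1] + vx / norm * run_len * frac])
                run_y = np.concatenate([cy, cy[-1] + vy / norm * run_len * frac])
                n_run = n_cruise + n_exit
            else:
                n_run = max(2, int(run_len / (speed * step_s)))
                frac = np.arange(1, n_run + 1) / n_run
                run_x = ex + vx / norm * run_len * frac + frng.normal(0, 15.0, n_run)
                run_y = ey + vy / norm * run_len * frac + frng.normal(0, 15.0, n_run)
            if fate == "predated":
                run_d = config.depth_mean_m / 2 + (config.depth_mean_m / 2 - 2) * np.sin(
                    np.linspace(0, 6 * np.pi, n_run)) + frng.normal(0, 1.0, n_run)
            else:
                run_d = np.full(n_run, depth[-1]) + frng.normal(0, 0.5, n_run)
            x = np.concatenate([x, run_x])
            y = np.concatenate([y, run_y])
            depth = np.concatenate([depth, np.clip(run_d, 0, config.depth_max_m)])
            times = np.concatenate([times, times[-1] + np.arange(1, n_run + 1) * step_s])
            dist = _draw_burr(frng, config.dispersal) if fate == "emigrated" else run_len
            dest_xy = (centroids[0][1] + vx / norm * max(dist, run_len),
                       centroids[0][2] + vy / norm * max(dist, run_len))
            last_transmit_s = times[-1]
        elif fate == "mortality":
            n_rest = (n_days - tag_day) * steps_per_day - n_steps
            if n_rest > 0:
                x = np.concatenate([x, np.full(n_rest, x[-1])])
                y = np.concatenate([y, np.full(n_rest, y[-1])])
                depth = np.concatenate([depth, depth[-1] + frng.normal(0, 0.03, n_rest)])
                times = np.concatenate([times, times[-1] + np.arange(1, n_rest + 1) * step_s])
            last_transmit_s = times[-1]
        elif fate == "captured":
            last_transmit_s = times[-1]
        else:  # survived
            last_transmit_s = times[-1]

        tracks.append(TrueTrack(
            tag_id=f"F{i:03d}", tag_day=tag_day, times_s=times.astype(float),
            x=x, y=y, depth=depth, fate=fate, fate_day=int(fate_day),
            centroids=centroids, dest_xy=dest_xy,
            last_transmit_s=float(last_transmit_s),
        ))
    return TrueTrackSet(tracks=tracks, t0=t0, study_days=n_days, config=config)


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold a coordinate path back into [lo, hi] by reflection."""
    span = hi - lo
    if span <= 0:
        return np.clip(v, lo, hi)
    w = np.mod(v - lo, 2 * span)
    return lo + np.where(w > span, 2 * span - w, w)


def _draw_burr(rng, spec: DispersalSpec) -> float:
    """Inverse-CDF draw from Burr XII: S(x) = (1 + (x/s)^c)^(−k)."""
    u = rng.random()
    return spec.scale_m * ((1.0 - u) ** (-1.0 / spec.k) - 1.0) ** (1.0 / spec.c)


# ---------------------------------------------------------------------------
# Detections and positions
# ---------------------------------------------------------------------------

def simulate_detections(tracks: TrueTrackSet, receivers: pd.DataFrame,
                        config: Optional[SimConfig] = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transmission, detection and triangulation for every true track.

    Transmissions fire at Uniform(delay_min, delay_max) intervals; each
    receiver detects independently with the logistic range curve; any
    transmission heard by >= 3 receivers becomes a position at the true
    location plus isotropic Gaussian error of SD error_per_hpe_m · HPE,
    HPE ~ Gamma (right-skewed).
    """
    config = config if config is not None else tracks.config
    rng = child_rng(config.seed, "detections")
    tx_spec, rg, pe = config.transmission, config.range_model, config.position_error
    rx = receivers[["x_m", "y_m"]].to_numpy(dtype=float)
    rx_ids = receivers["receiver_id"].to_numpy()
    det_parts, pos_parts = [], []
    max_range = rg.d50_m + 12.0 / rg.steepness  # p < ~1e-5 beyond this

    for tr in tracks.tracks:
        t_start, t_end = tr.times_s[0], tr.last_transmit_s
        n_tx = int((t_end - t_start) / tx_spec.delay_min_s) + 2
        delays = rng.uniform(tx_spec.delay_min_s, tx_spec.delay_max_s, n_tx)
        tx_t = t_start + np.cumsum(delays)
        tx_t = tx_t[tx_t <= t_end]
        if len(tx_t) == 0:
            continue
        tx_x = np.interp(tx_t, tr.times_s, tr.x)
        tx_y = np.interp(tx_t, tr.times_s, tr.y)
        tx_d = np.interp(tx_t, tr.times_s, tr.depth)
        # crude cull: skip transmissions far outside the array bounding box
        in_reach = (
            (tx_x > rx[:, 0].min() - max_range) & (tx_x < rx[:, 0].max() + max_range)
            & (tx_y > rx[:, 1].min() - max_range) & (tx_y < rx[:, 1].max() + max_range)
        )
        tx_t, tx_x, tx_y, tx_d = tx_t[in_reach], tx_x[in_reach], tx_y[in_reach], tx_d[in_reach]
        if len(tx_t) == 0:
            continue
        for lo in range(0, len(tx_t), 50_000):
            sl = slice(lo, lo + 50_000)
            dx = tx_x[sl, None] - rx[None, :, 0]
            dy = tx_y[sl, None] - rx[None, :, 1]
            dist = np.hypot(dx, dy)
            p = detection_probability(dist, rg)
            hit = rng.random(p.shape) < p
            n_det = hit.sum(axis=1)
            ti, ri = np.nonzero(hit)
            if len(ti):
                det_parts.append(pd.DataFrame({
                    "tag_id": tr.tag_id,
                    "receiver_id": rx_ids[ri],
                    "timestamp": tracks.t0 + pd.to_timedelta(
                        np.floor(tx_t[sl][ti]), unit="s"),
                    "depth_m": tx_d[sl][ti],
                }))
            posi = np.nonzero(n_det >= 3)[0]
            if len(posi):
                hpe = rng.gamma(pe.hpe_shape, pe.hpe_scale, len(posi))
                sd = pe.error_per_hpe_m * hpe
                pos_parts.append(pd.DataFrame({
                    "tag_id": tr.tag_id,
                    "timestamp": tracks.t0 + pd.to_timedelta(
                        np.floor(tx_t[sl][posi]), unit="s"),
                    "x_m": tx_x[sl][posi] + rng.normal(0, 1, len(posi)) * sd,
                    "y_m": tx_y[sl][posi] + rng.normal(0, 1, len(posi)) * sd,
                    "hpe": hpe,
                    "depth_m": tx_d[sl][posi],
                }))
    detections = (pd.concat(det_parts, ignore_index=True) if det_parts
                  else pd.DataFrame(columns=["tag_id", "receiver_id", "timestamp", "depth_m"]))
    positions = (pd.concat(pos_parts, ignore_index=True) if pos_parts
                 else pd.DataFrame(columns=["tag_id", "timestamp", "x_m", "y_m", "hpe", "depth_m"]))
    for df in (detections, positions):
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    detections = detections.sort_values(["tag_id", "timestamp"]).reset_index(drop=True)
    positions = positions.sort_values(["tag_id", "timestamp"]).reset_index(drop=True)
    positions["known_x_m"] = np.nan
    positions["known_y_m"] = np.nan
    return detections, positions


def simulate_relocations(tracks: TrueTrackSet, config: Optional[SimConfig] = None
                         ) -> pd.DataFrame:
    """Recapture and glider relocation records implied by the true fates.

    Captured fish are recaptured at their stop location; a configurable
    fraction of emigrants is later recaptured (dead, off-array) or detected
    alive by the glider near their destination.
    """
    config = config if config is not None else tracks.config
    rng = child_rng(config.seed, "relocations")
    rows = []
    t0 = tracks.t0 if tracks.t0.tzinfo is not None else tracks.t0.tz_localize("UTC")
    for tr in tracks.tracks:
        when = t0 + pd.Timedelta(seconds=float(tr.last_transmit_s))
        if tr.fate == "captured":
            rows.append({"tag_id": tr.tag_id, "timestamp": when,
                         "x_m": tr.x[-1], "y_m": tr.y[-1], "lon": np.nan,
                         "lat": np.nan, "source": "recapture", "alive": False})
        elif tr.fate == "emigrated" and tr.dest_xy is not None:
            u = rng.random()
            if u < config.dispersal.recapture_prob:
                rows.append({"tag_id": tr.tag_id,
                             "timestamp": when + pd.Timedelta(days=30),
                             "x_m": tr.dest_xy[0], "y_m": tr.dest_xy[1],
                             "lon": np.nan, "lat": np.nan,
                             "source": "recapture", "alive": True})
            elif u < config.dispersal.recapture_prob + config.dispersal.glider_prob:
                rows.append({"tag_id": tr.tag_id,
                             "timestamp": when + pd.Timedelta(days=10),
                             "x_m": tr.dest_xy[0], "y_m": tr.dest_xy[1],
                             "lon": np.nan, "lat": np.nan,
                             "source": "glider", "alive": True})
    return pd.DataFrame(rows, columns=["tag_id", "timestamp", "x_m", "y_m",
                                       "lon", "lat", "source", "alive"])


# ---------------------------------------------------------------------------
# Calibration, range trials, daily-emigration shortcuts
# ---------------------------------------------------------------------------

def simulate_calibration_positions(config: SimConfig, n: int,
                                   known_xy: tuple[float, float],
                                   error_scale: float = 1.0,
                                   tag_id: str = "SYNC0",
                                   rng=None) -> pd.DataFrame:
    """Known-location (sync/reference tag) positions for error calibration.

    ``error_scale`` multiplies error_per_hpe_m, letting different array
    regions carry genuinely different error-vs-HPE relationships.
    """
    rng = rng if rng is not None else child_rng(config.seed, "calibration", tag_id)
    pe = config.position_error
    hpe = rng.gamma(pe.hpe_shape, pe.hpe_scale, n)
    sd = pe.error_per_hpe_m * error_scale * hpe
    t0 = pd.Timestamp(config.t0, tz="UTC")
    return pd.DataFrame({
        "tag_id": tag_id,
        "timestamp": t0 + pd.to_timedelta(np.arange(n) * 600, unit="s"),
        "x_m": known_xy[0] + rng.normal(0, 1, n) * sd,
        "y_m": known_xy[1] + rng.normal(0, 1, n) * sd,
        "hpe": hpe,
        "known_x_m": known_xy[0],
        "known_y_m": known_xy[1],
        "depth_m": np.nan,
    })


def simulate_range_trials(config: SimConfig, distances_m, n_per_distance: int,
                          rng=None, d50=None) -> pd.DataFrame:
    """(distance, detected) Bernoulli trials from the logistic range curve."""
    rng = rng if rng is not None else child_rng(config.seed, "range")
    rows = []
    for d in np.asarray(distances_m, dtype=float):
        p = float(detection_probability(d, config.range_model, d50=d50))
        det = rng.random(n_per_distance) < p
        rows.append(pd.DataFrame({"distance_m": d, "detected": det}))
    return pd.concat(rows, ignore_index=True)


def simulate_daily_emigration(config: SimConfig, n_fish: int, study_days: int,
                              rng=None) -> pd.DataFrame:
    """Direct daily-scale cohort simulation for the emigration GLM.

    Returns one row per day: fish at risk, emigrations, and the true
    pressure class — the substrate of the daily-emigration-probability
    model without the expense of full track simulation.
    """
    rng = rng if rng is not None else child_rng(config.seed, "dep")
    hz, pr = config.hazards, config.pressure
    is_low = rng.random(study_days) < pr.low_day_prob
    p = np.where(is_low,
                 np.minimum(1.0, hz.base_emigration_per_day * hz.low_pressure_multiplier),
                 hz.base_emigration_per_day)
    at_risk = np.zeros(study_days, dtype=int)
    emig = np.zeros(study_days, dtype=int)
    alive = n_fish
    for d in range(study_days):
        at_risk[d] = alive
        emig[d] = rng.binomial(alive, p[d]) if alive else 0
        alive -= emig[d]
    dates = pd.date_range(config.t0, periods=study_days, freq="D")
    return pd.DataFrame({"date": dates, "n_at_risk": at_risk,
                         "emigrations": emig, "is_low": is_low})
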