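"""Rule-based terminal-fate classification for tracked fish.

Each fish ends the study in exactly one of: survived, emigrated, mortality
(tag stationary on the bottom), predated (shark-like run, then stationary
or gone), captured (recaptured in the array, or an abrupt stop in the array
interior), or unknown. Rules fire in priority order — hard evidence first:

    recapture in array > stationary > predation > emigration > survival
    > interior abrupt stop (capture) > unknown

Emigration uses three criteria: (1) typical resident movement followed by
movement toward the array edge, then silence; (2) confirmation by a
recapture or a live glider detection outside the array; (3) a group exit —
several tags leaving within 48 h of which at least one is confirmed.
Events inside the capture-tagging-release (CTR) recovery window are flagged
and excluded from downstream event histories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .synthetic import array_hull


class FateConflictError(ValueError):
    """Contradictory evidence, e.g. a live recapture after assigned mortality."""


@dataclass
class FateRuleConfig:
    recovery_days: int = 3
    stationary_depth_sd_m: float = 0.25
    stationary_min_days: int = 7
    group_window_h: float = 48.0
    edge_margin_m: float = 550.0          # ~one receiver spacing
    predation_speed_floor_mps: float = 0.75
    predation_min_duration_h: float = 1.0
    predation_depth_excursion_m: float = 5.0  # bin-to-bin mean-depth jump
    outward_run_min_m: float = 200.0      # final-day displacement for criterion 1
    survival_margin_days: int = 3         # still detected this close to study end

    def __post_init__(self):
        for f in ("recovery_days", "stationary_depth_sd_m", "stationary_min_days",
                  "group_window_h", "edge_margin_m", "predation_speed_floor_mps"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


# ---------------------------------------------------------------------------
# Signature detectors
# ---------------------------------------------------------------------------

def detect_stationary(coas: pd.DataFrame, config: FateRuleConfig | None = None
                      ) -> pd.DataFrame:
    """Maximal runs of days whose depth SD stays below the stationary
    threshold (default 0.25 m) for at least ``stationary_min_days``.

    Input is one tag's COA table; days with fewer than 3 depth values are
    treated as non-stationary (insufficient evidence). Returns one row per
    interval: start_date, end_date, n_days.
    """
    config = config or FateRuleConfig()
    if coas.empty or coas["mean_depth_m"].isna().all():
        import warnings
        warnings.warn("no depth data: stationary detection skipped", stacklevel=2)
        return pd.DataFrame(columns=["start_date", "end_date", "n_days"])
    df = coas.assign(date=coas["bin_start"].dt.normalize())
    daily = df.groupby("date")["mean_depth_m"].agg(["std", "count"])
    flat = (daily["std"] < config.stationary_depth_sd_m) & (daily["count"] >= 3)
    flat_dates = sorted(daily.index[flat])
    rows = []
    i = 0
    while i < len(flat_dates):
        j = i
        while (j + 1 < len(flat_dates)
               and (flat_dates[j + 1] - flat_dates[j]).days == 1):
            j += 1
        n = (flat_dates[j] - flat_dates[i]).days + 1
        if n >= config.stationary_min_days:
            rows.append({"start_date": flat_dates[i], "end_date": flat_dates[j],
                         "n_days": n})
        i = j + 1
    return pd.DataFrame(rows, columns=["start_date", "end_date", "n_days"])


def _sustained_fast_runs(coas: pd.DataFrame, config: FateRuleConfig) -> list:
    """Timestamps starting sustained runs outside the resident envelope:
    displacement rate above the predator speed floor and/or bin-to-bin
    mean-depth jumps beyond anything the study species shows, sustained for
    at least predation_min_duration_h."""
    df = coas.sort_values("bin_start")
    if len(df) < 3:
        return []
    dt = df["bin_start"].diff().dt.total_seconds().to_numpy()
    dx = df["x_m"].diff().to_numpy()
    dy = df["y_m"].diff().to_numpy()
    ddepth = np.abs(df["mean_depth_m"].diff().to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.hypot(dx, dy) / dt
    signature = (rate > config.predation_speed_floor_mps) | (
        ddepth > config.predation_depth_excursion_m)
    fast = signature & (dt > 0) & (dt <= 3600 * 6)
    runs = []
    i = 1
    while i < len(fast):
        if fast[i]:
            j = i
            dur = 0.0
            while j < len(fast) and fast[j]:
                dur += dt[j]
                j += 1
            if dur >= config.predation_min_duration_h * 3600:
                runs.append(df["bin_start"].iloc[i - 1])
            i = j
        else:
            i += 1
    return runs


def detect_predation_signature(coas: pd.DataFrame,
                               config: FateRuleConfig | None = None,
                               study_end: pd.Timestamp | None = None
                               ) -> tuple[bool, pd.Timestamp | None]:
    """Flag a shark-like signature: a sustained horizontal run faster than
    anything the study species does, followed by the tag going stationary
    or leaving the array. Fast runs with a normal resident sequel are NOT
    flagged (confirmed red snapper can move as fast as their predators)."""
    config = config or FateRuleConfig()
    if coas.empty or coas["bin_start"].dt.normalize().nunique() < 2:
        return False, None
    runs = _sustained_fast_runs(coas, config)
    if not runs:
        return False, None
    last_seen = coas["bin_start"].max()
    stationary = detect_stationary(coas, config)
    for start in runs:
        # sequel within 2 days: stationary interval or array exit (silence)
        sequel_deadline = start + pd.Timedelta(days=2)
        exited = last_seen <= sequel_deadline and (
            study_end is None or last_seen < study_end - pd.Timedelta(
                days=config.survival_margin_days))
        went_still = any(
            (s.start_date >= start.normalize())
            and (s.start_date <= sequel_deadline.normalize() + pd.Timedelta(days=1))
            for s in stationary.itertuples())
        if exited or went_still:
            return True, start
    return False, None


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_fates(coas: pd.DataFrame, relocations: pd.DataFrame,
                   receivers: pd.DataFrame, study_end: pd.Timestamp,
                   tag_dates: pd.Series | None = None,
                   config: FateRuleConfig | None = None,
                   roster: list | None = None) -> pd.DataFrame:
    """Assign one FateRecord per tag from COAs, relocations and array geometry.

    When a ``roster`` of tagged fish is supplied, fish with no COAs at all
    (never detected past release) still receive a record: fate ``unknown``,
    CTR-flagged, so they are excluded from event histories downstream.
    """
    config = config or FateRuleConfig()
    hull = array_hull(receivers)
    boundary = hull.exterior
    study_end = pd.Timestamp(study_end)
    if study_end.tzinfo is None:
        study_end = study_end.tz_localize("UTC")
    reloc = relocations if relocations is not None else pd.DataFrame(
        columns=["tag_id", "timestamp", "x_m", "y_m", "source", "alive"])

    provisional = {}
    for tag, g in coas.groupby("tag_id"):
        g = g.sort_values("bin_start").reset_index(drop=True)
        tag_date = (pd.Timestamp(tag_dates[tag]) if tag_dates is not None
                    and tag in tag_dates.index else g["bin_start"].iloc[0].normalize())
        if tag_date.tzinfo is None:
            tag_date = tag_date.tz_localize("UTC")
        last_seen = g["bin_start"].max()
        last_xy = Point(g["x_m"].iloc[-1], g["y_m"].iloc[-1])
        evidence, confirmed_by = [], "none"
        fate, fate_date = None, None

        my_reloc = reloc[reloc["tag_id"] == tag]
        recaps = my_reloc[my_reloc["source"] == "recapture"]
        in_array_recap = recaps[[
            hull.buffer(config.edge_margin_m).contains(Point(r.x_m, r.y_m))
            for r in recaps.itertuples()] if len(recaps) else []]
        outside = my_reloc[[
            not hull.buffer(config.edge_margin_m).contains(Point(r.x_m, r.y_m))
            and (r.source == "recapture" or bool(r.alive))
            for r in my_reloc.itertuples()] if len(my_reloc) else []]

        stationary = detect_stationary(g, config)
        pred_flag, pred_date = detect_predation_signature(g, config, study_end)

        if len(in_array_recap):
            if len(stationary) and stationary["start_date"].iloc[0] < \
                    in_array_recap["timestamp"].min().normalize() - pd.Timedelta(days=2):
                raise FateConflictError(
                    f"{tag}: recapture at "
                    f"{in_array_recap['timestamp'].min().date()} conflicts with "
                    f"stationary interval starting "
                    f"{stationary['start_date'].iloc[0].date()}")
            fate = "captured"
            fate_date = min(last_seen, in_array_recap["timestamp"].min())
            evidence.append("RECAPTURE_IN_ARRAY")
            confirmed_by = "recapture"
        elif len(stationary) and not (
                pred_flag and pred_date is not None
                and pred_date <= pd.Timestamp(stationary["start_date"].iloc[0]
                                              ).tz_localize(last_seen.tzinfo)
                + pd.Timedelta(days=2)):
            fate = "mortality"
            fate_date = stationary["start_date"].iloc[0]
            evidence.append("STATIONARY_DEPTH")
        elif pred_flag:
            fate = "predated"
            fate_date = pred_date
            evidence.append("PREDATION_RUN")
        else:
            gone_early = last_seen < study_end - pd.Timedelta(
                days=config.survival_margin_days)
            dist_to_edge = (0.0 if not hull.contains(last_xy)
                            else boundary.distance(last_xy))
            near_edge = dist_to_edge <= config.edge_margin_m
            outward = _final_outward_displacement(g) >= config.outward_run_min_m
            if len(outside):
                fate = "emigrated"
                fate_date = last_seen
                evidence.append("EMIG_C2_CONFIRMED")
                confirmed_by = ("glider" if (outside["source"] == "glider").any()
                                else "recapture")
            elif gone_early and near_edge and outward:
                fate = "emigrated"
                fate_date = last_seen
                evidence.append("EMIG_C1_EDGE")
            elif not gone_early:
                fate = "survived"
                fate_date = study_end
                evidence.append("DETECTED_TO_STUDY_END")
            elif not near_edge:
                fate = "captured"
                fate_date = last_seen
                evidence.append("INTERIOR_ABRUPT_STOP")
            else:
                fate = "unknown"
                fate_date = last_seen
                evidence.append("UNRESOLVED_STOP")
        fate_date = pd.Timestamp(fate_date)
        if fate_date.tzinfo is None:
            fate_date = fate_date.tz_localize("UTC")
        provisional[tag] = {
            "tag_id": tag, "fate": fate, "fate_date": fate_date.normalize(),
            "tag_date": tag_date.normalize(), "evidence": evidence,
            "confirmed_by": confirmed_by, "last_seen": last_seen,
        }

    # --- criterion 3: group exits anchored on a confirmed emigrant --------
    confirmed_exits = [v["last_seen"] for v in provisional.values()
                       if v["fate"] == "emigrated" and v["confirmed_by"] != "none"]
    win = pd.Timedelta(hours=config.group_window_h)
    for v in provisional.values():
        if v["fate"] == "unknown" and any(
                abs(v["last_seen"] - ce) <= win for ce in confirmed_exits):
            v["fate"] = "emigrated"
            v["evidence"].append("EMIG_C3_GROUP")
            v["confirmed_by"] = "group"

    rows = []
    for v in provisional.values():
        ctr = v["fate_date"] <= v["tag_date"] + pd.Timedelta(days=config.recovery_days)
        rows.append({
            "tag_id": v["tag_id"], "fate": v["fate"], "ctr_flag": bool(ctr),
            "fate_date": v["fate_date"], "tag_date": v["tag_date"],
            "evidence": ";".join(v["evidence"]), "confirmed_by": v["confirmed_by"],
        })
    if roster is not None:
        seen = {r["tag_id"] for r in rows}
        for tag in roster:
            if tag in seen:
                continue
            td = (pd.Timestamp(tag_dates[tag]) if tag_dates is not None
                  and tag in getattr(tag_dates, "index", ()) else study_end)
            if td.tzinfo is None:
                td = td.tz_localize("UTC")
            rows.append({"tag_id": tag, "fate": "unknown", "ctr_flag": True,
                         "fate_date": td.normalize(), "tag_date": td.normalize(),
                         "evidence": "NEVER_DETECTED", "confirmed_by": "none"})
    return pd.DataFrame(rows).sort_values("tag_id").reset_index(drop=True)


def _final_outward_displacement(coas: pd.DataFrame) -> float:
    """Displacement of the final observed location from the fish's median
    resident location — large when the last track leg heads away."""
    if len(coas) < 4:
        return np.inf  # too little data to call it resident; let geometry decide
    mx, my = coas["x_m"].median(), coas["y_m"].median()
    return float(np.hypot(coas["x_m"].iloc[-1] - mx, coas["y_m"].iloc[-1] - my))
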