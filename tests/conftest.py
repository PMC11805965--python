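"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pandas as pd
import pytest

import reeftrack as rt
from reeftrack.synthetic import SimConfig


def make_config(**kw) -> SimConfig:
    cfg = SimConfig(seed=kw.pop("seed", 5))
    cfg.n_fish = kw.pop("n_fish", 10)
    cfg.study_days = kw.pop("study_days", 60)
    cfg.array.n_rows = kw.pop("n_rows", 5)
    cfg.array.n_cols = kw.pop("n_cols", 5)
    for k, v in kw.items():
        obj = cfg
        parts = k.split("__")
        for p in parts[:-1]:
            obj = getattr(obj, p)
        setattr(obj, parts[-1], v)
    return cfg


@pytest.fixture(scope="session")
def small_sim():
    """10 fish, 60 d, 5x5 array — mostly survivors; the cheap workhorse."""
    cfg = make_config()
    receivers = rt.simulate_array(cfg)
    habitat = rt.simulate_habitat(cfg, receivers)
    env = rt.simulate_environment(cfg)
    tracks = rt.simulate_tracks(cfg, receivers, env, habitat)
    detections, positions = rt.simulate_detections(tracks, receivers, cfg)
    coas = rt.compute_coas(detections, receivers, 30)
    reloc = rt.simulate_relocations(tracks, cfg)
    return {"cfg": cfg, "receivers": receivers, "habitat": habitat, "env": env,
            "tracks": tracks, "detections": detections, "positions": positions,
            "coas": coas, "relocations": reloc,
            "study_end": tracks.t0 + pd.Timedelta(days=cfg.study_days)}


@pytest.fixture(scope="session")
def fate_cohort():
    """200 fish, 90 d, balanced competing risks with well-separated
    movement signatures — the fate-classification validation cohort."""
    cfg = make_config(seed=3, n_fish=200, study_days=90, n_rows=6, n_cols=6)
    cfg.hazards.base_emigration_per_day = 0.004
    cfg.hazards.low_pressure_multiplier = 1.0  # storms probed elsewhere
    cfg.hazards.mortality_per_day = 0.004
    cfg.hazards.capture_per_day = 0.004
    cfg.hazards.predation_per_day = 0.004
    receivers = rt.simulate_array(cfg)
    habitat = rt.simulate_habitat(cfg, receivers)
    env = rt.simulate_environment(cfg)
    tracks = rt.simulate_tracks(cfg, receivers, env, habitat)
    detections, _ = rt.simulate_detections(tracks, receivers, cfg)
    coas = rt.compute_coas(detections, receivers, 30)
    reloc = rt.simulate_relocations(tracks, cfg)
    fates = rt.classify_fates(coas, reloc, receivers,
                              tracks.t0 + pd.Timedelta(days=cfg.study_days),
                              roster=[t.tag_id for t in tracks.tracks])
    return {"cfg": cfg, "tracks": tracks, "coas": coas, "fates": fates,
            "receivers": receivers, "detections": detections}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
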