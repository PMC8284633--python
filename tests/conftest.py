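import numpy as np
import pytest

from cardioflow import PhantomConfig, make_beating_heart, make_particle_flow


@pytest.fixture(scope="session")
def heart_small():
    """Small clean beating-heart phantom (one cycle)."""
    cfg = PhantomConfig(shape=(16, 32, 32), radii_um=(11.0, 20.0, 17.0),
                        wall_thickness_um=6.0, n_cycles=1, seed=0)
    vol, truth = make_beating_heart(cfg)
    return cfg, vol, truth


@pytest.fixture(scope="session")
def heart64():
    """Registration-scale clean phantom (64^3, one cycle)."""
    cfg = PhantomConfig(shape=(64, 64, 64), n_cycles=1, seed=0)
    vol, truth = make_beating_heart(cfg)
    return cfg, vol, truth


@pytest.fixture(scope="session")
def heart64_cycle_fields(heart64):
    """Demons displacement fields over one full cycle of the 64^3 phantom.

    Shared between the displacement-recovery, cycle-closure and kymograph
    cross-check tests because the 40-pair registration dominates runtime.
    """
    from cardioflow import registration as reg

    cfg, vol, truth = heart64
    fields, vf = reg.register_cycle(vol)
    return cfg, vol, truth, fields, vf


@pytest.fixture(scope="session")
def particle_run():
    """Noisy tracer phantom with detection, linking and velocities attached."""
    from cardioflow import tracking as trk

    cfg = PhantomConfig(noise_sigma=0.1, seed=0)
    vol, truth = make_particle_flow(cfg)
    pre = trk.preprocess_particles(vol, sigma=1.0)
    detections = trk.detect_particles(pre)
    linked = trk.track_velocities(
        trk.filter_tracks(trk.link_tracks(detections), 5), cfg.frame_interval_s
    )
    return cfg, vol, truth, detections, linked


def truth_positions_by_frame(truth):
    out = {}
    for _, tr in truth.trajectories.items():
        for f, p in zip(tr["frames"], tr["positions_um"]):
            out.setdefault(int(f), []).append(p)
    return {f: np.asarray(v) for f, v in out.items()}
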