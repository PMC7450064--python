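import numpy as np
import pytest

import magnetospt as m


@pytest.fixture
def phys():
    return m.PhysicalParams()


@pytest.fixture
def free_trackset():
    """100 free-diffusion tracks at membrane-lipid diffusivity, no loc noise."""
    cfg = m.SimulationConfig(
        D_true=0.13, dt_s=0.02, n_frames=500, n_tracks=100,
        sigma_loc_um=0.0, arena_um=(-1e6, -1e6, 1e6, 1e6), seed=11,
    )
    return m.simulate_tracks(cfg)


@pytest.fixture
def constant_force_trackset():
    """100 tracks pulled by a constant 13.4 fN force toward a distant tip."""
    cfg = m.SimulationConfig(
        D_true=0.13, dt_s=0.1, n_frames=500, n_tracks=100,
        sigma_loc_um=0.01, arena_um=(-1e6, -1e6, 1e6, 1e6), seed=42,
    )
    needle = m.NeedleGeometry(tip_um=(1e5, 0.0), F0_fN=13.4, d0_um=50.0, p=0.0)
    starts = np.zeros((100, 2))
    starts[:, 1] = np.arange(100) * 10.0
    ts = m.simulate_tracks(cfg, needle, start_positions=starts)
    return ts, needle


def straight_track(track_id=0, n=100, v=1.0, dt=0.1, y=0.0):
    """Purely ballistic track moving along +x at velocity v um/s."""
    frames = np.arange(n)
    return m.Trajectory(
        track_id=track_id,
        frames=frames,
        x_um=v * frames * dt,
        y_um=np.full(n, float(y)),
        dt_s=dt,
    )
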