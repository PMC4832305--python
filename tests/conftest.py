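"""Shared fixtures: small simulated movies and tracking helpers.

All fixtures are seeded and deliberately small (tens of frames) so the
full suite stays within a desk-scale runtime budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from mttrack import RunConfig, TrackerConfig, simulate_movie, track_movie


def make_movie(n_frames=40, seed=1, **overrides):
    """Simulate a movie from RunConfig overrides."""
    cfg = RunConfig(seed=seed, **overrides)
    return simulate_movie(
        cfg.lattice_params(),
        cfg.growth_params(),
        cfg.imaging_params(),
        n_frames,
        geometry=cfg.geometry(),
        seed=seed,
        noise=cfg.noise,
        snr_target=cfg.snr_target,
        instantaneous_exposure=cfg.instantaneous_exposure,
    )


NOISELESS = dict(
    noise=False,
    labelling_ratio=1.0,
    d_p_nm2_per_s=0.0,
    sigma_ld_nm=0.0,
    taper_length_nm=0.0,
    instantaneous_exposure=True,
)


def track_errors(movie, cfg: TrackerConfig | None = None):
    """Track a movie and return (axial, lateral) errors of reliable frames."""
    tracks = track_movie(
        movie.frames,
        movie.init_backbone_px,
        movie.gp,
        movie.ip.pixel_size,
        movie.ip.sigma_psf,
        cfg=cfg,
    )
    m = min(len(tracks), len(movie.truth))
    truth = movie.truth.iloc[:m]
    tracks = tracks.iloc[:m]
    rel = tracks["reliability"].to_numpy()
    ex = tracks["end_x_nm"].to_numpy() - truth["true_x_nm"].to_numpy()
    ey = tracks["end_y_nm"].to_numpy() - truth["true_y_nm"].to_numpy()
    return ex[rel], ey[rel], tracks


@pytest.fixture(scope="session")
def noiseless_movie():
    """Blunt, fully labelled, noise-free growth movie (v_g = 50 nm/s)."""
    return make_movie(n_frames=30, seed=7, v_g_nm_per_s=50.0, **NOISELESS)


@pytest.fixture(scope="session")
def noisy_movie():
    """Baseline dynamic movie calibrated to SNR 2.5."""
    return make_movie(n_frames=40, seed=3, snr_target=2.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
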