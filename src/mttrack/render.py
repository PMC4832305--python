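"""Model-convolution rendering of lattice states into noisy movies.

Each labelled subunit contributes an isotropic 2D Gaussian (the PSF
approximation) point-sampled at pixel centres; contributions are summed
over fluorophores and added to a uniform background from labelled free
tubulin.  Subunits exchanged during the exposure contribute with
reduced peak intensity (linearly distributed residence times).  Photon
shot noise is Poisson; the detector applies a scalar gain and a
constant offset (EMCCD excess noise is not simulated per pixel).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import lattice as lat
from .imgprep import snr_box_masks, snr_from_stats

__all__ = [
    "ImagingParams",
    "MovieGeometry",
    "SimulatedMovie",
    "render_expected",
    "exposure_weights",
    "add_noise",
    "to_counts",
    "expected_snr",
    "calibrate_intensity_scale",
    "simulate_movie",
]


@dataclass(frozen=True)
class ImagingParams:
    """Detector and optics parameters.

    ``photons_per_fluorophore`` is the expected peak photon contribution
    of one labelled subunit per exposure; ``background_photons`` is the
    expected photons per pixel per exposure from labelled tubulin in
    solution.  Both scale with the illumination intensity and exposure.
    """

    pixel_size: float = 120.0  # nm
    sigma_psf: float = 135.0  # nm
    photons_per_fluorophore: float = 10.0
    background_photons: float = 10.0
    gain: float = 20.0  # counts per photon
    camera_offset: float = 100.0  # counts
    exposure: float = 0.2  # s

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.sigma_psf <= 0 or self.gain <= 0:
            raise ValueError("pixel_size, sigma_psf and gain must be positive")
        if self.photons_per_fluorophore < 0 or self.background_photons < 0:
            raise ValueError("photon counts must be >= 0")

    def scaled(self, s: float) -> "ImagingParams":
        """Scale the illumination intensity (signal and background together)."""
        return replace(
            self,
            photons_per_fluorophore=self.photons_per_fluorophore * s,
            background_photons=self.background_photons * s,
        )


@dataclass(frozen=True)
class MovieGeometry:
    """Placement of the microtubule within the image frame."""

    width_px: int = 128
    height_px: int = 64
    seed_origin_nm: tuple[float, float] = (500.0, 3840.0)
    axis_angle: float = 0.0
    seed_length_nm: float = 1000.0
    initial_length_nm: float = 3000.0


@dataclass
class SimulatedMovie:
    """A rendered movie plus its ground truth and full parameter set."""

    frames: np.ndarray  # (n_frames, h, w) detector counts
    truth: pd.DataFrame
    lp: lat.LatticeParams
    gp: lat.GrowthParams
    ip: ImagingParams
    geometry: MovieGeometry
    seed: int
    noise: bool = True
    intensity_scale: float = 1.0
    init_backbone_px: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    truth_backbone0_nm: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


def render_expected(
    coords_nm: np.ndarray,
    weights: np.ndarray | float,
    ip: ImagingParams,
    frame_shape: tuple[int, int],
) -> np.ndarray:
    """Expected photon count per pixel for a set of fluorophores.

    ``pixel[i, j] = background + sum_k w_k * P * g(centre_ij - x_k)``
    with ``g`` a unit-peak isotropic Gaussian of width ``sigma_psf``
    point-sampled at the pixel centre (no area integration).
    """
    h, w = frame_shape
    img = np.full((h, w), float(ip.background_photons))
    coords_nm = np.asarray(coords_nm, dtype=float).reshape(-1, 2)
    if coords_nm.shape[0] == 0:
        return img
    weights = np.broadcast_to(np.asarray(weights, dtype=float), coords_nm.shape[:1])

    a = ip.pixel_size
    cx = coords_nm[:, 0] / a - 0.5  # fractional column of each fluorophore
    cy = coords_nm[:, 1] / a - 0.5
    r = int(np.ceil(5.0 * ip.sigma_psf / a)) + 1
    off = np.arange(-r, r + 1)
    j0 = np.rint(cx).astype(int)
    i0 = np.rint(cy).astype(int)
    jj = j0[:, None] + off  # (n, 2r+1)
    ii = i0[:, None] + off
    dx = (jj - cx[:, None]) * a
    dy = (ii - cy[:, None]) * a
    s2 = 2.0 * ip.sigma_psf**2
    gx = np.exp(-dx * dx / s2)
    gy = np.exp(-dy * dy / s2)
    gx *= (jj >= 0) & (jj < w)
    gy *= (ii >= 0) & (ii < h)
    amp = weights * ip.photons_per_fluorophore
    patch = amp[:, None, None] * gy[:, :, None] * gx[:, None, :]
    np.add.at(
        img,
        (np.clip(ii, 0, h - 1)[:, :, None], np.clip(jj, 0, w - 1)[:, None, :]),
        patch,
    )
    return img


def exposure_weights(
    n_present: int,
    added: list[int],
    removed: list[int],
    exposure: float,
    frame_interval: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak-intensity weights for subunits exchanged around one exposure.

    ``added``/``removed`` are indices (into the present/removed
    coordinate arrays) in chronological order of exchange during the
    frame interval.  The exposure occupies the trailing part of the
    interval; of the ``n`` exchanged subunits the last
    ``K = round(n * exposure / frame_interval)`` fall inside the
    exposure window and receive residence-time weights evenly spaced in
    (0, 1): the j-th of K added subunits gets ``(K - j + 1)/(K + 1)``
    (latest lowest), the j-th of R removed gets ``j/(R + 1)`` (earliest
    lowest).  Subunits present for the whole exposure get weight 1.
    """
    frac = exposure / frame_interval
    w_present = np.ones(n_present)
    k = int(round(len(added) * frac))
    for j, idx in enumerate(added[len(added) - k :], start=1):
        w_present[idx] = (k - j + 1) / (k + 1)
    r = int(round(len(removed) * frac))
    w_removed = np.zeros(len(removed))
    for j, idx in enumerate(removed[len(removed) - r :], start=1):
        w_removed[idx] = j / (r + 1)
    return w_present, w_removed


def add_noise(
    mean_image: np.ndarray, ip: ImagingParams, rng: np.random.Generator
) -> np.ndarray:
    """Poisson photon noise, then gain and constant camera offset (uint16)."""
    mean_image = np.asarray(mean_image, dtype=float)
    if np.any(mean_image < 0):
        raise ValueError("mean photon image must be non-negative")
    photons = rng.poisson(mean_image)
    counts = photons * ip.gain + ip.camera_offset
    return np.clip(np.rint(counts), 0, np.iinfo(np.uint16).max).astype(np.uint16)


def to_counts(mean_image: np.ndarray, ip: ImagingParams) -> np.ndarray:
    """Noiseless detector counts (float; no quantization)."""
    return np.asarray(mean_image, dtype=float) * ip.gain + ip.camera_offset


def expected_snr(
    expected: np.ndarray,
    end_nm: np.ndarray,
    axis_angle: float,
    ip: ImagingParams,
    backbone_nm: np.ndarray | None = None,
) -> float:
    """SNR the box measurement would converge to for an expected image.

    Combines the spatial variance of the expected counts with the mean
    per-pixel shot variance ``gain^2 * mu``.
    """
    mt, bk = snr_box_masks(
        expected.shape, end_nm, axis_angle, ip.pixel_size, ip.sigma_psf, backbone_nm
    )
    g2 = ip.gain**2
    return snr_from_stats(
        ip.gain * expected[mt].mean() + ip.camera_offset,
        ip.gain * expected[bk].mean() + ip.camera_offset,
        g2 * (expected[mt].var() + expected[mt].mean()),
        g2 * (expected[bk].var() + expected[bk].mean()),
    )


def calibrate_intensity_scale(
    expected_unit: np.ndarray,
    end_nm: np.ndarray,
    axis_angle: float,
    ip: ImagingParams,
    snr_target: float,
    backbone_nm: np.ndarray | None = None,
) -> float:
    """Intensity scale ``s`` such that ``s * expected`` hits an SNR target.

    With both signal and background scaling together, the box SNR is
    ``s * D / sqrt(s^2 * V + s * M)`` (D: count difference, V: spatial
    variance, M: mean shot variance per photon), which is solved for
    ``s`` in closed form.  SNR saturates at ``D / sqrt(V)``; targets at
    or above the saturation level raise ``ValueError``.
    """
    mt, bk = snr_box_masks(
        expected_unit.shape, end_nm, axis_angle, ip.pixel_size, ip.sigma_psf, backbone_nm
    )
    d = expected_unit[mt].mean() - expected_unit[bk].mean()
    v = expected_unit[mt].var() + expected_unit[bk].var()
    m = expected_unit[mt].mean() + expected_unit[bk].mean()
    if d <= 0:
        raise ValueError("no signal contrast in the SNR boxes")
    t2 = snr_target**2
    if d * d - t2 * v <= 0:
        raise ValueError(
            f"SNR target {snr_target:.2f} above saturation {d / np.sqrt(v):.2f} "
            "for this labelling/geometry"
        )
    return t2 * m / (d * d - t2 * v)


def _frame_emitters(
    state: lat.LatticeState,
    lp: lat.LatticeParams,
    gp: lat.GrowthParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray]:
    """Fluorophore frame coordinates and weights, plus deflected truth.

    Returns (coords_nm, weights, end_nm, deflection, backbone_nm).
    Thermal bending is drawn once per frame and applied identically to
    the subunits, the ground-truth tip coordinates and the true
    backbone centreline.
    """
    coords, ids = lat.place_subunits(state, lp)
    rem_coords = lat.removed_subunit_coords(state, lp)
    id_pos = {sid: k for k, sid in enumerate(ids)}
    added_idx = [id_pos[sid] for sid in state.last_added if sid in id_pos]
    w_present, w_removed = exposure_weights(
        len(ids), added_idx, list(range(len(rem_coords))), gp.exposure, gp.frame_interval
    )
    tips = lat.tip_coords_local(state, lp)
    end_local = tips.mean(axis=0)
    centreline = np.column_stack(
        [np.linspace(0.0, end_local[0], 64), np.full(64, end_local[1])]
    )

    n_lab, n_rem = coords.shape[0], rem_coords.shape[0]
    stacked = np.vstack(
        [coords.reshape(-1, 2), rem_coords.reshape(-1, 2), tips, centreline]
    )
    free_length = max(float(stacked[:, 0].max()) - state.clamp_length, 0.0)
    stacked, d = lat.apply_thermal_deflection(
        stacked, gp, state.clamp_length, rng, free_length=free_length
    )
    stacked = lat.to_frame(stacked, state)
    emit = stacked[: n_lab + n_rem]
    weights = np.concatenate([w_present, w_removed])
    keep = weights > 0
    n_pf = lp.n_protofilaments
    end_nm = stacked[n_lab + n_rem : n_lab + n_rem + n_pf].mean(axis=0)
    backbone_nm = stacked[n_lab + n_rem + n_pf :]
    return emit[keep], weights[keep], end_nm, d, backbone_nm


def simulate_movie(
    lp: lat.LatticeParams,
    gp: lat.GrowthParams,
    ip: ImagingParams,
    n_frames: int,
    geometry: MovieGeometry | None = None,
    seed: int = 0,
    noise: bool = True,
    snr_target: float | None = None,
    instantaneous_exposure: bool = False,
) -> SimulatedMovie:
    """Simulate a movie of one dynamic microtubule with ground truth.

    Runs the lattice simulation frame by frame, renders expected photon
    images, optionally rescales the illumination so the first frame
    hits ``snr_target``, and applies the noise model.  The ground-truth
    track records the end position at the end-of-frame lattice state.
    """
    geometry = geometry or MovieGeometry()
    rng = np.random.default_rng(seed)
    state = lat.new_lattice(
        lp,
        gp,
        geometry.seed_length_nm,
        geometry.initial_length_nm,
        seed_origin=geometry.seed_origin_nm,
        axis_angle=geometry.axis_angle,
        rng=rng,
    )
    shape = (geometry.height_px, geometry.width_px)
    if instantaneous_exposure:
        # exposure -> 0: every exchanged subunit is either fully in or out
        gp = replace(gp, exposure=gp.frame_interval * 1e-12)

    expected = np.empty((n_frames,) + shape)
    rows = []
    backbone0_nm: np.ndarray | None = None
    for f in range(n_frames):
        state = lat.step_growth(state, gp, lp, rng)
        emit, weights, end_nm, defl, backbone_nm = _frame_emitters(state, lp, gp, rng)
        if f == 0:
            backbone0_nm = backbone_nm
        expected[f] = render_expected(emit, weights, ip, shape)
        rows.append(
            {
                "frame": f,
                "true_x_nm": end_nm[0],
                "true_y_nm": end_nm[1],
                "length_nm": lat.true_end(state, lp)[0],
                "sigma_pf_nm": lat.sigma_pf(state, lp),
                "deflection_nm": defl,
                "state": "growing" if gp.v_g >= 0 else "shrinking",
            }
        )
    truth = pd.DataFrame(rows)

    scale = 1.0
    if snr_target is not None:
        end0 = truth[["true_x_nm", "true_y_nm"]].iloc[0].to_numpy()
        scale = calibrate_intensity_scale(
            expected[0], end0, geometry.axis_angle, ip, snr_target, backbone0_nm
        )
        expected *= scale
        ip = ip.scaled(scale)

    if noise:
        frames = np.stack([add_noise(e, ip, rng) for e in expected])
    else:
        frames = np.stack([to_counts(e, ip) for e in expected])

    # initial backbone: the true first-frame centreline, as a user would
    # click it, in pixel coordinates
    init_backbone_px = backbone0_nm / ip.pixel_size - 0.5

    return SimulatedMovie(
        frames=frames,
        truth=truth,
        lp=lp,
        gp=gp,
        ip=ip,
        geometry=geometry,
        seed=seed,
        noise=noise,
        intensity_scale=scale,
        init_backbone_px=init_backbone_px,
        truth_backbone0_nm=backbone0_nm,
    )
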