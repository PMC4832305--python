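"""Run configuration, unit bookkeeping and file formats.

A :class:`RunConfig` holds every simulation/tracking setting as a flat
set of fields with units in the names, defaulting to the baseline
imaging condition used throughout the characterization: labelling ratio
0.2, exposure 200 ms, pixel size 120 nm, PSF sigma 135 nm, growth speed
11 nm/s, tip diffusion 271 nm^2/s, lateral deflection SD 150 nm and
taper length 96 nm.

Movies are written as multi-page TIFF (16-bit unsigned for noisy data,
float32 for noiseless renders), ground truth and tracks as CSV, and
run parameters as a JSON/YAML sidecar so any movie can be re-simulated
bit-identically from its metadata.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .lattice import GrowthParams, LatticeParams
from .render import ImagingParams, MovieGeometry
from .track import TrackerConfig

__all__ = ["RunConfig", "write_movie", "read_movie", "write_sidecar", "read_backbone_csv"]


@dataclass
class RunConfig:
    """Flat, serializable configuration for simulate/track/evaluate runs."""

    # lattice
    n_protofilaments: int = 13
    subunit_length_nm: float = 8.0
    lattice_radius_nm: float = 12.5
    helix_start: int = 3
    labelling_ratio: float = 0.2
    # growth
    v_g_nm_per_s: float = 11.0
    d_p_nm2_per_s: float = 271.0
    sigma_ld_nm: float = 150.0
    taper_length_nm: float = 96.0
    frame_interval_s: float = 0.2
    exposure_s: float = 0.2
    # imaging; photon_rate is total detected photons per fluorophore per
    # second, background_factor the free-tubulin background in
    # fluorophore-equivalents per (120 nm)^2 pixel at labelling ratio 1
    # (8.7 ~ 10 uM labelled tubulin in a ~100 nm evanescent field)
    pixel_size_nm: float = 120.0
    sigma_psf_nm: float = 135.0
    photon_rate_per_fluorophore: float = 2000.0
    background_factor: float = 8.7
    gain: float = 20.0
    camera_offset: float = 100.0
    # geometry (frame sized in um so pixel-size sweeps keep the field of view)
    width_um: float = 15.36
    height_um: float = 7.68
    seed_x_um: float = 0.5
    seed_y_um: float = 3.9
    axis_angle_rad: float = 0.0
    seed_length_um: float = 1.0
    initial_length_um: float = 5.0
    # run
    n_frames: int = 100
    seed: int = 0
    noise: bool = True
    snr_target: float | None = None
    instantaneous_exposure: bool = False
    # tracker overrides (field name -> value, see TrackerConfig)
    tracker: dict = field(default_factory=dict)

    # ---- derived parameter objects -------------------------------------
    def lattice_params(self) -> LatticeParams:
        return LatticeParams(
            n_protofilaments=self.n_protofilaments,
            subunit_length=self.subunit_length_nm,
            lattice_radius=self.lattice_radius_nm,
            helix_start=self.helix_start,
            labelling_ratio=self.labelling_ratio,
        )

    def growth_params(self) -> GrowthParams:
        return GrowthParams(
            v_g=self.v_g_nm_per_s,
            D_p=self.d_p_nm2_per_s,
            sigma_LD=self.sigma_ld_nm,
            taper_length=self.taper_length_nm,
            frame_interval=self.frame_interval_s,
            exposure=self.exposure_s,
        )

    def imaging_params(self) -> ImagingParams:
        a, sig = self.pixel_size_nm, self.sigma_psf_nm
        total = self.photon_rate_per_fluorophore * self.exposure_s
        peak = total * a**2 / (2.0 * np.pi * sig**2)
        bg = (
            self.background_factor
            * self.labelling_ratio
            * self.photon_rate_per_fluorophore
            * self.exposure_s
            * (a / 120.0) ** 2
        )
        return ImagingParams(
            pixel_size=a,
            sigma_psf=sig,
            photons_per_fluorophore=peak,
            background_photons=bg,
            gain=self.gain,
            camera_offset=self.camera_offset,
            exposure=self.exposure_s,
        )

    def geometry(self) -> MovieGeometry:
        a = self.pixel_size_nm
        # snap the backbone onto a pixel-row centre so the lateral
        # sampling of the microtubule is reproducible across pixel sizes
        y = (round(self.seed_y_um * 1000.0 / a - 0.5) + 0.5) * a
        return MovieGeometry(
            width_px=int(round(self.width_um * 1000.0 / a)),
            height_px=int(round(self.height_um * 1000.0 / a)),
            seed_origin_nm=(self.seed_x_um * 1000.0, y),
            axis_angle=self.axis_angle_rad,
            seed_length_nm=self.seed_length_um * 1000.0,
            initial_length_nm=self.initial_length_um * 1000.0,
        )

    def tracker_config(self) -> TrackerConfig:
        return TrackerConfig(**self.tracker)

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def write_movie(path: str | Path, frames: np.ndarray) -> None:
    """Write a movie as multi-page TIFF, one page per frame."""
    frames = np.asarray(frames)
    if np.issubdtype(frames.dtype, np.integer):
        data = frames.astype(np.uint16)
    else:
        data = frames.astype(np.float32)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_movie(path: str | Path) -> np.ndarray:
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    return frames


def write_sidecar(path: str | Path, cfg: RunConfig, extra: dict | None = None) -> None:
    """JSON sidecar with the full parameter set and seed of a movie."""
    payload = {"config": cfg.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def read_backbone_csv(path: str | Path) -> np.ndarray:
    """Read an initial backbone polyline CSV with columns x_px, y_px."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        return df[[cols["x_px"], cols["y_px"]]].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError("backbone CSV needs x_px and y_px columns") from exc
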