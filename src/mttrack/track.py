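"""Per-frame microtubule identification and end tracking.

The workflow for every frame: filter (Wiener then Wallis, used only for
segmentation), refine the backbone from the previous frame allowing
perpendicular moves only, sample an axial intensity profile that
extends beyond the current end, weight it with an approximately
Gaussian "proposed growth" function driven by a two-state
(polymerizing / depolymerizing) dynamic model, take the weighted
maximum as the proposed end, build a morphological mask, and hand the
proposal to the sub-pixel 2D fit on the raw, unfiltered frame.

The dynamic state flips only after the end has been undetectable near
its expected position for ``k_switch`` consecutive frames, and never
within ``k_refractory`` frames of the previous flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import savgol_filter

from . import imgprep
from .endfit import EndModelParams, FitResult, fit_end
from .lattice import GrowthParams

__all__ = [
    "TrackerConfig",
    "TrackState",
    "refine_backbone",
    "axial_profile",
    "propose_end",
    "build_mask",
    "track_movie",
]


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable tracking parameters (pixel units unless noted)."""

    search_halfwidth: float = 3.0
    smooth_kernel: int = 3
    wiener_window: int = 3
    wallis_window: int = 15
    wallis_gain_limit: float = 5.0
    k_switch: int = 3
    k_refractory: int = 5
    detection_nsigma: float = 2.0
    dilation_radius: int = 2
    w_min_factor: float = 2.0  # proposal width floor, in units of sigma_PSF
    fit_window_sigmas: float = 6.0  # axial extent beyond the end, in sigma_PSF
    fit_window_back_sigmas: float = 12.0  # axial extent behind the end
    fit_window_lateral_sigmas: float = 4.0
    r2_min: float = 0.2
    variant: str = "wall"


@dataclass
class TrackState:
    """Tracker state carried between frames."""

    backbone: np.ndarray  # (n, 2) [col, row] px, ~1 px arclength spacing
    dyn_state: int = 1  # +1 polymerizing, -1 depolymerizing
    miss_count: int = 0
    refractory_count: int = 10**6  # frames since last state flip
    last_end: np.ndarray = field(default_factory=lambda: np.zeros(2))
    anchor_var: float = 200.0**2  # nm^2, uncertainty of the expected end
    miss_streak: int = 0
    lost: bool = False


def _resample_polyline(points: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a polyline to uniform arclength spacing."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return points[:1].repeat(2, axis=0)
    n = max(int(np.floor(total / spacing)) + 1, 2)
    si = np.linspace(0.0, total, n)
    return np.column_stack(
        [np.interp(si, s, points[:, 0]), np.interp(si, s, points[:, 1])]
    )


def _arclengths(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _tangents(points: np.ndarray) -> np.ndarray:
    t = np.gradient(points, axis=0)
    norm = np.linalg.norm(t, axis=1, keepdims=True)
    return t / np.maximum(norm, 1e-12)


def _sample(frame: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear sampling at [col, row] pixel coordinates."""
    return ndimage.map_coordinates(
        np.asarray(frame, dtype=float),
        [pts[:, 1], pts[:, 0]],
        order=1,
        mode="nearest",
    )


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx * xx + yy * yy) <= r * r


def refine_backbone(
    smoothed_frame: np.ndarray,
    backbone: np.ndarray,
    search_halfwidth: float,
) -> np.ndarray:
    """Move each backbone point to the perpendicular intensity maximum.

    Only displacements perpendicular to the previous axis are allowed;
    the displacement field is smoothed with a local polynomial filter so
    the refined backbone stays a simple curve.  Points whose refined
    position would leave the frame are truncated.
    """
    backbone = _resample_polyline(backbone)
    if search_halfwidth <= 0:
        return backbone
    tang = _tangents(backbone)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(-search_halfwidth, search_halfwidth + 0.25, 0.5)
    cand = backbone[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    vals = ndimage.map_coordinates(
        np.asarray(smoothed_frame, dtype=float),
        [cand[..., 1].ravel(), cand[..., 0].ravel()],
        order=1,
        mode="nearest",
    ).reshape(cand.shape[:2])
    disp = offsets[np.argmax(vals, axis=1)]
    if len(disp) >= 7:
        win = min(15, len(disp) - (1 - len(disp) % 2))
        disp = savgol_filter(disp, window_length=max(win, 5), polyorder=2)
    refined = backbone + disp[:, None] * normal
    # the seed end is surface-immobilized: pin the first point so the
    # backbone cannot drift as perpendicular refinements accumulate
    refined[0] = backbone[0]
    h, w = smoothed_frame.shape
    refined[:, 0] = np.clip(refined[:, 0], 0.0, w - 1.0)
    refined[:, 1] = np.clip(refined[:, 1], 0.0, h - 1.0)
    return _resample_polyline(refined)


def axial_profile(
    frame: np.ndarray,
    backbone: np.ndarray,
    n_extrapolate: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """1D intensity profile along the backbone, extended past the end.

    Samples the frame (bilinear) at the backbone points and at
    ``n_extrapolate`` unit-spaced points continuing along the end
    tangent; off-frame extrapolated points are truncated.  Returns
    ``(profile, arclengths, sample_points)``.
    """
    backbone = np.asarray(backbone, dtype=float)
    tang = _tangents(backbone)[-1]
    extra = backbone[-1] + np.arange(1, n_extrapolate + 1)[:, None] * tang
    h, w = frame.shape
    ok = (
        (extra[:, 0] >= 0)
        & (extra[:, 0] <= w - 1)
        & (extra[:, 1] >= 0)
        & (extra[:, 1] <= h - 1)
    )
    if not ok.all():
        extra = extra[: int(np.argmin(ok))] if not ok.all() else extra
    pts = np.vstack([backbone, extra])
    return _sample(frame, pts), _arclengths(pts), pts


def propose_end(
    profile: np.ndarray,
    arclens: np.ndarray,
    expected_arclen: float,
    ts: TrackState,
    gp: GrowthParams,
    pixel_size: float,
    sigma_psf: float,
    bg_mean: float,
    bg_sd: float,
    cfg: TrackerConfig,
) -> tuple[int, bool, TrackState]:
    """Weighted-maximum end proposal plus dynamic-model update.

    The approximately Gaussian proposal weight is centred on the
    expected end (last end advanced by the state-signed mean growth per
    frame) with width ``sqrt(2 D_p dt + w_min^2) / pixel_size`` where
    ``w_min = w_min_factor * sigma_psf`` — wide enough that transient
    depolymerization episodes stay detectable.  If the weighted
    background-subtracted maximum falls below ``detection_nsigma``
    background SDs the frame counts as a miss; ``k_switch`` consecutive
    misses flip the dynamic state (subject to the refractory period).

    Returns ``(index of proposed end, detected, updated state)``; ties
    in the weighted maximum resolve to the smallest arclength.
    """
    width_nm = np.sqrt(
        2.0 * gp.D_p * gp.frame_interval + (cfg.w_min_factor * sigma_psf) ** 2
    )
    width_px = width_nm / pixel_size
    centre = expected_arclen + ts.dyn_state * gp.v_g * gp.frame_interval / pixel_size
    centre = float(np.clip(centre, arclens[0], arclens[-1]))
    weight = np.exp(-((arclens - centre) ** 2) / (2.0 * width_px**2))
    score = (profile - bg_mean) * weight
    # candidates only where the proposal has support: expected end +- 3 widths
    candidate = np.abs(arclens - centre) <= 3.0 * width_px
    score = np.where(candidate, score, -np.inf)
    idx = int(np.argmax(score))
    detected = bool(score[idx] >= cfg.detection_nsigma * bg_sd)
    if detected:
        # the weighted maximum sits on the bright side of the edge; march
        # towards the tip until the profile falls below half the local
        # plateau, which recovers the apparent end even when the
        # expected position lags behind the true one
        half = bg_mean + 0.5 * (profile[idx] - bg_mean)
        limit = centre + 3.0 * width_px + 2.0 * sigma_psf / pixel_size
        j = idx
        while j + 1 < len(profile) and profile[j + 1] >= half and arclens[j + 1] <= limit:
            j += 1
        idx = j

    ts.refractory_count += 1
    if detected:
        ts.miss_count = 0
        ts.miss_streak = 0
    else:
        ts.miss_count += 1
        ts.miss_streak += 1
        idx = int(np.argmin(np.abs(arclens - expected_arclen)))
        if ts.miss_count >= cfg.k_switch and ts.refractory_count >= cfg.k_refractory:
            ts.dyn_state *= -1
            ts.miss_count = 0
            ts.refractory_count = 0
        if ts.miss_streak >= 2 * cfg.k_switch + cfg.k_refractory:
            ts.lost = True
    return idx, detected, ts


def build_mask(
    shape: tuple[int, int],
    backbone: np.ndarray,
    end_arclen: float,
    dilation_radius: int,
) -> np.ndarray:
    """Binary microtubule mask: accepted backbone pixels up to the
    proposed end, dilated then morphologically closed (stays a single
    connected component for a connected backbone)."""
    s = _arclengths(backbone)
    pts = backbone[s <= end_arclen + 0.5]
    mask = np.zeros(shape, dtype=bool)
    if len(pts) == 0:
        return mask
    jj = np.clip(np.rint(pts[:, 0]).astype(int), 0, shape[1] - 1)
    ii = np.clip(np.rint(pts[:, 1]).astype(int), 0, shape[0] - 1)
    mask[ii, jj] = True
    if dilation_radius > 0:
        footprint = _disk(dilation_radius)
        mask = ndimage.binary_dilation(mask, structure=footprint)
        mask = ndimage.binary_closing(mask, structure=footprint)
    return mask


def _fit_window(
    shape: tuple[int, int],
    end_px: np.ndarray,
    angle: float,
    pixel_size: float,
    sigma_psf: float,
    cfg: TrackerConfig,
) -> np.ndarray:
    """Rotated-box fit window around the proposed end (local fit)."""
    h, w = shape
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    dx = (jj - end_px[0]) * pixel_size
    dy = (ii - end_px[1]) * pixel_size
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (
        (u <= cfg.fit_window_sigmas * sigma_psf)
        & (u >= -cfg.fit_window_back_sigmas * sigma_psf)
        & (np.abs(v) <= cfg.fit_window_lateral_sigmas * sigma_psf)
    )


def _project_arclen(backbone: np.ndarray, point: np.ndarray) -> float:
    """Arclength of the closest backbone sample to ``point``."""
    s = _arclengths(backbone)
    d = np.linalg.norm(backbone - point, axis=1)
    return float(s[int(np.argmin(d))])


def track_movie(
    frames: np.ndarray,
    init_backbone_px: np.ndarray,
    gp: GrowthParams,
    pixel_size: float,
    sigma_psf: float = 135.0,
    cfg: TrackerConfig | None = None,
) -> pd.DataFrame:
    """Track one microtubule end through a movie.

    ``init_backbone_px`` is the user-supplied seed-to-end polyline for
    frame 0 in ``[col, row]`` pixel coordinates.  Filtered images are
    used only to segment and propose; the 2D model fit always receives
    the raw frame.  Returns one row per frame with the fitted end in
    pixels and nm, the model parameters, fit quality and the dynamic
    state.
    """
    cfg = cfg or TrackerConfig()
    frames = np.asarray(frames)
    ts = TrackState(backbone=_resample_polyline(np.asarray(init_backbone_px, float)))
    ts.last_end = ts.backbone[-1].copy()

    rows = []
    for f in range(frames.shape[0]):
        raw = frames[f].astype(float)
        filt = imgprep.wallis_normalize(
            imgprep.wiener_denoise(raw, cfg.wiener_window),
            window=cfg.wallis_window,
            gain_limit=cfg.wallis_gain_limit,
        )
        smoothed = imgprep.smooth(filt, cfg.smooth_kernel)

        backbone = refine_backbone(smoothed, ts.backbone, cfg.search_halfwidth)
        prop_width_nm = np.sqrt(
            2.0 * gp.D_p * gp.frame_interval + (cfg.w_min_factor * sigma_psf) ** 2
        )
        n_extra = int(
            np.ceil(
                (abs(gp.v_g) * gp.frame_interval + 3.0 * prop_width_nm + 2.0 * sigma_psf)
                / pixel_size
            )
        )
        profile, arclens, pts = axial_profile(smoothed, backbone, max(n_extra, 10))

        bg_med = float(np.median(smoothed))
        bg_sd = 1.4826 * float(np.median(np.abs(smoothed - bg_med)))
        expected_arclen = _project_arclen(pts, ts.last_end)
        idx, detected, ts = propose_end(
            profile,
            arclens,
            expected_arclen,
            ts,
            gp,
            pixel_size,
            sigma_psf,
            bg_med,
            max(bg_sd, 1e-9),
            cfg,
        )
        end_px = pts[idx]
        mask = build_mask(raw.shape, pts, arclens[idx], cfg.dilation_radius)

        # initial model parameters from the proposal and robust image stats
        tang = _tangents(pts)[min(idx, len(pts) - 1)]
        angle = float(np.arctan2(tang[1], tang[0]))
        raw_bg = float(np.median(raw))
        inside = arclens <= arclens[idx] - 2.0 * sigma_psf / pixel_size
        raw_profile = _sample(raw, pts)
        plateau = float(np.median(raw_profile[inside])) if inside.sum() >= 3 else float(
            raw_profile[: max(idx, 1)].mean()
        )
        init = EndModelParams(
            end_xy=((end_px[0] + 0.5) * pixel_size, (end_px[1] + 0.5) * pixel_size),
            sigma=sigma_psf,
            amplitude=max(plateau - raw_bg, 1e-3),
            background=raw_bg,
            angle=angle,
        )
        # local fit: a rotated box around the proposed end covering the
        # end ribbon and enough background beyond the tip to pin the edge
        fit_mask = _fit_window(raw.shape, end_px, angle, pixel_size, sigma_psf, cfg)
        fit: FitResult | None
        try:
            fit = fit_end(
                raw,
                fit_mask,
                init,
                variant=cfg.variant,
                pixel_size=pixel_size,
                sigma_psf=sigma_psf,
                r2_min=cfg.r2_min,
            )
        except ValueError:
            fit = None

        # a reliable fit must also stay in the vicinity of the proposal;
        # a fit that jumped away is a noise artefact and must not steer
        # the dynamic model
        consistent = False
        if fit is not None:
            jump_nm = np.linalg.norm(
                np.array(fit.params.end_xy) - (end_px + 0.5) * pixel_size
            )
            consistent = jump_nm <= max(3.0 * prop_width_nm, 3.0 * sigma_psf)
            if not consistent:
                fit.reliability = False

        # variance-weighted anchor update: the dynamic model's expected
        # end moves by the predicted growth each frame and absorbs the
        # measurement (fit if reliable, else the pixel-level proposal)
        # with a gain set by process vs measurement variance, so a noisy
        # measurement cannot drag the track away at low SNR
        process_var = 2.0 * gp.D_p * gp.frame_interval + (
            0.5 * abs(gp.v_g) * gp.frame_interval
        ) ** 2 + 10.0**2
        ts.anchor_var += process_var
        if fit is not None and fit.reliability:
            meas_px = np.array(fit.params.end_xy) / pixel_size - 0.5
            se = np.nan_to_num(fit.param_errors.get("end_x", 50.0), nan=50.0)
            meas_var = float(np.clip(se, 5.0, 500.0)) ** 2
        elif detected:
            meas_px = end_px.copy()
            meas_var = (1.5 * pixel_size) ** 2
        else:
            meas_px = None
            meas_var = np.inf
        s_pred = _project_arclen(pts, ts.last_end) + ts.dyn_state * abs(
            gp.v_g
        ) * gp.frame_interval / pixel_size
        predicted = pts[int(np.argmin(np.abs(arclens - s_pred)))]
        if meas_px is not None:
            gain = ts.anchor_var / (ts.anchor_var + meas_var)
            ts.last_end = predicted + gain * (meas_px - predicted)
            ts.anchor_var *= 1.0 - gain
        else:
            ts.last_end = end_px.copy()

        # carry forward a backbone that covers the microtubule to the end
        end_s = _project_arclen(pts, ts.last_end)
        keep = arclens <= max(end_s, 2.0)
        ts.backbone = _resample_polyline(pts[keep]) if keep.sum() >= 2 else ts.backbone

        p = fit.params if fit is not None else init
        rows.append(
            {
                "frame": f,
                "detected": detected,
                "dyn_state": "polymerizing" if ts.dyn_state > 0 else "depolymerizing",
                "proposed_x_px": end_px[0],
                "proposed_y_px": end_px[1],
                "end_x_px": p.end_xy[0] / pixel_size - 0.5,
                "end_y_px": p.end_xy[1] / pixel_size - 0.5,
                "end_x_nm": p.end_xy[0],
                "end_y_nm": p.end_xy[1],
                "sigma_nm": p.sigma,
                "sigma_end_nm": p.sigma_end_eff,
                "amplitude": p.amplitude,
                "background": p.background,
                "angle_rad": p.angle,
                "r2": fit.r2 if fit is not None else np.nan,
                "reliability": bool(fit.reliability) if fit is not None else False,
                # the end was successfully determined this frame (tracking
                # efficiency); reliability above is the stricter quality
                # flag used to filter downstream statistics
                "tracked": bool(fit is not None and fit.converged and consistent),
                "end_x_err_nm": fit.param_errors.get("end_x", np.nan) if fit else np.nan,
                "end_y_err_nm": fit.param_errors.get("end_y", np.nan) if fit else np.nan,
                "lost": ts.lost,
            }
        )
        if ts.lost:
            break
    return pd.DataFrame(rows)
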