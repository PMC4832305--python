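"""SNR measurement and the pre-segmentation filtering stack.

The signal-to-noise ratio of a microtubule image is defined from two
1.0 um x 0.4 um boxes, one centred on the backbone near the end and one
shifted 1.0 um perpendicular off the microtubule:

    SNR = (I_MT - I_BK) / sqrt(sigma_MT^2 + sigma_BK^2)

with I and sigma the mean and SD of the pixel intensities in each box.

The Wiener/Wallis/averaging filters are used only to segment the
microtubule; the sub-pixel model fit always consumes raw frames.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import px_to_nm, rotate

__all__ = [
    "snr_box_masks",
    "measure_snr",
    "snr_from_stats",
    "wiener_denoise",
    "wallis_normalize",
    "smooth",
]

BOX_LENGTH_NM = 1000.0
BOX_WIDTH_NM = 400.0
BK_OFFSET_NM = 1000.0


def _box_mask(
    shape: tuple[int, int],
    centre_nm: np.ndarray,
    axis_angle: float,
    pixel_size: float,
    length_nm: float = BOX_LENGTH_NM,
    width_nm: float = BOX_WIDTH_NM,
) -> np.ndarray:
    """Pixels whose centres fall in a rotated rectangle (long axis = backbone)."""
    h, w = shape
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    px = px_to_nm(np.stack([jj, ii], axis=-1), pixel_size)
    rel = px - centre_nm
    uv = rotate(rel, -axis_angle)
    return (np.abs(uv[..., 0]) <= length_nm / 2) & (np.abs(uv[..., 1]) <= width_nm / 2)


def snr_box_masks(
    shape: tuple[int, int],
    end_nm: np.ndarray,
    axis_angle: float,
    pixel_size: float,
    sigma_psf: float = 135.0,
    backbone_nm: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of the microtubule and background SNR boxes.

    The microtubule box trails the end along the backbone, its leading
    edge one PSF FWHM behind the end so tip taper does not bias the
    signal estimate; the background box is shifted 1 um perpendicular.
    When a backbone polyline is given (nm coordinates ending at the
    tip), the box centre and orientation follow the local backbone, so
    a thermally bent microtubule stays centred in its box.
    """
    end_nm = np.asarray(end_nm, dtype=float)
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma_psf
    back = fwhm + BOX_LENGTH_NM / 2.0
    if backbone_nm is not None and len(backbone_nm) >= 2:
        bb = np.asarray(backbone_nm, dtype=float)
        seg = np.linalg.norm(np.diff(bb, axis=0), axis=1)
        s_from_end = np.concatenate([[0.0], np.cumsum(seg[::-1])])[::-1]
        k = int(np.argmin(np.abs(s_from_end - back)))
        mt_centre = bb[k]
        k0, k1 = max(k - 1, 0), min(k + 1, len(bb) - 1)
        tang = bb[k1] - bb[k0]
        angle = float(np.arctan2(tang[1], tang[0]))
    else:
        angle = axis_angle
        axis = np.array([np.cos(angle), np.sin(angle)])
        mt_centre = end_nm - back * axis
    perp = np.array([-np.sin(angle), np.cos(angle)])
    bk_centre = mt_centre + BK_OFFSET_NM * perp
    mt = _box_mask(shape, mt_centre, angle, pixel_size)
    bk = _box_mask(shape, bk_centre, angle, pixel_size)
    return mt, bk


def snr_from_stats(i_mt: float, i_bk: float, var_mt: float, var_bk: float) -> float:
    denom = np.sqrt(var_mt + var_bk)
    if denom == 0:
        return 0.0
    return float((i_mt - i_bk) / denom)


def measure_snr(
    frame: np.ndarray,
    end_nm: np.ndarray,
    axis_angle: float,
    pixel_size: float,
    sigma_psf: float = 135.0,
    backbone_nm: np.ndarray | None = None,
) -> float:
    """SNR of one frame given the tracked end position and backbone angle.

    Raises if either box falls (partly) outside the frame or holds
    fewer than 10 pixels.
    """
    frame = np.asarray(frame, dtype=float)
    mt, bk = snr_box_masks(
        frame.shape, end_nm, axis_angle, pixel_size, sigma_psf, backbone_nm
    )
    expected = int(round((BOX_LENGTH_NM / pixel_size) * (BOX_WIDTH_NM / pixel_size)))
    for name, mask in (("microtubule", mt), ("background", bk)):
        n = int(mask.sum())
        if n < 10:
            raise ValueError(f"{name} SNR box holds {n} < 10 pixels")
        if n < 0.7 * expected:
            raise ValueError(f"{name} SNR box extends outside the frame")
    return snr_from_stats(
        frame[mt].mean(), frame[bk].mean(), frame[mt].var(), frame[bk].var()
    )


def wiener_denoise(frame: np.ndarray, window: int = 3) -> np.ndarray:
    """Adaptive local MMSE (Wiener) smoothing; window 1 is the identity.

    The noise variance is estimated as the mean local variance over the
    frame; each pixel is shrunk toward its local mean by the factor
    ``max(var_local - var_noise, 0) / var_local``.  Zero-variance
    regions pass through as their (identical) local mean.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    frame = np.asarray(frame, dtype=float)
    if window == 1:
        return frame.copy()
    local_mean = ndimage.uniform_filter(frame, size=window, mode="reflect")
    local_sq = ndimage.uniform_filter(frame * frame, size=window, mode="reflect")
    local_var = np.maximum(local_sq - local_mean**2, 0.0)
    noise_var = float(local_var.mean())
    shrink = np.divide(
        np.maximum(local_var - noise_var, 0.0),
        local_var,
        out=np.zeros_like(local_var),
        where=local_var > 0,
    )
    return local_mean + shrink * (frame - local_mean)


def wallis_normalize(
    frame: np.ndarray,
    window: int = 15,
    target_mean: float | None = None,
    target_sd: float | None = None,
    gain_limit: float = 5.0,
) -> np.ndarray:
    """Wallis local contrast normalization.

    Maps the local mean to ``target_mean`` and the local SD toward
    ``target_sd`` with the contrast gain clipped to
    ``[1/gain_limit, gain_limit]``, flattening slow illumination
    gradients across the field of view.  Defaults use the global frame
    statistics as targets.
    """
    if gain_limit < 1:
        raise ValueError("gain_limit must be >= 1")
    frame = np.asarray(frame, dtype=float)
    if target_mean is None:
        target_mean = float(frame.mean())
    if target_sd is None:
        target_sd = float(frame.std())
    local_mean = ndimage.uniform_filter(frame, size=window, mode="reflect")
    local_sq = ndimage.uniform_filter(frame * frame, size=window, mode="reflect")
    local_sd = np.sqrt(np.maximum(local_sq - local_mean**2, 0.0))
    gain = np.clip(
        target_sd / np.maximum(local_sd, 1e-12), 1.0 / gain_limit, gain_limit
    )
    return (frame - local_mean) * gain + target_mean


def smooth(frame: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Box-average smoothing with reflective borders; kernel 1 is identity."""
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    frame = np.asarray(frame, dtype=float)
    if kernel == 1:
        return frame.copy()
    return ndimage.uniform_filter(frame, size=kernel, mode="reflect")
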