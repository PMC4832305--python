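"""Coordinate conventions shared across the package.

All physical positions are in nanometres; image arrays are indexed
``[row, col]``.  The centre of pixel ``(i, j)`` sits at
``((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)`` in nm, with the
origin at the image corner.  Every nm <-> pixel conversion in the
package goes through the helpers below so the half-pixel offset lives
in exactly one place.
"""

from __future__ import annotations

import numpy as np


def nm_to_px(coords_nm: np.ndarray, pixel_size: float) -> np.ndarray:
    """Convert ``[x, y]`` nm coordinates to fractional ``[col, row]`` pixels."""
    return np.asarray(coords_nm, dtype=float) / pixel_size - 0.5


def px_to_nm(coords_px: np.ndarray, pixel_size: float) -> np.ndarray:
    """Convert fractional ``[col, row]`` pixel coordinates to nm."""
    return (np.asarray(coords_px, dtype=float) + 0.5) * pixel_size


def pixel_centres(n: int, pixel_size: float) -> np.ndarray:
    """nm coordinates of the centres of ``n`` pixels along one axis."""
    return (np.arange(n) + 0.5) * pixel_size


def rotate(xy: np.ndarray, angle: float) -> np.ndarray:
    """Rotate ``(..., 2)`` coordinates by ``angle`` radians about the origin."""
    c, s = np.cos(angle), np.sin(angle)
    xy = np.asarray(xy, dtype=float)
    out = np.empty_like(xy)
    out[..., 0] = c * xy[..., 0] - s * xy[..., 1]
    out[..., 1] = s * xy[..., 0] + c * xy[..., 1]
    return out
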