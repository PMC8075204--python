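"""Summary images: temporal mean and local correlation.

Both images are z-scored over pixels (subtract the image mean, divide by the
image std) so they can be displayed or fed to a segmentation model on a
common scale.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._filters import butter_highpass
from .io_core import Movie

__all__ = ["mean_image", "correlation_image"]

# the eight chessboard-neighbor offsets
_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


def _zscore_image(img: np.ndarray) -> np.ndarray:
    sd = img.std()
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("degenerate normalization: image is constant; returning zeros")
        return np.zeros_like(img, dtype=np.float64)
    return (img - img.mean()) / sd


def mean_image(movie: Movie) -> np.ndarray:
    """Temporal mean per pixel, z-scored across pixels.

    A constant movie has no contrast to normalize; the function then warns
    and returns zeros.
    """
    if movie.n_frames < 2:
        raise ValueError("mean_image needs at least 2 frames")
    img = movie.data.mean(axis=0).astype(np.float64)
    return _zscore_image(img)


def correlation_image(movie: Movie, highpass_cutoff: float = 1.0 / 3.0) -> np.ndarray:
    """Mean correlation of each pixel with its 8-neighborhood, z-scored.

    The movie is first temporally high-pass filtered (3rd-order zero-phase
    Butterworth at ``highpass_cutoff`` Hz) to remove slow baseline drifts,
    then each pixel's value is the average Pearson correlation of its time
    series with those of its existing chessboard neighbors (edge pixels
    average over fewer than 8). Zero-variance pixels contribute correlation
    0.
    """
    if movie.n_frames < 3:
        raise ValueError("correlation_image needs at least 3 frames")
    Y = butter_highpass(
        movie.data.astype(np.float64), highpass_cutoff, movie.frame_rate, order=3
    )
    T, H, W = Y.shape
    Y = Y - Y.mean(axis=0)
    norm = np.sqrt((Y**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(norm > 0, Y / norm, 0.0)  # unit-norm time series per pixel

    corr_sum = np.zeros((H, W))
    counts = np.zeros((H, W))
    for dr, dc in _NEIGHBOR_OFFSETS:
        r0, r1 = max(0, dr), H + min(0, dr)
        c0, c1 = max(0, dc), W + min(0, dc)
        a = Z[:, r0:r1, c0:c1]
        b = Z[:, r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        corr_sum[r0:r1, c0:c1] += (a * b).sum(axis=0)
        counts[r0:r1, c0:c1] += 1.0
    img = corr_sum / counts
    return _zscore_image(img)
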