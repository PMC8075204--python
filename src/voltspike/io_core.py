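"""Movie, mask and result I/O plus the pipeline configuration.

Conventions used throughout the package: coordinates are 0-based
``(row, col)`` pairs, frame indices are 0-based, and pixel linearization is
row-major.

File formats:

* movies — multipage TIFF, or an HDF5 dataset named ``"mov"`` of shape
  ``(T, H, W)``;
* masks — an HDF5 dataset named ``"masks"`` of shape ``(n, H, W)`` with
  values in {0, 1};
* results — HDF5 with one group ``"neuron_<i>"`` per neuron holding datasets
  ``t, ts, trec, tsub, spikes, template, w`` and attributes ``locality``,
  ``low_confidence`` and ``n_spikes``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, fields, replace

import h5py
import numpy as np
import tifffile

from .errors import MovieFormatError

__all__ = [
    "Movie",
    "MaskSet",
    "PipelineConfig",
    "MovieStore",
    "load_movie",
    "save_movie",
    "load_masks",
    "save_masks",
    "movie_store",
    "save_bundle",
    "load_bundles",
]


@dataclass
class Movie:
    """A fluorescence movie with acquisition metadata.

    Parameters
    ----------
    data
        ``(T, H, W)`` array of fluorescence values (arbitrary units).
    frame_rate
        Sampling rate in Hz; must be positive.
    reverse_polarity
        True for indicators (e.g. Voltron) whose fluorescence *decreases*
        when the membrane voltage increases; the pipeline then sign-inverts
        the movie so spikes point upward.
    """

    data: np.ndarray
    frame_rate: float
    reverse_polarity: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise MovieFormatError(
                f"not a movie: expected a 3-D (T, H, W) array, got "
                f"{self.data.ndim}-D"
            )
        if not np.issubdtype(self.data.dtype, np.number):
            raise MovieFormatError("not a movie: non-numeric data")
        if min(self.data.shape) < 1:
            raise MovieFormatError("not a movie: empty axis")
        if not np.all(np.isfinite(self.data)):
            raise MovieFormatError("movie contains non-finite values")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def fov(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class MaskSet:
    """A list of binary ROI masks sharing one field of view."""

    masks: list[np.ndarray]
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.masks = [np.asarray(m).astype(bool) for m in self.masks]
        if self.masks:
            shape = self.masks[0].shape
            for i, m in enumerate(self.masks):
                if m.ndim != 2 or m.shape != shape:
                    raise ValueError(f"mask {i} does not share the FOV shape")
                if not m.any():
                    raise ValueError(f"mask {i} has no true pixel")
        if self.names is None:
            self.names = [f"neuron_{i}" for i in range(len(self.masks))]

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)


@dataclass
class PipelineConfig:
    """Tunable parameters of the trace-denoising pipeline.

    Defaults are the method's standard settings: background pixels are context
    pixels more than ``n_b`` pixels (Chebyshev) from the ROI, the top
    ``n_pc`` background principal components are regressed out with ridge
    strength ``lambda_b``, the spike/spatial loop runs ``K`` times, and the
    spike template spans ``tau`` frames on each side (20 ms by default).

    ``p1``/``p2`` are the adaptive-threshold stringencies for the first and
    second detection round; ``l1``/``l2`` the simple-threshold noise
    multiples. ``f_bleach``, ``f_spike`` and ``f_sub`` are the photobleaching
    high-pass, spike-band high-pass and subthreshold low-pass corners in Hz.
    """

    context_margin: int = 30
    n_b: int = 12
    n_pc: int = 8
    lambda_b: float = 0.01
    lambda_w: float = 0.01
    K: int = 3
    tau: int | None = None  # None -> round(0.020 s * frame_rate)
    threshold_method: str = "adaptive"
    p1: float = 0.25
    p2: float = 0.5
    l1: float = 3.5
    l2: float = 3.0
    f_bleach: float = 1.0 / 3.0
    f_spike: float = 1.0
    f_sub: float = 20.0
    min_spikes: int = 5
    n_grid: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.p1 <= 1 and 0 < self.p2 <= 1):
            raise ValueError("stringencies p1, p2 must lie in (0, 1]")
        if not (self.l1 > 0 and self.l2 > 0):
            raise ValueError("noise multiples l1, l2 must be > 0")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_pc < 1:
            raise ValueError("n_pc must be >= 1")
        if self.threshold_method not in ("adaptive", "simple"):
            raise ValueError("threshold_method must be 'adaptive' or 'simple'")

    def resolve_tau(self, frame_rate: float) -> int:
        """Template half-width in frames (20 ms bin unless set explicitly)."""
        if self.tau is not None:
            return int(self.tau)
        return max(1, int(round(0.020 * frame_rate)))

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


class MovieStore:
    """Random access into a movie by pixel set and frame range.

    The store satisfies a read-only contract: ``read_pixels`` is a pure view
    (repeated reads are bit-identical) and never materializes more than the
    requested pixels per call. The default backing is the in-memory array of
    the movie, which meets the contract; a memory-mapped array can be passed
    just as well.
    """

    def __init__(self, movie: Movie):
        self.movie = movie
        self._flat = movie.data.reshape(movie.n_frames, -1)
        self._fov = movie.fov

    @property
    def n_frames(self) -> int:
        return self.movie.n_frames

    @property
    def fov(self) -> tuple[int, int]:
        return self._fov

    def _linearize(self, pixels: np.ndarray) -> np.ndarray:
        pixels = np.asarray(pixels)
        if pixels.ndim == 1:  # already linear indices
            lin = pixels.astype(np.intp)
            if lin.size and (lin.min() < 0 or lin.max() >= self._flat.shape[1]):
                raise IndexError("pixel index out of bounds")
            return lin
        if pixels.ndim != 2 or pixels.shape[1] != 2:
            raise ValueError("pixels must be (row, col) pairs or linear indices")
        rows, cols = pixels[:, 0], pixels[:, 1]
        H, W = self._fov
        if pixels.size and (
            rows.min() < 0 or rows.max() >= H or cols.min() < 0 or cols.max() >= W
        ):
            raise IndexError("pixel index out of bounds")
        return (rows * W + cols).astype(np.intp)

    def read_pixels(
        self, pixels: np.ndarray, frames: slice | np.ndarray | None = None
    ) -> np.ndarray:
        """Return a ``T' x N`` matrix of the given pixels' time series.

        ``pixels`` is an ``(N, 2)`` array of 0-based ``(row, col)`` pairs or
        an ``(N,)`` array of row-major linear indices; ``frames`` is a slice
        or index array over frames (all frames when omitted).
        """
        lin = self._linearize(pixels)
        if frames is None:
            frames = slice(None)
        return np.array(self._flat[frames][:, lin])


def movie_store(movie: Movie) -> MovieStore:
    """Wrap a movie in a random-access pixel store."""
    return MovieStore(movie)


def load_movie(
    path: str | os.PathLike,
    frame_rate: float,
    reverse_polarity: bool = False,
) -> Movie:
    """Read a multipage TIFF or HDF5 (dataset ``"mov"``) movie from disk."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as f:
            if "mov" not in f:
                raise MovieFormatError(f"{path}: no 'mov' dataset")
            data = f["mov"][()]
    else:
        data = tifffile.imread(path)
    return Movie(np.asarray(data), frame_rate, reverse_polarity)


def save_movie(movie: Movie, path: str | os.PathLike) -> None:
    """Write a movie to multipage TIFF (.tif/.tiff) or HDF5 (anything else)."""
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, movie.data)
    else:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("mov", data=movie.data)
            d.attrs["frame_rate"] = movie.frame_rate
            d.attrs["reverse_polarity"] = movie.reverse_polarity


def load_masks(path: str | os.PathLike) -> MaskSet:
    """Read an HDF5 ``(n, H, W)`` dataset ``"masks"`` into a MaskSet."""
    with h5py.File(path, "r") as f:
        if "masks" not in f:
            raise MovieFormatError(f"{path}: no 'masks' dataset")
        arr = f["masks"][()]
    if arr.ndim != 3:
        raise MovieFormatError("masks dataset must be (n, H, W)")
    return MaskSet(list(arr.astype(bool)))


def save_masks(masks: MaskSet, path: str | os.PathLike) -> None:
    arr = np.stack([m.astype(np.uint8) for m in masks.masks]) if len(masks) else (
        np.zeros((0, 0, 0), dtype=np.uint8)
    )
    with h5py.File(path, "w") as f:
        f.create_dataset("masks", data=arr)


def save_bundle(bundles: list, path: str | os.PathLike) -> None:
    """Write per-neuron trace bundles to an HDF5 container.

    One group ``neuron_<i>`` per bundle with datasets ``t, ts, trec, tsub,
    spikes, template, w`` and attrs ``locality``, ``low_confidence``,
    ``n_spikes``. Round-trips losslessly through :func:`load_bundles`.
    """
    with h5py.File(path, "w") as f:
        f.attrs["n_neurons"] = len(bundles)
        for i, b in enumerate(bundles):
            g = f.create_group(f"neuron_{i}")
            g.create_dataset("t", data=np.asarray(b.t, dtype=np.float64))
            g.create_dataset("ts", data=np.asarray(b.t_s, dtype=np.float64))
            g.create_dataset("trec", data=np.asarray(b.t_rec, dtype=np.float64))
            g.create_dataset("tsub", data=np.asarray(b.t_sub, dtype=np.float64))
            g.create_dataset("spikes", data=np.asarray(b.s, dtype=np.int64))
            g.create_dataset("template", data=np.asarray(b.z, dtype=np.float64))
            g.create_dataset("w", data=np.asarray(b.w, dtype=np.float64))
            g.attrs["locality"] = bool(b.locality)
            g.attrs["low_confidence"] = bool(b.low_confidence)
            g.attrs["n_spikes"] = int(len(b.s))


def load_bundles(path: str | os.PathLike) -> list:
    """Read bundles written by :func:`save_bundle` (inverse operation)."""
    from .pipeline import TraceBundle  # avoid circular import at module load

    out = []
    with h5py.File(path, "r") as f:
        n = int(f.attrs.get("n_neurons", len(f)))
        for i in range(n):
            g = f[f"neuron_{i}"]
            out.append(
                TraceBundle(
                    t=g["t"][()],
                    t_s=g["ts"][()],
                    t_rec=g["trec"][()],
                    t_sub=g["tsub"][()],
                    s=g["spikes"][()],
                    z=g["template"][()],
                    w=g["w"][()],
                    locality=bool(g.attrs["locality"]),
                    low_confidence=bool(g.attrs["low_confidence"]),
                )
            )
    return out
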