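"""Per-neuron trace extraction: context regions, background removal, the
spike/spatial-filter loop, subthreshold extraction and the locality test.

For each candidate neuron the ROI's bounding box is dilated into a context
region C; pixels of C farther than ``n_b`` (Chebyshev) from the ROI form the
local background B. After sign correction and photobleaching high-pass, the
top ``n_pc`` left singular vectors of the background movie are regressed out
of the trace by ridge regression, spikes are detected and a denoised trace
reconstructed, and a refined spatial filter is obtained by ridge-regressing
the reconstruction on the context movie. The loop runs K times (the filter
and trace are frozen on the final round); the subthreshold signal is the
low-passed residual, and a neuron is accepted only if the context pixel best
correlated with its reconstruction lies inside its own ROI.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import lsqr, svds

from ._filters import butter_highpass, butter_lowpass
from .detect import SpikeResult, denoise_spikes
from .errors import EmptyBackgroundError, VoltSpikeError
from .io_core import MaskSet, Movie, MovieStore, PipelineConfig, movie_store

__all__ = [
    "ContextRegion",
    "TraceBundle",
    "NeuronFailure",
    "build_context",
    "preprocess",
    "initial_trace",
    "background_subtract",
    "refine_spatial_filter",
    "extract_subthreshold",
    "locality_test",
    "process_neuron",
    "run_pipeline",
]


@dataclass
class ContextRegion:
    """Pixel index sets of one neuron: ROI S, context C, background B.

    Each is an ``(n, 2)`` array of 0-based ``(row, col)`` pairs; ``S`` and
    ``B`` are disjoint subsets of ``C``. ``s_cols``/``b_cols`` index the
    corresponding columns of the ``T x |C|`` context matrix (row-major pixel
    order).
    """

    S: np.ndarray
    C: np.ndarray
    B: np.ndarray
    s_cols: np.ndarray
    b_cols: np.ndarray


@dataclass
class TraceBundle:
    """All per-neuron outputs of the pipeline."""

    t: np.ndarray
    t_s: np.ndarray
    t_rec: np.ndarray
    t_sub: np.ndarray
    s: np.ndarray
    z: np.ndarray
    w: np.ndarray
    locality: bool
    low_confidence: bool = False
    history: list = field(default_factory=list, repr=False)


@dataclass
class NeuronFailure:
    """Recorded in a result slot when one neuron's processing raised."""

    index: int
    error: str


def build_context(
    mask: np.ndarray,
    fov: tuple[int, int],
    margin: int = 30,
    n_b: int = 12,
) -> ContextRegion:
    """Build the (S, C, B) pixel sets for one ROI mask.

    C is the mask's bounding box expanded by ``margin`` pixels per side and
    clipped to the FOV; B keeps the pixels of C whose Chebyshev distance to
    every ROI pixel exceeds ``n_b``.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    H, W = fov
    rows, cols = np.nonzero(mask)
    r0, r1 = max(0, rows.min() - margin), min(H - 1, rows.max() + margin)
    c0, c1 = max(0, cols.min() - margin), min(W - 1, cols.max() + margin)

    rr, cc = np.meshgrid(
        np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"
    )
    C = np.column_stack([rr.ravel(), cc.ravel()])  # row-major order

    in_S = mask[C[:, 0], C[:, 1]]
    # Chebyshev distance of every context pixel to the nearest ROI pixel
    cheb = np.maximum(
        np.abs(C[:, 0][:, None] - rows[None, :]),
        np.abs(C[:, 1][:, None] - cols[None, :]),
    ).min(axis=1)
    in_B = cheb > n_b
    if not in_B.any():
        raise EmptyBackgroundError(
            "background set is empty: increase context_margin "
            f"(margin={margin}, n_b={n_b})"
        )
    return ContextRegion(
        S=C[in_S],
        C=C,
        B=C[in_B],
        s_cols=np.flatnonzero(in_S),
        b_cols=np.flatnonzero(in_B),
    )


def preprocess(
    Y: np.ndarray,
    reverse_polarity: bool,
    f_bleach: float,
    frame_rate: float,
) -> np.ndarray:
    """Sign-correct and high-pass the context matrix.

    Reverse-polarity movies are negated so spikes point upward, then each
    pixel's time series is high-passed (3rd-order zero-phase Butterworth at
    ``f_bleach``, 1/3 Hz by default) to remove photobleaching.
    """
    Y = np.asarray(Y)
    if reverse_polarity:
        Y = -Y
    return butter_highpass(Y, f_bleach, frame_rate, order=3, axis=0)


def initial_trace(
    Y_h: np.ndarray, context: ContextRegion, w: np.ndarray | None = None
) -> np.ndarray:
    """Initial temporal trace: ROI mean, or ``Y_h @ w`` if a filter is given.

    The weighted average is literal (not normalized by the weight sum); a
    filter equal to the ROI indicator divided by |S| reproduces the mean.
    """
    Y_h = np.asarray(Y_h)
    if w is None:
        return Y_h[:, context.s_cols].mean(axis=1)
    w = np.asarray(w)
    if w.size != Y_h.shape[1]:
        raise ValueError("spatial filter length does not match context size")
    return Y_h @ w


def _top_left_singular_vectors(Y_b: np.ndarray, n_pc: int) -> np.ndarray:
    """First ``n_pc`` left singular vectors of ``Y_b`` (descending order)."""
    T, M = Y_b.shape
    k = min(n_pc, min(T, M))
    if k < n_pc:
        warnings.warn(
            f"background rank {k} < n_pc={n_pc}; using available components"
        )
    if k >= min(T, M) or min(T, M) < 32:
        U, sv, _ = np.linalg.svd(np.asarray(Y_b, dtype=np.float64), full_matrices=False)
        return U[:, :k]
    # deterministic start vector keeps runs bit-reproducible
    v0 = np.ones(min(T, M))
    U, sv, _ = svds(np.asarray(Y_b, dtype=np.float64), k=k, v0=v0)
    order = np.argsort(sv)[::-1]
    return U[:, order]


def background_subtract(
    t: np.ndarray,
    Y_b: np.ndarray,
    n_pc: int = 8,
    lambda_b: float = 0.01,
    U_b: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove background structure from a trace by ridge regression.

    The trace is regressed on the top ``n_pc`` left singular vectors of the
    background matrix with ridge coefficient ``lambda_b * ||U_b||_F**2``
    (the Frobenius scaling applied literally); the fitted component is
    subtracted. A precomputed ``U_b`` may be supplied to amortize the SVD
    across loop iterations. Returns ``(t_clean, beta)``.
    """
    t = np.asarray(t, dtype=np.float64)
    if U_b is None:
        U_b = _top_left_singular_vectors(np.asarray(Y_b), n_pc)
    G = U_b.T @ U_b + lambda_b * np.linalg.norm(U_b, "fro") ** 2 * np.eye(
        U_b.shape[1]
    )
    beta = np.linalg.solve(G, U_b.T @ t)
    return t - U_b @ beta, beta


def refine_spatial_filter(
    Y_h: np.ndarray, t_rec: np.ndarray, lambda_w: float = 0.01
) -> np.ndarray:
    """Ridge-regress the reconstructed trace on the context movie.

    Solves ``w = (Y_h' Y_h + lambda_w ||Y_h||_F**2 I)^-1 Y_h' t_rec`` with
    the LSQR damped least-squares solver (tolerances tight enough to match
    the dense closed form to ~1e-6 relative).
    """
    Y_h = np.asarray(Y_h)
    t_rec = np.asarray(t_rec, dtype=np.float64)
    damp = float(np.sqrt(lambda_w) * np.linalg.norm(Y_h, "fro"))
    res = lsqr(
        Y_h,
        t_rec,
        damp=damp,
        atol=1e-12,
        btol=1e-12,
        iter_lim=8 * max(Y_h.shape),
    )
    return res[0]


def extract_subthreshold(
    t: np.ndarray, t_rec: np.ndarray, f_sub: float, frame_rate: float
) -> np.ndarray:
    """Low-pass the spike-subtracted residual to the subthreshold band.

    5th-order zero-phase Butterworth at ``f_sub`` (20 Hz default) applied
    to ``t - t_rec``.
    """
    t = np.asarray(t, dtype=np.float64)
    t_rec = np.asarray(t_rec, dtype=np.float64)
    if t.shape != t_rec.shape:
        raise ValueError("t and t_rec must have the same length")
    return butter_lowpass(t - t_rec, f_sub, frame_rate, order=5)


def locality_test(
    Y_h: np.ndarray, t_rec: np.ndarray, context: ContextRegion
) -> bool:
    """True iff the context pixel most correlated with ``t_rec`` is in S.

    Pearson correlation of the reconstruction with every context pixel's
    time series; exact ties count as inside if any tying pixel belongs to
    the ROI. A zero-variance reconstruction (no spikes) cannot certify
    locality and returns False with a warning.
    """
    Y_h = np.asarray(Y_h, dtype=np.float64)
    t_rec = np.asarray(t_rec, dtype=np.float64)
    tc = t_rec - t_rec.mean()
    t_norm = np.linalg.norm(tc)
    if t_norm == 0:
        warnings.warn("zero-variance reconstruction: locality cannot be certified")
        return False
    Yc = Y_h - Y_h.mean(axis=0)
    norms = np.linalg.norm(Yc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(norms > 0, (Yc.T @ tc) / (norms * t_norm), 0.0)
    mx = corr.max()
    winners = np.flatnonzero(corr == mx)
    return bool(np.isin(winners, context.s_cols).any())


def process_neuron(
    store: MovieStore,
    mask: np.ndarray,
    config: PipelineConfig | None = None,
    keep_history: bool = False,
) -> TraceBundle:
    """Run the full per-neuron loop on one ROI mask.

    Context extraction, preprocessing, then K rounds of background
    subtraction -> spike detection; rounds 1..K-1 additionally refine the
    spatial filter and recompute the trace as ``Y_h @ w`` (the final round
    freezes both). Afterwards the subthreshold trace is extracted and the
    locality test decides acceptance. ``keep_history`` records each round's
    :class:`~voltspike.detect.SpikeResult` and input trace for diagnostics.
    """
    if config is None:
        config = PipelineConfig()
    frame_rate = store.movie.frame_rate
    context = build_context(
        mask, store.fov, margin=config.context_margin, n_b=config.n_b
    )
    Y = store.read_pixels(context.C).astype(np.float32)
    Y_h = preprocess(
        Y, store.movie.reverse_polarity, config.f_bleach, frame_rate
    ).astype(np.float32)
    del Y

    t = initial_trace(Y_h, context).astype(np.float64)
    U_b = _top_left_singular_vectors(Y_h[:, context.b_cols], config.n_pc)

    w = np.zeros(Y_h.shape[1])
    w[context.s_cols] = 1.0 / context.s_cols.size
    result: SpikeResult | None = None
    history: list = []
    for k in range(1, config.K + 1):
        t_clean, _beta = background_subtract(
            t, None, config.n_pc, config.lambda_b, U_b=U_b
        )
        result = denoise_spikes(t_clean, frame_rate, config)
        if keep_history:
            history.append((t_clean, result))
        if k < config.K:
            w = refine_spatial_filter(Y_h, result.t_rec, config.lambda_w)
            t = initial_trace(Y_h, context, w=w).astype(np.float64)

    t_sub = extract_subthreshold(t, result.t_rec, config.f_sub, frame_rate)
    loc = locality_test(Y_h, result.t_rec, context)
    return TraceBundle(
        t=t,
        t_s=result.t_s,
        t_rec=result.t_rec,
        t_sub=t_sub,
        s=result.s,
        z=result.z,
        w=w,
        locality=loc,
        low_confidence=result.low_confidence,
        history=history,
    )


def run_pipeline(
    movie: Movie,
    masks: MaskSet,
    config: PipelineConfig | None = None,
    workers: int = 1,
) -> list[TraceBundle | NeuronFailure]:
    """Process every mask; output order matches mask order.

    Neurons are independent, so results do not depend on ``workers`` or on
    scheduling order. A neuron whose processing raises is recorded as a
    :class:`NeuronFailure` in its slot without aborting the others.
    """
    if config is None:
        config = PipelineConfig()
    store = movie_store(movie)
    H, W = movie.fov
    for i, m in enumerate(masks):
        if m.shape != (H, W):
            raise ValueError(f"mask {i} does not match the movie FOV")

    def _one(i: int):
        try:
            return process_neuron(store, masks.masks[i], config)
        except (VoltSpikeError, ValueError) as exc:
            return NeuronFailure(index=i, error=str(exc))

    if workers <= 1 or len(masks) <= 1:
        return [_one(i) for i in range(len(masks))]
    with ThreadPoolExecutor(max_workers=workers) as ex:
        return list(ex.map(_one, range(len(masks))))
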