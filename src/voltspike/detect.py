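"""Spike detection on one fluorescence trace.

The detector runs in two rounds. Round one thresholds the 1 Hz high-passed,
median-subtracted trace (adaptively from the distribution of local-maximum
heights, or simply at a multiple of the noise level) to gather
high-confidence spikes and average them into a template z. A whitened
matched filter — prewhitening in the frequency domain by the Welch noise
spectrum, then cross-correlating with a template recomputed from the
prewhitened trace — enhances waveforms shaped like z, and a second, less
stringent round of thresholding on the filtered trace yields the final
spike set. Convolving the spike train with z reconstructs the denoised
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.stats import gaussian_kde

from ._filters import butter_highpass
from .errors import (
    DegenerateTraceError,
    NoNoiseSamplesError,
    NoTemplateError,
    TooFewPeaksError,
)
from .io_core import PipelineConfig

__all__ = [
    "SpikeResult",
    "local_maxima",
    "adaptive_threshold",
    "simple_threshold",
    "compute_template",
    "whitened_matched_filter",
    "reconstruct",
    "denoise_spikes",
]

#: minimum number of local maxima required to estimate a peak-height KDE
MIN_PEAKS_FOR_KDE = 10


@dataclass
class SpikeResult:
    """Output of :func:`denoise_spikes` for one trace.

    ``t_s`` is the trace after high-pass filtering and (unless the detector
    fell back to a single round) whitened matched filtering; ``s`` the
    sorted spike frame indices; ``z`` the spike template of length
    ``2*tau + 1``; ``t_rec`` the superposition of ``z`` at the spike frames;
    ``threshold_used`` the final-round threshold on ``t_s``.
    """

    t_s: np.ndarray
    s: np.ndarray
    z: np.ndarray
    t_rec: np.ndarray
    threshold_used: float
    low_confidence: bool = False


def local_maxima(x: np.ndarray, height: float | None = None) -> np.ndarray:
    """Indices of strict local maxima of ``x``.

    A sample qualifies when it exceeds both neighbors; for a plateau of
    equal values exceeding both flanks, the first plateau index is
    returned. ``height`` keeps only maxima with value >= height.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        return np.array([], dtype=np.intp)
    _, props = signal.find_peaks(x, plateau_size=1)
    idx = props["left_edges"].astype(np.intp)
    if height is not None:
        idx = idx[x[idx] >= height]
    return idx


def adaptive_threshold(
    t_s: np.ndarray, p: float, n_grid: int = 1000
) -> tuple[np.ndarray, float]:
    """Threshold local maxima of a median-subtracted trace adaptively.

    The distribution of local-maximum heights ``P_max`` is estimated by
    Gaussian KDE (Scott's-rule bandwidth) on an even grid of ``n_grid``
    points. Reflecting ``P_max`` about the median of the heights
    approximates the noise-peak distribution ``P_noise``; with survival
    functions ``F_max``/``F_noise`` built from the two, the threshold is
    the grid point maximizing ``F_max**p - F_noise**p``. Smaller ``p`` is
    more stringent.

    Returns ``(spike indices, h)``: all local maxima of ``t_s`` with height
    >= h.
    """
    t_s = np.asarray(t_s, dtype=np.float64)
    peaks = local_maxima(t_s)
    heights = t_s[peaks]
    if heights.size < MIN_PEAKS_FOR_KDE:
        raise TooFewPeaksError(
            f"too few peaks: {heights.size} local maxima "
            f"(need >= {MIN_PEAKS_FOR_KDE})"
        )
    x = np.linspace(heights.min(), heights.max(), n_grid)
    p_max = gaussian_kde(heights)(x)
    mu = np.median(heights)

    # index of the last grid point strictly below the median
    below = np.flatnonzero(x < mu)
    j = below[-1] if below.size else 0

    # reflect the sub-median part of P_max about the point between j, j+1
    p_noise = np.zeros_like(p_max)
    p_noise[: j + 1] = p_max[: j + 1]
    i = np.arange(j + 1, n_grid)
    src = 2 * j + 1 - i
    valid = src >= 0
    p_noise[i[valid]] = p_max[src[valid]]

    # survival functions and the stringency-weighted contrast
    F_max = np.cumsum(p_max)
    F_noise = np.cumsum(p_noise)
    F_max = F_max[-1] - F_max
    F_noise = F_noise[-1] - F_noise
    g = F_max**p - F_noise**p
    h = float(x[int(np.argmax(g))])
    return peaks[heights >= h], h


def simple_threshold(t_s: np.ndarray, l: float) -> tuple[np.ndarray, float]:
    """Threshold local maxima at ``l`` times the noise level.

    The noise sigma is estimated from the negative samples only
    (``sqrt(mean(t_s[t_s < 0]**2))``), assuming the noise is symmetric
    about the (zero) median. Returns ``(spike indices, l * sigma)``.
    """
    t_s = np.asarray(t_s, dtype=np.float64)
    neg = -t_s[t_s < 0]
    if neg.size == 0:
        raise DegenerateTraceError(
            "degenerate trace: no negative samples, noise level undefined"
        )
    sigma = float(np.sqrt(np.mean(neg**2)))
    thr = l * sigma
    return local_maxima(t_s, height=thr), thr


def compute_template(t_s: np.ndarray, s: np.ndarray, tau: int) -> np.ndarray:
    """Average the +-tau waveform windows around the spikes in ``s``.

    Spikes closer than ``tau`` frames to either trace end are discarded;
    if none survive, a template cannot be formed.
    """
    t_s = np.asarray(t_s, dtype=np.float64)
    s = np.asarray(s, dtype=np.intp)
    T = t_s.size
    keep = s[(s >= tau) & (s <= T - 1 - tau)]
    if keep.size == 0:
        raise NoTemplateError("no template: no spike survives edge trimming")
    windows = np.stack([t_s[i - tau : i + tau + 1] for i in keep])
    return windows.mean(axis=0)


def whitened_matched_filter(
    t_s: np.ndarray, q: np.ndarray, s: np.ndarray, tau: int
) -> np.ndarray:
    """Prewhiten ``t_s`` by its Welch noise spectrum and match the template.

    Noise samples are those farther than ``tau`` frames from every spike
    (``convolve(q, ones(2 tau + 1)) < 0.5``). Their Welch PSD (Hann window,
    50% overlap), interpolated onto the full FFT grid and floored at 1e-10
    of its maximum, rescales the trace's spectrum so the residual noise is
    approximately white. A fresh template from the prewhitened trace is
    then cross-correlated with it ('same' alignment, so peaks stay at spike
    frames).
    """
    t_s = np.asarray(t_s, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    s = np.asarray(s, dtype=np.intp)
    if s.size == 0:
        raise NoTemplateError("whitened matched filter needs a non-empty spike set")
    tw = _prewhiten(t_s, q, tau)
    # zero-mean template: the filter output is then orthogonal to local
    # baseline offsets, which would otherwise scale with sum(z) and can
    # exceed spike peaks near the trace ends
    z_w = compute_template(tw, s, tau)
    z_w = z_w - z_w.mean()
    return signal.correlate(tw, z_w, mode="same")


def _prewhiten(t_s: np.ndarray, q: np.ndarray, tau: int) -> np.ndarray:
    """Rescale the trace's spectrum by the Welch noise amplitude spectrum.

    Noise samples are those farther than ``tau`` frames from every spike of
    the 0/1 train ``q``. For an already-white noise spectrum this is an
    (approximate) identity up to a global scale.
    """
    T = t_s.size
    near_spike = np.convolve(q, np.ones(2 * tau + 1), mode="same")
    noise = t_s[near_spike < 0.5]
    if noise.size == 0:
        raise NoNoiseSamplesError("no noise samples: spikes cover the whole trace")

    nperseg = int(min(1024, max(8, noise.size // 2)))
    f_welch, psd = signal.welch(
        noise, fs=1.0, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    # undo the one-sided edge convention (DC/Nyquist bins are not doubled),
    # so a white spectrum interpolates to a flat scaling
    psd = psd.copy()
    psd[0] *= 2.0
    if nperseg % 2 == 0:
        psd[-1] *= 2.0
    psd = np.maximum(psd, 1e-10 * psd.max())

    # whiten the fluctuation, not the offset: Welch detrends each segment, so
    # its near-zero DC estimate would otherwise blow up the trace's residual
    # mean by orders of magnitude; reflect-pad so the circular FFT does not
    # splice the trace ends together
    pad = min(T - 1, 256)
    x = t_s - t_s.mean()
    xp = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
    freqs = np.abs(np.fft.fftfreq(xp.size, d=1.0))
    s_n = np.interp(freqs, f_welch, np.sqrt(psd))
    return np.real(np.fft.ifft(np.fft.fft(xp) / s_n))[pad : pad + T]


def reconstruct(q: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Superpose the template ``z`` at every spike of the 0/1 train ``q``.

    The template center (index ``tau``) lands on each spike frame; spikes
    near the trace ends contribute truncated copies.
    """
    q = np.asarray(q, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    tau = (z.size - 1) // 2
    full = np.convolve(q, z, mode="full")
    return full[tau : tau + q.size]


def _detect(t_s: np.ndarray, config: PipelineConfig, round_idx: int):
    """One thresholding round; returns (spikes, threshold)."""
    if config.threshold_method == "adaptive":
        p = config.p1 if round_idx == 1 else config.p2
        return adaptive_threshold(t_s, p, config.n_grid)
    l = config.l1 if round_idx == 1 else config.l2
    return simple_threshold(t_s, l)


def denoise_spikes(
    t: np.ndarray,
    frame_rate: float,
    config: PipelineConfig | None = None,
) -> SpikeResult:
    """Two-round spike detection and trace denoising on one trace.

    ``t`` must already be background-subtracted. The trace is high-passed
    at ``config.f_spike`` (5th-order zero-phase Butterworth) and
    median-subtracted; round one detects template spikes, the whitened
    matched filter enhances them, and round two detects the final spike
    set on the filtered trace. ``t_rec`` superposes the (round-one)
    template at the final spikes.

    When round one finds fewer than ``config.min_spikes`` spikes (or too
    few maxima to threshold at all), the whitening step is skipped, round
    two runs on the unwhitened filtered trace, and the result is flagged
    ``low_confidence``.
    """
    if config is None:
        config = PipelineConfig()
    t = np.asarray(t, dtype=np.float64)
    T = t.size
    tau = config.resolve_tau(frame_rate)

    t_s = butter_highpass(t, config.f_spike, frame_rate, order=5)
    t_s = t_s - np.median(t_s)

    low_confidence = False
    try:
        s1, _ = _detect(t_s, config, round_idx=1)
    except TooFewPeaksError:
        s1 = np.array([], dtype=np.intp)
    s1_trimmed = s1[(s1 >= tau) & (s1 <= T - 1 - tau)]

    z = None
    if s1_trimmed.size >= config.min_spikes:
        z = compute_template(t_s, s1, tau)
        q1 = np.zeros(T)
        q1[s1] = 1.0
        try:
            t_s = whitened_matched_filter(t_s, q1, s1, tau)
        except NoNoiseSamplesError:
            low_confidence = True
    else:
        low_confidence = True

    try:
        s2, thr = _detect(t_s, config, round_idx=2)
    except TooFewPeaksError:
        s2, thr = np.array([], dtype=np.intp), np.nan

    if z is None:
        # fallback template from whatever round two found
        try:
            z = compute_template(t_s, s2, tau)
        except NoTemplateError:
            z = np.zeros(2 * tau + 1)

    q2 = np.zeros(T)
    q2[s2] = 1.0
    t_rec = reconstruct(q2, z)
    return SpikeResult(
        t_s=t_s,
        s=np.sort(s2).astype(np.int64),
        z=z,
        t_rec=t_rec,
        threshold_used=float(thr),
        low_confidence=low_confidence,
    )
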