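"""Precision/recall machinery for masks and spike trains, plus SpNR.

Masks are matched by solving a linear assignment problem (Hungarian
algorithm) on pairwise Jaccard distances; spike trains by a greedy
leftmost-first matcher with a tolerance window (10 ms by default, chosen in
the original protocol because ground-truth ISIs were at least 30 ms). The
spike-to-noise ratio (SpNR) compares denoising quality on spikes detected
by all compared algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._filters import butter_highpass
from .errors import DegenerateTraceError
from .io_core import MaskSet

__all__ = [
    "MatchResult",
    "precision_recall_f1",
    "match_masks",
    "match_spikes_greedy",
    "spnr",
]


@dataclass
class MatchResult:
    """TP/FP/FN counts with derived scores and the matched index pairs.

    True negatives are structurally zero in this framework (every candidate
    is a positive prediction). Zero-denominator scores are defined as 0 so
    aggregation stays stable.
    """

    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    f1: float
    pairs: list[tuple[int, int]] = field(default_factory=list)


def precision_recall_f1(TP: int, FP: int, FN: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from counts; zero denominators give 0."""
    if min(TP, FP, FN) < 0:
        raise ValueError("counts must be non-negative")
    precision = TP / (TP + FP) if TP + FP > 0 else 0.0
    recall = TP / (TP + FN) if TP + FN > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def _result(TP: int, FP: int, FN: int, pairs: list) -> MatchResult:
    p, r, f1 = precision_recall_f1(TP, FP, FN)
    return MatchResult(TP=TP, FP=FP, FN=FN, precision=p, recall=r, f1=f1, pairs=pairs)


def match_masks(
    set_a: MaskSet, set_b: MaskSet, max_jaccard_distance: float = 0.7
) -> MatchResult:
    """Optimally match two mask sets by Jaccard distance.

    The cost of pairing mask i of ``set_a`` ("predictions") with mask j of
    ``set_b`` ("ground truth") is the Jaccard distance ``1 - |i&j|/|i|j|``;
    pairs farther apart than ``max_jaccard_distance`` are ineligible. The
    assignment minimizing total cost over eligible pairs defines the
    matches (TP); unmatched members of ``set_a`` are FP, of ``set_b`` FN.
    """
    na, nb = len(set_a), len(set_b)
    if na and nb and set_a.masks[0].shape != set_b.masks[0].shape:
        raise ValueError("mask sets must share the FOV shape")
    if na == 0 or nb == 0:
        return _result(0, na, nb, [])

    A = np.stack([m.ravel() for m in set_a.masks]).astype(bool)
    B = np.stack([m.ravel() for m in set_b.masks]).astype(bool)
    inter = (A[:, None, :] & B[None, :, :]).sum(axis=2)
    union = (A[:, None, :] | B[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        dist = np.where(union > 0, 1.0 - inter / union, 1.0)

    eligible = dist <= max_jaccard_distance
    BIG = 2.0  # > any Jaccard distance; blocks ineligible pairs
    cost = np.where(eligible, dist, BIG)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if eligible[i, j]]
    TP = len(pairs)
    return _result(TP, na - TP, nb - TP, pairs)


def match_spikes_greedy(
    v: np.ndarray, e: np.ndarray, window: float = 0.010
) -> MatchResult:
    """Greedy leftmost-first matching of two sorted spike-time sequences.

    Repeatedly take the globally leftmost remaining spike across both
    sequences. If its nearest counterpart in the other sequence lies within
    ``window`` (inclusive), the two are removed as a match; otherwise it is
    removed alone as a mismatch. ``v`` plays the prediction role, ``e`` the
    ground truth; equidistant counterparts resolve to the earlier one.
    """
    v = np.asarray(v, dtype=np.float64)
    e = np.asarray(e, dtype=np.float64)
    for name, arr in (("v", v), ("e", e)):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise ValueError(f"spike sequence {name} must be sorted")

    rem_v, rem_e = list(v), list(e)
    pairs: list[tuple[int, int]] = []
    idx_v = list(range(len(rem_v)))
    idx_e = list(range(len(rem_e)))
    TP = FP = FN = 0
    while rem_v or rem_e:
        take_v = bool(rem_v) and (not rem_e or rem_v[0] <= rem_e[0])
        if take_v:
            t0 = rem_v.pop(0)
            i0 = idx_v.pop(0)
            if rem_e:
                # nearest counterpart; ties go to the earlier (first) one
                d = [abs(t0 - te) for te in rem_e]
                j = int(np.argmin(d))
                if d[j] <= window:
                    rem_e.pop(j)
                    j0 = idx_e.pop(j)
                    pairs.append((i0, j0))
                    TP += 1
                    continue
            FP += 1
        else:
            t0 = rem_e.pop(0)
            j0 = idx_e.pop(0)
            if rem_v:
                d = [abs(t0 - tv) for tv in rem_v]
                i = int(np.argmin(d))
                if d[i] <= window:
                    rem_v.pop(i)
                    i0 = idx_v.pop(i)
                    pairs.append((i0, j0))
                    TP += 1
                    continue
            FN += 1
    return _result(TP, FP, FN, pairs)


def spnr(
    traces: list[np.ndarray],
    spike_sets: list[np.ndarray],
    frame_rate: float,
) -> list[float]:
    """Spike-to-noise ratio of each denoised trace on the common spikes.

    The spike sets of all compared algorithms are intersected first; for
    each trace independently, the trace is 15 Hz high-pass filtered, the
    noise is the standard deviation of its strictly negative samples, and
    SpNR is the mean filtered amplitude at the common spike frames divided
    by that noise.
    """
    if not traces:
        return []
    common = set(np.asarray(spike_sets[0], dtype=np.intp).tolist())
    for s in spike_sets[1:]:
        common &= set(np.asarray(s, dtype=np.intp).tolist())
    if not common:
        raise ValueError("common spike set is empty; SpNR is undefined")
    frames = np.array(sorted(common), dtype=np.intp)

    out = []
    for trace in traces:
        hp = butter_highpass(
            np.asarray(trace, dtype=np.float64), 15.0, frame_rate, order=5
        )
        neg = hp[hp < 0]
        if neg.size == 0:
            raise DegenerateTraceError("no negative samples; noise undefined")
        # RMS about zero, as in the simple-threshold noise estimator: the
        # plain std of the negative subsample would be biased to ~0.6 sigma
        noise = float(np.sqrt(np.mean(neg**2)))
        out.append(float(hp[frames].mean() / noise))
    return out
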