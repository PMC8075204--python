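"""Mask matching, greedy spike matching, scores, SpNR."""

import itertools

import numpy as np
import pytest

import voltspike as vs
from voltspike.errors import DegenerateTraceError


def greedy_oracle(v, e, window):
    """Step-by-step reference implementation of the leftmost-first matcher."""
    v, e = list(v), list(e)
    TP = FP = FN = 0
    while v or e:
        if v and (not e or v[0] <= e[0]):
            t0 = v.pop(0)
            if e:
                d = [abs(t0 - x) for x in e]
                j = d.index(min(d))
                if d[j] <= window:
                    e.pop(j)
                    TP += 1
                    continue
            FP += 1
        else:
            t0 = e.pop(0)
            if v:
                d = [abs(t0 - x) for x in v]
                i = d.index(min(d))
                if d[i] <= window:
                    v.pop(i)
                    TP += 1
                    continue
            FN += 1
    return TP, FP, FN


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((5, 0, 0), (1.0, 1.0, 1.0)),
            ((3, 1, 1), (0.75, 0.75, 0.75)),
            ((0, 0, 0), (0.0, 0.0, 0.0)),
            ((0, 4, 0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert vs.precision_recall_f1(*counts) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            vs.precision_recall_f1(-1, 0, 0)


class TestMatchMasks:
    def _masks(self, specs, shape=(12, 12)):
        out = []
        for (r, c, size) in specs:
            m = np.zeros(shape, dtype=bool)
            m[r : r + size, c : c + size] = True
            out.append(m)
        return vs.MaskSet(out)

    def test_identical_sets_perfect(self):
        a = self._masks([(1, 1, 3), (6, 6, 4)])
        res = vs.match_masks(a, a)
        assert (res.precision, res.recall, res.f1) == (1.0, 1.0, 1.0)

    def test_disjoint_sets_zero(self):
        a = self._masks([(0, 0, 3)])
        b = self._masks([(8, 8, 3)])
        res = vs.match_masks(a, b)
        assert res.TP == 0 and res.f1 == 0.0

    def test_tp_bounded_by_smaller_set(self):
        a = self._masks([(0, 0, 4), (5, 5, 4), (0, 8, 3)])
        b = self._masks([(0, 0, 4)])
        assert vs.match_masks(a, b).TP <= 1

    def test_matches_exhaustive_assignment_oracle(self):
        # 3x3 instance: enumerate all permutations with the same
        # ineligibility convention and check the Hungarian result
        rng = np.random.default_rng(0)
        shape = (16, 16)
        def rand_masks():
            out = []
            for _ in range(3):
                m = np.zeros(shape, dtype=bool)
                r, c = rng.integers(0, 10, 2)
                m[r : r + rng.integers(2, 6), c : c + rng.integers(2, 6)] = True
                out.append(m)
            return vs.MaskSet(out)

        for _ in range(10):
            a, b = rand_masks(), rand_masks()
            dist = np.ones((3, 3))
            for i, ma in enumerate(a):
                for j, mb in enumerate(b):
                    inter = (ma & mb).sum()
                    union = (ma | mb).sum()
                    dist[i, j] = 1 - inter / union if union else 1.0
            best_cost, best_tp = np.inf, 0
            for perm in itertools.permutations(range(3)):
                cost = sum(
                    dist[i, perm[i]] if dist[i, perm[i]] <= 0.7 else 2.0
                    for i in range(3)
                )
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    best_tp = sum(dist[i, perm[i]] <= 0.7 for i in range(3))
            res = vs.match_masks(a, b, max_jaccard_distance=0.7)
            assert res.TP == best_tp


class TestMatchSpikesGreedy:
    def test_single_pair_within_window(self):
        res = vs.match_spikes_greedy([0.100], [0.105], 0.010)
        assert (res.TP, res.FP, res.FN, res.f1) == (1, 0, 0, 1.0)

    def test_hand_traced_extra_prediction(self):
        res = vs.match_spikes_greedy([0.100, 0.112], [0.105], 0.010)
        assert (res.TP, res.FP, res.FN) == (1, 1, 0)
        assert res.precision == 0.5 and res.recall == 1.0

    def test_empty_prediction_all_missed(self):
        res = vs.match_spikes_greedy([], [0.05, 0.10], 0.010)
        assert (res.TP, res.FP, res.FN) == (0, 0, 2)
        assert res.recall == 0.0

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            vs.match_spikes_greedy([0.2, 0.1], [0.1], 0.010)

    def test_exhaustive_small_instances_match_oracle(self):
        # every pair of spike sets of size <= 4 on a coarse 1-ms grid
        grid = [i / 1000.0 for i in range(0, 24, 3)]
        subsets = [
            list(c)
            for k in range(5)
            for c in itertools.combinations(grid, k)
        ]
        for v in subsets:
            for e in subsets:
                res = vs.match_spikes_greedy(v, e, 0.010)
                assert (res.TP, res.FP, res.FN) == greedy_oracle(v, e, 0.010)

    def test_tp_symmetric_under_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = np.sort(rng.uniform(0, 1, rng.integers(0, 8)))
            e = np.sort(rng.uniform(0, 1, rng.integers(0, 8)))
            assert (
                vs.match_spikes_greedy(v, e, 0.010).TP
                == vs.match_spikes_greedy(e, v, 0.010).TP
            )

    def test_zero_window_counts_exact_coincidences(self):
        v = [0.1, 0.2, 0.3]
        e = [0.1, 0.25, 0.3]
        res = vs.match_spikes_greedy(v, e, 0.0)
        assert res.TP == 2


class TestSpnr:
    def test_unit_spikes_scale_with_inverse_noise(self):
        rng = np.random.default_rng(0)
        sigma = 0.1
        t = rng.normal(0, sigma, 20000)
        frames = np.arange(100, 19900, 197)
        t[frames] += 1.0
        val = vs.spnr([t], [frames], 400.0)[0]
        assert abs(val - 1 / sigma) < 0.1 / sigma

    def test_scale_invariant(self):
        rng = np.random.default_rng(1)
        t = rng.normal(0, 0.2, 5000)
        frames = np.arange(50, 4950, 133)
        t[frames] += 1.0
        a = vs.spnr([t], [frames], 400.0)[0]
        b = vs.spnr([2 * t], [frames], 400.0)[0]
        assert a == pytest.approx(b, rel=1e-9)

    def test_empty_common_spike_set_rejected(self):
        with pytest.raises(ValueError, match="common"):
            vs.spnr([np.zeros(100)], [np.array([1]), np.array([2])], 400.0)

    def test_no_negative_samples_rejected(self):
        # an identically-zero trace filters to zero: no negative samples
        with pytest.raises(DegenerateTraceError, match="negative"):
            vs.spnr([np.zeros(200)], [np.array([50])], 400.0)
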