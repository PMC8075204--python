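"""Evaluation metrics: mask matching, greedy spike matching, SpNR.

Shows the three scoring tools on small hand-built inputs so the numbers
are easy to verify by eye.
"""

import numpy as np

import voltspike as vs

# --- mask matching (Hungarian assignment on Jaccard distances) ----------
a = np.zeros((12, 12), dtype=bool); a[2:6, 2:6] = True
b = np.zeros((12, 12), dtype=bool); b[2:6, 3:7] = True   # shifted: IoU = 0.6
c = np.zeros((12, 12), dtype=bool); c[8:11, 8:11] = True
res = vs.match_masks(vs.MaskSet([a, c]), vs.MaskSet([b]))
print(f"masks: TP={res.TP} FP={res.FP} FN={res.FN} F1={res.f1:.3f}")
# one eligible pair (Jaccard distance 0.4 <= 0.7) -> TP=1, FP=1, FN=0

# --- greedy spike matching within 10 ms ---------------------------------
m = vs.match_spikes_greedy([0.100, 0.112], [0.105], window=0.010)
print(f"spikes: TP={m.TP} FP={m.FP} precision={m.precision:.2f} "
      f"recall={m.recall:.2f}")
# leftmost spike 0.100 matches 0.105 (5 ms); 0.112 has no partner left -> FP

# --- spike-to-noise ratio ----------------------------------------------
rng = np.random.default_rng(0)
trace = rng.normal(0, 0.1, 20000)
frames = np.arange(100, 19900, 197)
trace[frames] += 1.0
(val,) = vs.spnr([trace], [frames], frame_rate=400.0)
print(f"SpNR of unit spikes on sigma=0.1 noise: {val:.1f} (~1/sigma = 10)")
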