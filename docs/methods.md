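# Methods

This note documents the models and procedures implemented in `voltspike`,
the parameters that matter, what the simulator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Signal model and per-neuron procedure

A voltage-imaging movie is modeled as a sum of neuron signals (spatial
footprint × temporal fluorescence), a slowly varying background, optical
cross-talk, and white sensor noise. Indicators like Voltron have *reverse
polarity* — fluorescence drops when voltage rises — so movies are
sign-inverted first. Photobleaching multiplies everything by a slow
exponential decay and is removed by a 1/3 Hz zero-phase high-pass
(3rd-order Butterworth).

Per neuron, computation is confined to a *context region*: the ROI bounding
box dilated by `context_margin` pixels per side and clipped to the field of
view. The *local background* is every context pixel whose Chebyshev
distance to the ROI exceeds `n_b`; its top `n_pc` left singular vectors
capture structured contamination (out-of-focus signal from neighbors,
residual motion, global noise) and are removed from the trace by ridge
regression. Ridge rather than plain regression keeps coefficients bounded
when the neuron's own signal bleeds into background components; both ridge
problems scale the penalty by the squared Frobenius norm of the design
matrix, so `lambda_b`/`lambda_w` are dimensionless.

Spike detection runs in two rounds because the matched filter needs a
template and a noise spectrum before it can help. The *adaptive threshold*
estimates the distribution of local-maximum heights by Gaussian KDE,
reflects it about its median to approximate the noise-peak distribution,
and picks the threshold maximizing `F_max^p − F_noise^p` (survival
functions); `p` trades off template purity (round one, p₁ = 0.25) against
recall (round two, p₂ = 0.5). The *simple threshold* estimates the noise
sigma from the negative samples only and cuts at `l·σ` (3.5, then 3.0).
The reflection assumes noise-peak heights are symmetric about their
median; they are in fact right-skewed, so the adaptive threshold can sit
inside the noise tail on featureless traces — one reason the simple
threshold exists as a fallback, and why detection on pure noise is only
*mostly* empty.

The reconstruction `t_rec` is exactly the superposition of the round-one
template at the round-two spike frames. The spatial filter regresses
`t_rec` on the high-passed context movie (damped LSQR; agrees with the
dense closed form to better than 1e-6 relative). Three rounds of the loop
are run; the filter and trace are frozen on the final round. Subthreshold
activity is the 20 Hz low-pass of the residual, and the *locality test*
accepts a neuron only when the context pixel with maximal Pearson
correlation to `t_rec` lies inside its own ROI — inactive or contaminated
neurons fail this test.

## Key parameters

| name | default | units | meaning |
|---|---|---|---|
| `context_margin` | 30 | px | ROI bounding-box dilation per side; ≥ 2×`n_b` so a background annulus always exists for typical somata |
| `n_b` | 12 | px | Chebyshev exclusion zone between ROI and background |
| `n_pc` | 8 | – | background singular vectors removed |
| `lambda_b`, `lambda_w` | 0.01 | – | ridge strengths (Frobenius-scaled) |
| `K` | 3 | – | spike/spatial-filter loop rounds |
| `tau` | round(0.02·rate) | frames | template half width (20 ms bin) |
| `p1`, `p2` | 0.25, 0.5 | – | adaptive stringency, rounds 1/2 |
| `l1`, `l2` | 3.5, 3.0 | – | simple-threshold noise multiples |
| `f_bleach` | 1/3 | Hz | photobleaching high-pass corner |
| `f_spike` | 1 | Hz | spike-band high-pass corner |
| `f_sub` | 20 | Hz | subthreshold low-pass corner |
| `min_spikes` | 5 | – | round-one minimum before whitening |

## Numerical choices

* **All filtering is zero-phase** (forward–backward `sosfiltfilt`): causal
  filtering would shift detected spike times. The pad length is at least
  one cutoff period (`fs/cutoff`, capped at T−2): the scipy default of a
  few dozen samples is far shorter than a 1/3 Hz filter's response at
  400 Hz and leaves edge transients large enough to masquerade as spikes.
* **KDE**: Gaussian kernel, Scott's-rule bandwidth, 1000-point grid over
  the height range. At least 10 local maxima are required; below that the
  detector falls back (see below).
* **Whitened matched filter guards.** The Welch estimate (Hann window,
  segment length min(1024, n/2), 50% overlap) detrends each segment, so
  its DC bin is near zero; the trace is therefore mean-subtracted before
  the spectral division, the one-sided DC/Nyquist bins are doubled so a
  white spectrum maps to a flat scaling, the spectrum is floored at 1e-10
  of its maximum, the FFT operates on a reflection-padded trace (a
  circular FFT would splice the trace ends together), and the matched
  template is made zero-mean so the correlation output is insensitive to
  local baseline offsets (a template with net mass turns any sustained
  offset into output proportional to sum(z), which near trace ends can
  out-peak real spikes). None of these changes the algorithm; they keep
  its output finite and edge-clean.
* **Fallback**: when round one finds fewer than `min_spikes` spikes, the
  template would be an average of a handful of noisy windows, so whitening
  is skipped, round two runs on the unwhitened filtered trace, and the
  neuron is flagged `low_confidence`.
* **SVD**: the top background components are computed with ARPACK
  (`svds`, deterministic start vector) rather than a full SVD — identical
  leading subspace at a fraction of the cost; dense SVD is used for small
  matrices. Background subtraction is invariant to the sign ambiguity.
* **SpNR** divides the mean 15 Hz-high-passed amplitude at the common
  spike frames by the RMS of the strictly negative samples (the same
  noise estimator the simple threshold uses; the plain standard deviation
  of the negative subsample would be biased to ~0.6σ for Gaussian noise).
* **Plateau local maxima** take the first plateau index; greedy spike
  matching resolves equidistant counterparts to the earlier one;
  zero-denominator precision/recall/F1 are defined as 0. All tie-breaks
  are deterministic.
* **Eq. for the initial trace is literal**: the weighted average `Y_h·w`
  is *not* normalized by the weight sum. A filter equal to the ROI
  indicator divided by |S| reproduces the plain ROI mean.

## Simulator

The generator emulates layer-1 cortex recordings with a Voltron-like
indicator at 400 Hz in a 50×50-pixel (default) field of view:

* **Footprints**: ring-shaped (annulus, outer radius 6 px, inner ~0.65×)
  real-valued maps with one narrow radial process at a random angle,
  max-normalized. Non-overlap placement uses a jittered grid with
  disjoint 0.5-level supports; two-neuron overlap experiments place the
  pair so the shared-support fraction — intersection over the smaller
  support — hits the requested value within 0.02 (the fractions
  0/0.06/0.19/0.26/0.35 are all reachable).
* **Spike trains**: i.i.d. inter-spike intervals uniform on [0.1, 0.2] s,
  each gap quantized to frames *before* the cumulative sum so every
  frame-domain ISI stays inside the stated support exactly.
* **Traces**: spike train convolved with a biexponential kernel (1-frame
  rise, 2-frame decay at 400 Hz — the indicator's published dynamics are
  qualitative, so the constants are config-exposed), scaled to the target
  dF/F; plus Gaussian-smoothed white-noise subthreshold activity (sd
  0.25× the spike amplitude, ~10 Hz bandwidth); flipped (reverse
  polarity); baseline multiplied by exp(−t/2500 s) photobleaching.
* **Movie**: Σ footprints × brightness (100 a.u.) × traces, plus a smooth
  synthetic background (static low-spatial-frequency image, ±20%
  contrast, with a 1% slow multiplicative drift) standing in for a real
  cortical patch, per-neuron out-of-focus bleed-through (the neuron's
  fluctuation times a Gaussian-blurred point weight at a random pixel,
  10% strength), and i.i.d. white noise (sd 15 a.u. = 0.15 of baseline)
  on every voxel. A (config, seed) pair reproduces the movie bit-exactly,
  and the additive components can be returned separately for exact
  accounting.

What it does **not** emulate: residual motion, realistic vasculature or
neuropil structure, shot-noise statistics (noise is Gaussian, not
Poisson), dendritic morphology beyond the single process, firing-rate
nonstationarity, or optics beyond a Gaussian blur. Passing tests on these
simulations therefore demonstrate the pipeline's correctness and its
behavior under controlled SNR, not its performance on any particular real
preparation.

## Test and reproduction scales

The test suite and `scripts/acceptance.py` choose problem sizes that keep
a full run on one CPU comfortable while preserving the study conditions:
the headline recovery check uses 10 neurons in an 84×84 field (the 50×50
default cannot hold 10 non-overlapping rings of the default radius),
10,000 frames at 400 Hz, spike amplitude 0.075, three seeds; the
amplitude sweep uses 3 neurons, 5,000 frames and three seeds per
amplitude over the full grid {0.05 … 0.2}; planted-spike exactness uses
4,000-frame traces with spikes at the simulator's ISI statistics in
Gaussian noise truncated at 3 sd (the truncation makes "exact recovery"
a property of the detector rather than of the noise draw; see the test
docstrings).

## Known limitations

* The adaptive threshold's symmetry assumption makes it unreliable on
  traces with no real spikes; the locality test and `low_confidence` flag
  are the intended backstops.
* Spike times are integer frame indices; no sub-frame interpolation.
* The two-neuron overlap placement is defined for exactly two neurons.
* `run_pipeline` parallelism is thread-based and benefits mainly from
  BLAS/FFT releasing the GIL; results are identical for any worker count.
* Motion correction and automated segmentation are out of scope: the
  pipeline consumes a motion-corrected movie and externally provided
  masks (the summary images exist to support inspection and external
  segmenters).
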