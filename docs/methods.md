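# Methods

`gss-hdemg` decomposes multichannel surface EMG into motor-unit (MU) firing
trains with a *guided* source-separation scheme: a template-clustering stage
proposes initial points, a gradient Convolution Kernel Compensation (CKC)
loop refines one MU filter per initial point, an EM-Kalman stage accelerates
the loop, and adaptive soft-thresholding converts the continuous spike-train
estimates into discrete firings. This note records the model, the concrete
numerical choices, and what the synthetic benchmark does and does not show.

## Data model and estimator

The recorded EMG is modelled as a convolutive mixture: each channel is the
sum over MUs of the MU action potential (MUAP) convolved with a binary
firing train, plus noise. Stacking every channel with R−1 delayed copies of
itself (extension, R = 30 by default) converts the convolutive mixture into
an approximately instantaneous one; eigenvalue whitening
(W = U D^(−1/2) U^T from E{ZZᵀ} = U D Uᵀ, "convolutive sphering") renders
the extended observations X uncorrelated. The CKC estimate of the j-th MU
spike train is

    ť_j = r_jᵀ R_XX⁻¹ X ,

where r_j is the cross-correlation vector between X and the (unknown)
train — the *MU filter*. After whitening, R_XX = I. The filter is refined
by the gradient recursion

    r ← r + η(g) · X f(ť),   f(x) = α(x) · log(1 + x²),

with step schedule η(g) = 0.1/(1 + g/20) and a per-spike attenuation α
(soft-thresholding, below). Before the first iteration the filter is
re-initialized by one spike-triggered (fixed-point) pass: peaks of the
initial estimate above 0.6× the PNR-optimal threshold are averaged in X.
The factor 0.6 deliberately admits weaker discharges into the average; the
following iterations and the soft threshold remove the few false peaks this
lets in.

Numerical conventions that matter:

* ť estimates a *binary* train, so every estimate is rescaled to unit spike
  amplitude (mean of its 10 largest samples = 1) before f is applied. At
  this scale f weights a spike ≈ 70× a baseline sample; at unit-baseline
  scale the ratio is only ≈ 4 and the recursion stalls.
* The gradient is normalized (r ← r + η·u/‖u‖, r renormalized). The raw
  summed gradient is orders of magnitude larger than the filter at
  realistic problem sizes and would turn the recursion into a one-step
  fixed point. η therefore acts as a relative step.

## Spike detection and the soft threshold

After each iteration a spike-detection threshold is chosen by maximizing
the pulse-to-noise ratio

    PNR = 10 log10( E[ť² | ť ≥ thr] / E[ť² | ť < thr] )

over candidate thresholds (tail-weighted quantiles of the local-maximum
amplitudes). The search is constrained to thresholds that keep at least
4 Hz × duration peaks: an MU cannot discharge more slowly, and the
unconstrained maximizer occasionally locks onto a handful of extreme peaks.
A 95% CI for the threshold comes from 200 bootstrap resamples of the peak
amplitudes. Spikes above the upper CI bound are confident (α = 1); spikes
inside the CI band are *marginal* and keep α = 1 only if the Pearson
correlation between their 2-ms EMG segment (on the channel that proposed
the initial point) and the template of the confident spikes reaches 0.8,
otherwise α = 0.9 — which both attenuates them in the update and excludes
them from the discrete firing train. Peaks are separated by an 8-ms
refractory distance (physiological trains here never fire faster than
35 Hz).

Iteration stops when the detected firing set is unchanged for 3 consecutive
iterations or the PNR improves by < 0.1 dB over 5 iterations, with a floor
of 6 and a cap of 150 iterations.

## EM-Kalman acceleration

The gradient recursion is embedded in a state-space model with state
x = [r; 1]. The prediction step applies the gradient increment (the same
normalized f-gradient as the plain path, so that the prediction reproduces
the gradient recursion). The measurement is the soft-thresholded train
detected in the current iteration — the algorithm's current belief about
the underlying binary train. The observation-noise variance σ² is
re-estimated each iteration from the innovation (the EM step), and the
Kalman gain reduces to a scalar blend γ = p/(p + σ²) between the predicted
filter and the least-squares filter reproducing the detected train (for
whitened X simply X·target/M, the spike-triggered average). The error
covariance is isotropic, P = pI (symmetric PSD by construction), and
contracts by (1 − γ) per iteration with a small floor: early iterations
jump most of the way to the least-squares solution, later ones settle.

This realization was chosen over two more literal variants after measuring
them: full per-sample gains cost O(N²M) per iteration (≈10¹³ flops at
benchmark size), and a diagonal-covariance per-sample variant with the
innovation taken between consecutive estimates *increased* iteration counts
and lost weak sources — the opposite of the acceleration the state-space
formulation is meant to deliver.

## Post-processing

Firings are the α = 1 spikes. Discharge statistics use the inter-spike
intervals after symmetric trimming (outside [median/1.75, median·1.75]):
a missed discharge creates an ISI at ≈ 2× the median and a false detection
a very short one, and both would otherwise dominate MDR and CoV. The
untrimmed span rate is kept as `mdr_span_hz`. A MU is kept when all of the
following hold:

* PNR ≥ 20 dB;
* inconsistent firings (ISI < 20 ms) ≤ 50;
* ISI-normality probability p_d ≥ 0.5 — by default the p-value of a KS test
  against the normal with fitted parameters. This uncorrected p-value is
  deliberately conservative (the test suite verifies that ≥ 90% of
  genuinely Gaussian ISI trains score ≥ 0.5), which is what makes a 50%
  cutoff usable; a Shapiro–Wilk option exists but its null p-values are
  uniform and the same cutoff would discard half of all perfect trains;
* MDR ≤ 35 Hz and ≥ 5 Hz (the low bound applied to both the trimmed rate
  and the span rate — a sparse noise-locked train can have plausible short
  ISIs while firing far too rarely overall);
* ISI CoV ≤ 0.25. During constant-force isometric contractions single-MU
  ISI variability stays near 0.1–0.2; an estimate mixing two interleaved
  MUs is markedly more dispersed (CoV ≈ 0.3) while passing every other
  rule, and such mixtures are the dominant precision failure mode.

Duplicates (≥ 50% of the smaller train matching within ±0.5 ms after
constant-lag alignment — CKC recovers each source up to a constant delay)
are grouped into connected components; the survivor is the highest-PNR
pattern among those with at least 2/3 of the component's largest firing
count. PNR alone is not a safe selector because a sparse partial estimate
of a MU carries an inflated PNR.

## Synthetic benchmark

The generator emulates a constant-force isometric contraction:

* MU pool: fiber counts uniform on {24..2048} (20 fibers/mm² territories),
  conduction velocities Normal(4.0, 0.3) m/s truncated at 2.5 m/s,
  recruitment thresholds on the exponential ladder exp(i·ln 30/n)/30 · 0.6
  (recruitment range 30, last MU at 60% MVC), thresholds independent of MU
  size, territory depths uniform in 2–14 mm.
* Rate coding: 8 pps at recruitment, +0.3 pps per % excitation above
  threshold, capped at 35 pps; Gaussian ISIs with CoV 0.14 and a 20-ms
  refractory floor.
* MUAP surrogate: a biphasic waveform (second derivative of a Gaussian,
  σ = 0.45 ms scaled by 4/v and a ±15% per-MU jitter) propagating along the
  electrode columns with inter-row delay ied/v; amplitude scales linearly
  with fiber count, decays as exp(−distance/6 mm) with the
  electrode-to-territory distance, and carries a Gaussian longitudinal
  envelope (18 mm) centered at the MU endplate row. The 6-mm decay length
  is the one free spatial parameter; it is set so that superficial MUs
  (< 6 mm depth, the scoreable targets) dominate the surface signal while
  deep MUs form the physiological background — which is how real
  high-density recordings behave.
* Noise: Gaussian, band-limited to 20–500 Hz, at an exact global SNR.

This surrogate deliberately replaces an analytic volume-conductor model.
It preserves what the decomposition actually uses — distinct spatio-temporal
templates, propagation, amplitude hierarchy, physiological background — but
not tissue filtering, fiber-length/end-of-fiber effects, or electrode-skin
artifacts. Passing the benchmark therefore demonstrates the correctness and
calibration of the algorithmic chain, not performance on experimental
signals.

### Problem sizes

The default desk-scale condition is 5 s at 4,096 Hz on a 7-row × 6-column
monopolar grid (36 single-differential channels; extended dimension
N = 1080, M = 20,480 samples) with an 80-MU pool, chosen so the full
3 SNR × 3 MVC × 2 replicate grid plus the comparator runs in minutes on a
single CPU. `SimConfig.full()` restores the reference geometry (16 s,
10 × 9 grid). The decomposition runs in single precision inside the
pipeline; the library operates at the input dtype.

The gradient-CKC comparator ("gCKC") uses the same preprocessing and
exclusion rules but peak-based initial points (largest whitened-observation
energy peaks), α ≡ 1 and no Kalman stage.

At this signal length each MU train holds only ~45 inter-spike intervals,
so per-MU discharge statistics carry ~0.1 Hz of pure estimation noise; the
benchmark's firing-statistics figures therefore average over five seeded
replicates of the relevant conditions rather than the minimum of three.

## Validation metrics

Matching of estimated to simulated firings is greedy nearest-first
one-to-one within ±0.5 ms, *after removing the best constant time shift*
(searched over ±15 ms via the pairwise-offset histogram): CKC recovers each
source up to a constant delay, so "time-locked" comparisons must allow a
global lag while individual firings still have to agree to ±0.5 ms.
RoA = TP/(TP+FN+FP), sensitivity, precision; a simulated MU counts as
*identified* when ≥ 30% of its firings are time-locked. A cluster of active
segments is *correct* when ≥ 75% of its proxy spikes (representative + 20
nearest in the reachability ordering) are time-locked to one simulated MU.
SIR is the percentage of single-differential signal variance explained by
the reconstruction from spike-triggered-average MUAPs; the decomposability
index DI_ki = min(‖m_ki‖, ‖m_ki − m_k*i‖)/V_i^RMS uses the nearest
competitor MUAP per channel and the residual RMS as the noise estimate.

## Known limitations

* The iteration-count contrast between the Kalman and plain-gradient paths
  is regime-dependent: with clustered initial points and the fixed-point
  start, both paths converge within ~5–15 iterations at desk scale, so the
  measured ratio is noisy and less pronounced than in slow-start regimes.
* PNR discriminates strongly between kept MUs and noise, but among the
  *kept* population its dynamic range is narrow — the surrogate's MUAPs
  stay distinct even at the lowest benchmark SNR, so the kept MUs are all
  fairly accurate and correlations between PNR and per-MU accuracy are
  weak in this regime.
* OPTICS clustering runs per channel on aligned 2-ms waveform vectors
  (a `features="lags"` toggle preserves the peak-time-only variant);
  MinPts scales linearly from 40 per 10-s epoch.
* The pipeline is offline; no peel-off subtraction, no duplicate-aware
  re-estimation, no real-data ingestion beyond the documented container.
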