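# Methods

This note documents the models, estimators and numerical choices behind
`bfnet`, what the synthetic-session generator does and does not
emulate, and the calibration properties we have measured.

## Signals and preprocessing

LFPs are represented at 1250 Hz in microvolts. `lfpproc.decimate_lfp`
low-passes raw input with a zero-phase Kaiser-window FIR (corner
300 Hz, 100 Hz transition, ≥60 dB stopband per pass; forward–backward
filtering squares the response) and downsamples by slicing (integer
ratios) or polyphase resampling. The corner frequency is the only
externally fixed quantity; the transition width and stopband depth are
package choices, exposed as parameters.

## Time–frequency decomposition

The spectrogram is an analytic Morlet transform, ω₀ = 6, evaluated on a
logarithmic grid (8 voices/octave, 1–110 Hz by default — gamma work
uses the in-band grid points only). The transform is computed directly
as an FFT convolution with ψ(t/s), ψ(t) = (2π)^(-1/2) e^(−t²/2)
e^(iω₀t), zero-padded past the widest wavelet. With this (un-rescaled)
kernel the expected |W|² for white noise grows linearly with scale, so
`Spectrogram.power()` divides by scale, making white-noise power flat
across the grid; a pure sinusoid peaks at its nearest grid frequency.
Samples within √2·scale of the segment edges are flagged as inside the
cone of influence and excluded from band averages by default.

We implemented this small kernel directly rather than delegating to a
wavelet library because we require an exactly characterised
normalisation across three decades of frequency; the implementation is
validated against white-noise flatness and sinusoid-localisation
oracles in the test suite.

## Wavelet coherence

Squared coherence |S(W_x W_y*)|² / (S|W_x|² S|W_y|²) needs a smoothing
operator S to be non-degenerate (the unsmoothed magnitude coherence is
identically 1; a guard test keeps this from regressing). Two smoothers
are provided:

* `wavelet_coherence` (pairwise time series): Gaussian smoothing in
  time with σ equal to the wavelet scale, plus a boxcar over ±1 voice
  in scale. This resolves coherence dynamics at roughly the wavelet's
  own resolution, at the price of a high bias floor (~0.4 for
  independent signals) because few independent samples enter each
  estimate.
* `pairwise_band_coherence` (used by the map builder): the cross- and
  auto-spectra are averaged over the whole analysis interval (boxcar
  smoothing spanning the interval) and over the band's grid
  frequencies. When only the interval mean is consumed this is the
  natural estimator; it reduces each trial × pair to one matrix product
  per frequency and has a bias floor of roughly the reciprocal number
  of independent samples in the interval (~0.01 for 2–4 s of gamma).

Both are consistent estimators of the same population quantity;
magnitude-squared coherence is the default (`squared=False` gives the
magnitude). Coherence values are clipped to [0, 1] and symmetric in
the channel order to numerical precision.

**Matched averaging windows.** The bias floor scales inversely with
the averaging window, so comparing a 2-s epoch against a 4-s baseline
would bias the change score positive at every null voxel. The sampler
therefore truncates the epoch and baseline of each trial to their
common minimum duration, making the two groups exchangeable under the
null; measured null maps then flag ≈ α of voxels at both α = 0.05 and
α = 0.01.

## Change scores and permutation maps

The coherence change score is the normalised difference of group mean
coherences, bounded in [−1, +1], antisymmetric under swapping the
groups, and undefined (reported as a missing voxel, never propagated)
when both means are zero. Significance uses a Monte-Carlo permutation
test: both groups are pooled, label permutations preserving the group
sizes are drawn (3000 by default; a with-replacement bootstrap variant
sits behind a flag), the difference of means is the resampling
statistic, and p = (1 + #{|T*| ≥ |T|}) / (n_perm + 1), two-sided by
default so maps report both increases and decreases. α is a required
argument everywhere — the analysis level (0.05 vs 0.01) is an explicit
choice, not a buried default. Map builders share one permutation index
set across the 1024 voxels (valid since the null is per-voxel) and
reject at p ≤ α with no correction across voxels; that per-voxel
convention is anti-conservative family-wise and is stated in the
output metadata.

Measured type-I error of the permutation machinery (600 null
replications, groups of 20): 0.042 at α = 0.05 and 0.010 at α = 0.01 —
inside the exact binomial 95% bands. Hotspot recovery on full 32 × 32
maps (coupling 0.8, 20 trials, α = 0.01, 20 seeded sessions):
sensitivity 1.0, false-discovery proportion ≈ 0.06.

Epoch-level comparisons divide each trial's epoch coherence (averaged
over all channel pairings) by the same trial's centre/rest baseline,
concatenate across trials, and run a one-way fixed-effects ANOVA with
Tukey-HSD pairwise comparisons; the family α is Bonferroni-divided by
the number of band × region-pair analyses.

## Spike-unit analyses

**Epoch modulation.** Per-trial firing rates in an epoch and the same
trial's centre/rest baseline are compared with the two-sided
Mann–Whitney/Wilcoxon rank-sum test (scipy; exact null for small
tie-free samples, normal approximation with tie correction otherwise
— verified against exhaustive enumeration at 4 vs 4). Z-scores are
emitted per trial and as a trial-averaged time course (both, since
either convention is in use); normalised rates use min–max feature
scaling over the session.

**Optotagging.** Evoked rate = spikes within the response window
(default: the 10-ms pulse width) per unit time over ≥100 stimuli;
responsive iff it deviates from the control mean by more than 2 control
SDs. Control rates come from the 2000 ms preceding events whose gap to
the previous event is at least the control window — within a train
(pulses every ~100 ms) the pre-stimulus window would otherwise contain
earlier pulses, so in practice controls anchor at train onsets. The
criterion is invariant under time rescaling and its measured
specificity on null units is ≈96%, consistent with the nominal ~95% of
a 2-SD rule.

**Cross-correlograms.** CCGs use 0.5-ms bins over ±50 ms. The baseline
predictor is the CCG convolved with a unit-area 10-ms-SD Gaussian (a
partial-hollow fraction for the centre tap is exposed but defaults to
0, i.e. the plain kernel); per-bin thresholds are the smallest k with
Poisson CDF(k; predicted) ≥ 0.9999 (upper) and the analogous 10⁻⁴
lower quantile. A connection is excitatory (inhibitory) when ≥2
consecutive bins with lag centres in [+1.5, +5] ms exceed (fall below)
threshold. The threshold is tested bin-exactly against brute-force pmf
summation. Note that a strong sharp peak inflates the smoothed
predictor in neighbouring bins, which can mark adjacent ordinary bins
as "significantly low"; sign assignment checks the excitatory run
first. With a plain Gaussian and two consecutive 10⁻⁴ tails, false
detections on independent Poisson pairs are expected at ~10⁻⁷ per
pair; none were observed in 300 pairs.

**Waveform features.** TP latency is the time from the global trough
to the subsequent maximum on the peak channel (the site of maximum
deviation). The burst index is the mean 1-ms-binned autocorrelogram
count at lags [3, 5) ms over the mean at [200, 300) ms (NaN when the
denominator is empty). Waveform PCA upsamples the peak-channel
waveform ×5 by cubic spline, takes the second finite difference,
aligns at the global trough, crops 0–0.8 ms, and projects the stacked
matrix on its first two principal axes. K-means (k = 6, 10 seeded
restarts) runs on z-scored (TP, w-PCA1, w-PCA2); bagged decision trees
(100 estimators) trained on (TP, w-PCA1, w-PCA2, mean rate) with
cholinergic units held out report out-of-bag accuracy and predict
cluster labels for the held-out cells. The preliminary
excitatory/inhibitory split (TP > 0.485 ms or rate < 6 Hz) is provided
as stated defaults.

## Spike-triggered gamma

For each (trigger unit, channel, band), band power from the CWT is
averaged over [−500, 0) and (0, +500] ms around each spike, one sample
per spike per side; pooled per-sample mode exists behind the API.
Spikes nearer than 500 ms to the session edges are dropped, and
triggers are greedily thinned to ≥1 s separation (2 × half-window) so
windows from consecutive triggers never overlap; at ~2 Hz cholinergic
rates this keeps ≥50 usable spikes in a few minutes of recording.
Before/after sets are compared with the two-sample KS test, and the
difference score (mean_after − mean_before)/(mean_after + mean_before)
mirrors the coherence change score's normalised form — a package
convention, chosen for consistency, since no closed form is canonical.
Summaries report 100 × n_significant / n_sites per (cell, probe,
band), flagging incomplete probes.

**Calibration contract.** On null synthetic sessions the per-site flag
rate is exactly calibrated at α = 0.01 (measured 0.008–0.009 over
≥1600 tests) but runs mildly conservative at α = 0.05 (measured
≈0.040–0.044): window means drawn from one finite session realisation
are weakly dependent, which depresses the lower tail of the KS p-value
distribution by ~15% even though scipy's KS is exactly calibrated on
iid data of the same size. The acceptance checks therefore assert the
two-sided binomial band at α = 0.01 and, at α = 0.05, that the rate
shows no inflation above the binomial upper bound and at most
factor-two conservatism. Conservatism leaves the significant-site
summaries valid (specificity ≥ nominal); users wanting exact 0.05
calibration should increase the trigger-separation or session length.

## The synthetic generator

`synth` is a statistical emulator, not a biophysical simulation. Per
channel it sums 1/f-shaped Gaussian background (exponent 1.0, RMS
30 µV — matching broadband LFP spectra in form), plus an independent
band-limited Gaussian component per gamma band (RMS 15 µV, giving
in-band SNR ≈ 3.5 over the background). A hotspot replaces each member
channel's band component with √(1−c²)·own + c·shared during its epoch
(cosine-ramped, 50 ms), so the coupling is strictly larger in-epoch
than at rest and band coherence increases monotonically with c. STA
effects multiply the band component by a gain in (0, +500 ms] after
each trigger spike; with a gain g and dominant band component the
after/before power ratio approaches g². Spike trains are (piecewise)
Poisson; excitatory couplings insert a post spike per pre spike with
probability = efficacy at lag ± uniform jitter, inhibitory couplings
delete post spikes in the lag window (thinning), making CCG peaks and
troughs analytically predictable; light-responsive units add one spike
per 10-ms pulse with the stated probability. Waveforms come from
biphasic templates (trough→peak 0.60 ms wide / 0.25 ms narrow at
20 kHz) with seeded perturbation and Gaussian spatial attenuation
across the shank. All randomness derives from named SeedSequence
streams: identical config + seed gives byte-identical datasets.

Default study conditions: BF 8 shanks × 8 sites, cortical probes
4 × 8 with 100 µm pitch; six epochs per trial (centre 4 s, cue 4 s —
fixed by the task design — decision/approach/consume/return 2 s each,
our choice for a compact locomotor sequence); cholinergic units at
2.16 Hz mean rate; light protocol 10-ms pulses at 100-ms period in 2-s
trains (the within-train interval is not externally fixed; 100 ms is
the package default), 15 trains → 300 pulses ≥ the 100-stimulus
minimum, 3-s gaps so control windows are stimulation-free.

What the generator does **not** emulate — and hence what passing
recovery tests do not show about real data: volume conduction and
shared references between nearby contacts, non-Poisson (bursting,
oscillation-locked) spiking, theta and other non-gamma rhythms,
cross-frequency coupling, behavioural nonstationarity within epochs,
spike-sorting errors, and electrode drift. Recovery results are
best-case benchmarks under the model's own assumptions.

## Problem sizes and determinism

The shipped validation batteries use: 600 replications × 1000
permutations for type-I error; 20 sessions of 20 trials with a 64-voxel
injected block for 1024-voxel map recovery; 1000 random rates for the
Poisson-threshold oracle; 20 coupled pairs (~3500 pre spikes each) and
300 independent pairs for the CCG detector; 200 simulated units for
optotagging; 50 sessions × 14 null sites for STA calibration; 120
units for classifier recovery. These sizes put every binomial check's
resolution well inside the effect sizes being asserted while keeping
the whole battery in the minutes range on one CPU. Every battery
derives its seeds from a single SeedSequence, so results are exactly
reproducible given `--seed`.

## Known limitations

* The Morlet ω₀ = 6 grid has σ_f ≈ f/6, so adjacent gamma bands leak:
  a strong 45–75 Hz effect raises 75–85 Hz estimates on the same
  channel. Band-level claims should be read with that resolution in
  mind.
* The per-voxel α in change maps is uncorrected across 1024 voxels by
  design; interpret isolated voxels accordingly.
* The CCG detector assumes stationary baselines over the ±50 ms window;
  strong co-modulation (e.g. shared slow rhythms) can defeat the
  Gaussian predictor.
* The bagged-tree prediction for held-out cells extrapolates when their
  features lie outside the training support; with few held-out cells,
  read the population-level fraction, not single-cell assignments.
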