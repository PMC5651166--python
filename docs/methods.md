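# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `gecca-eeg`, and what the synthetic test bench does and
does not establish about real recordings.

## Problem setting

Scalp EEG is routinely contaminated by non-neural activity: eye blinks
(EOG) appear as smooth negative impulses roughly ten times the EEG
amplitude, and muscle activity (EMG) as broadband bursts with much lower
autocorrelation than EEG.  The cleaning chain implemented here works on a
single contaminated channel at a time, using a second, cleaner channel of
the same recording only as a *correlation reference*.  It assumes:

* artifacts are additive on top of the neural signal;
* neural activity is shared across channels (volume conduction), so a
  genuine EEG component of the contaminated channel correlates measurably
  with the reference channel, while artifact components do not;
* EMG-like artifacts have low lag-correlation, so a delay-based CCA
  orders them into the trailing canonical components.

## Pipeline stages and defaults

**Reference selection.**  The reference is the channel with the smallest
sample standard deviation (n−1 denominator), ties broken toward the lowest
index — high variance on this timescale is dominated by artifact, so the
lowest-variance channel is the best available stand-in for clean EEG.
Channel indices are 1-based in every user-facing surface.

**EEMD** (`eemd` module).  Sifting uses cubic-spline envelopes through the
interior extrema, mirror-extended by two extrema at each boundary (the
standard guard against end-point spline overshoot).  A sift stops when the
Cauchy criterion `Σ(h_prev − h)² / Σ h_prev² < 0.2` holds *and* the
candidate satisfies the IMF property (extrema and zero-crossing counts
differ by at most one), with a hard cap of 50 sifts.  Extraction stops at
8 IMFs or when the residual has fewer than two interior extrema.  The
ensemble version averages the IMFs of noise-perturbed copies index-wise,
zero-padding members that produced fewer modes.  The library default for
the noise amplitude is 0.2 of the signal standard deviation (the common
choice when hundreds of ensemble members are averaged); the *pipeline*
default is `noise_std = 0.1` with 3 ensembles, because the un-cancelled
injected noise scales as `noise_std/√N` and with only three members the
larger amplitude would leave more than one percent of spurious broadband
variance in the streams, which both biases the correlation screening and
caps the attainable reconstruction fidelity.

**GECCA** (`gecca` module).  Channels are rows, time is columns.  The
delayed copy drops one sample at each end; the covariance of the stacked
pair is cut into blocks and both auto-blocks get `β = 1e-8` on the
diagonal.  Two solvers produce the same `CanonicalModel`:

* `solve_cca_inverse`: eigen-decomposition of
  `Cxx⁻¹·Cxy·Cyy⁻¹·Cyx` (and the role-swapped product for the Y-side
  weights);
* `solve_cca_leftdiv`: LU-factorisation solves of `Cxx·A = Cxy` and
  `Cyy·B = Cyx`, then eigen-decomposition of `A·B` (the Y-side spectrum
  comes free as `B·A`).  On singular blocks it falls back to a
  least-squares solve via QR with column pivoting instead of failing.

Numerical policies shared by both solvers:

* eigenvalues/vectors with imaginary parts above `1e-8` (relative) raise a
  diagnostic error; below that they are clipped to real;
* weight vectors are unit-norm with the largest-magnitude entry positive;
* *degenerate clusters*: canonical correlations of smooth streams against
  their one-lag neighbourhood pile up at ρ² = 1 with gaps of order 1e-10,
  far below the sampling error of the covariance estimates.  Within a
  cluster of eigenvalues equal to 1e-6 (relative), the individual
  eigenvectors carry no statistical meaning and LAPACK's choice of basis
  is effectively arbitrary — in particular it can differ between the two
  solver routes and can place genuine signal into variance-cancelling
  combinations that a correlation screen then wrongly discards.  The
  cluster basis is therefore canonicalised: orthonormalise, then
  diagonalise the projection of `Cxx` onto the cluster, which yields
  mutually uncorrelated, variance-ordered within-cluster components that
  depend only on the (well-conditioned) invariant subspace.

Sources are the projections `p = a·X` of the *centred* streams; the
stream means (the slow trend) belong to no zero-mean component and are
restored after remixing, whatever was suppressed.  Remixing maps the
masked sources back through `a⁻¹` (least squares with a warning if `a` is
not invertible).

**Artifact recognition.**  A component is suppressed when
`|Pearson r(component, reference)| < τ` with τ = 0.1.  Zero-variance
components are suppressed by definition.  If *every* component falls below
τ the best-correlated one is kept — erasing the signal entirely is never
the right answer.  τ trades artifact rejection against loss of genuine
channel-specific activity; 0.1 rejects only components statistically
indistinguishable from reference-independent on a 10 s record.

**Wavelet smoothing** (`swt_denoise` module).  Default `sym4` at 4
levels, soft thresholding, stationary transform.  The SWT is computed on
the signal symmetric-padded to a multiple of `2^level` with periodic
convolution inside the transform, so on already-dyadic lengths the
transform (and the whole denoiser) is exactly shift-equivariant.  The
threshold per detail band minimises Stein's unbiased risk estimate over
the band's own coefficient magnitudes.  The noise scale is estimated
*once*, from the finest detail band, as `median(|d₁|)/0.6745`: for white
noise every band of an undecimated orthogonal-filter transform carries
the same noise variance, and the finest band is the one least occupied by
genuine signal.  (A per-band estimate would declare any dense narrow-band
content — an alpha rhythm, a narrowband IMF stream — to be "noise" at its
own scale and wipe it.)  A decimated DWT variant with periodised
boundaries is provided for comparison runs; it reconstructs exactly and
halves coefficient counts per level, but is not shift-equivariant.

**Reconstruction.**  Each surviving stream is denoised and the streams are
summed.  The delayed-copy alignment trims one sample at each end; those
two samples are copied from the input so the cleaned channel keeps the
original length.

## Evaluation metrics

* `MSE`/`RMSE` between cleaned channel and reference;
* `DSNR` — SNR gain in dB, `10·log₁₀(Σ(raw−ref)²/Σ(cleaned−ref)²)`,
  capped at ±120 dB; 0 when nothing changed, positive when cleaning moved
  the channel toward the reference;
* correlation improvement — `r(cleaned,ref) − r(raw,ref)`;
* `λ` — the same improvement as a percentage of the attainable headroom
  `1 − r(raw,ref)`; 100 means the cleaned channel correlates perfectly;
* confusion counts and ROC parameters (Sen, Spe, PPV, NPV, accuracy) from
  per-sample masks.  On real data per-sample artifact truth does not
  exist; the surrogate rule labels a sample artifactual when it departs
  from the reference by more than `θ` reference standard deviations
  (θ = 1), and a sample as *detected* when cleaning changed it by the same
  margin.  Ratios with zero denominators are reported as missing, never
  coerced to 0.

## Synthetic test bench

The generator (`synth` module) emulates a 16-channel, 256 Hz, 10 s block:

* clean channels mix a **shared** 1/f background (volume conduction; mean
  inter-channel correlation ≈ 0.8, typical of common-reference scalp
  montages) with weight 1.0, an individual 1/f background with weight 0.4,
  and an alpha-band oscillation (one frequency in 8–12 Hz per recording,
  per-channel random gain 0.2–0.4 and phase lag within ±0.4 rad —
  posterior alpha is coherent across electrodes).  Backgrounds are
  band-limited at 45 Hz, the realistic scalp-EEG rolloff; channels are
  scaled to a common standard deviation of 50 (microvolt-like units);
* one designated channel (index 7, mirroring typical clinical numbering)
  is scaled to 0.4 of the others' standard deviation and left
  uncontaminated, so lowest-std reference selection provably finds it;
* blinks: negative half-sine bumps of 300 ms at `blink_gain = 10` times
  the channel standard deviation (the half-sine's steep shoulders match
  real blink morphology; >90 % of its support exceeds one EEG standard
  deviation at that gain);
* EMG: 20–100 Hz Gaussian bursts of 200–500 ms, RMS three channel
  standard deviations, half-sine envelope;
* `artifact_snr_db` rescales each channel's artifact waveform so the
  clean-to-artifact power ratio hits the target exactly; the default
  (`None`) keeps natural amplitudes.  Contaminated data is exactly
  `clean + artifact` and event supports are recorded per channel.

What passing the synthetic suite shows: every algebraic contract holds
(reconstruction identities, solver equivalence, threshold optimality),
and under contamination twice as powerful as the EEG the chain reliably
moves the contaminated channel toward both the reference channel and the
true clean waveform.  What it does not show: performance on real EEG with
electrode drift, non-additive artifacts, line noise, or channel-specific
neural activity that the correlation screen cannot distinguish from
artifact — see limitations.

## Limitations

* A component is kept only if it correlates with the *reference channel*;
  genuinely channel-specific neural activity (e.g., a focal rhythm absent
  at the reference site) can be suppressed.  On a 10 s record the Pearson
  correlation of slow components has few effective degrees of freedom, so
  components near the τ boundary are classified with real uncertainty.
  Consequently, passing a channel with *no* artifact through the pipeline
  is only guaranteed near-lossless (< 1 % of variance) when the channel
  genuinely shares its activity with the reference.
* The canonical correlations of smooth streams are nearly degenerate;
  separation *within* such clusters is by construction variance-based
  (PCA-like), not correlation-based.
* EEMD with 3 ensembles is a light stabiliser, not a full ensemble; its
  injected-noise residue (≈ `noise_std/√3` of the signal std) is treated
  as part of the broadband tail and largely removed by suppression and
  wavelet smoothing.
* DSNR, λ and the σ-rule artifact masks all measure distance to the
  chosen reference, not to unknowable ground truth; on synthetic data the
  generator's clean waveform can be passed as `eval_reference` to measure
  true recovery.

## Reproduction script

`scripts/acceptance.py --seed S --out results.json` recomputes, from
scratch at run time: solver equivalence and SVD-oracle agreement over 100
random covariance instances; EMD/SWT/remix reconstruction errors; the
SURE-threshold agreement rate over 200 random sequences; the worked ROC
example; the closed-form 3.01 dB check; and recovery statistics over 20
synthetic recordings at −3 dB artifact SNR (success rate, median DSNR,
median correlation improvement, median λ, and the leftdiv-vs-inverse RMS
output difference).  All randomness derives from the single `--seed`.
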