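# gecca-eeg

Motion-artifact removal for scalp EEG by a three-stage cascade:

1. **EEMD** — ensemble empirical mode decomposition turns one contaminated
   channel into a matrix of intrinsic mode function (IMF) streams;
2. **GECCA** — canonical correlation analysis against a time-delayed copy
   separates the streams into autocorrelation-ordered components, solved
   either the textbook way (explicit covariance inverses) or by **left
   matrix division** (Gaussian elimination / LU factorisation, the
   "backslash" route), which avoids forming inverses and tolerates
   rank-deficient covariance blocks; components whose Pearson correlation
   with a clean reference channel falls below a threshold are suppressed;
3. **SWT** — stationary (undecimated, shift-invariant) wavelet denoising
   with SURE ("rigrsure") threshold selection smooths the surviving
   streams before they are summed back into a cleaned channel.

The package is aimed at biomedical-signal researchers who want each stage
of this cascade as a tested, composable library function — plus a
command-line tool, an evaluation suite (MSE/RMSE, DSNR, λ, correlation
improvement, confusion counts and ROC parameters) and a synthetic EEG
generator with known ground truth, so the whole chain is verifiable
without any data download.

## The model

CCA pairs the stream matrix `X` with a delayed copy
`Y[c, i] = X[c, i-1] + X[c, i+1]` (valid convolution with `[1 0 1]`).
With covariance blocks `Cxx, Cyy, Cxy, Cyx` of the stacked `Z = [X; Y]`
(diagonals regularised by `β = 1e-8`), the weight vectors solve

```
G a = ρ² a,   G = Cxx⁻¹ Cxy Cyy⁻¹ Cyx
```

The left-division solver computes `A = Cxx \ Cxy` and `B = Cyy \ Cyx` by
LU factorisation and eigen-decomposes `G = A·B` — no explicit inverse.
Because the canonical correlations ρ of EEG-like streams against their
delayed copy measure autocorrelation, broadband muscle activity collects
in the trailing components; eye blinks and other non-neural waveforms are
recognised by their weak Pearson correlation `|r| < τ` (default τ = 0.1)
with the reference channel (the channel with the smallest standard
deviation, presumed cleanest).

Evaluation against a reference `x_ref` uses, for raw channel `x` and
cleaned channel `x̂`:

```
DSNR = 10·log₁₀( Σ(x − x_ref)² / Σ(x̂ − x_ref)² )        [dB]
λ    = 100·( r(x̂, x_ref) − r(x, x_ref) ) / ( 1 − r(x, x_ref) )   [%]
```

together with MSE/RMSE, the plain correlation difference, and
Sen/Spe/PPV/NPV/accuracy from per-sample artifact masks.

## Worked example

```python
import numpy as np
from gecca_eeg import synth, pipeline

# 16 channels, 256 Hz, 10 s; blinks at 10x EEG amplitude plus EMG bursts,
# total artifact power 3 dB above the clean EEG (artifact_snr_db=-3)
rec = synth.generate(synth.SynthConfig(seed=7, artifact_snr_db=-3.0))

result = pipeline.run(rec.contaminated, channel=5,
                      config=pipeline.PipelineConfig(seed=7))
rep = result.report
print(f"reference channel : {result.provenance['reference_channel']}")
print(f"components kept   : {result.sources_kept}")
print(f"components removed: {result.sources_suppressed}")
print(f"DSNR              : {rep.dsnr_db:.2f} dB")
print(f"corr improvement  : {rep.corr_improvement:.4f}")
print(f"lambda            : {rep.lambda_pct:.1f} %")
```

prints

```
reference channel : 7
components kept   : [1, 3, 5, 6]
components removed: [0, 2, 4, 7]
DSNR              : 1.56 dB
corr improvement  : 0.0763
lambda            : 17.4 %
```

Channel 7 (the designated low-variance channel) is auto-selected as the
reference; four canonical components — the blink-dominated slow
components and the broadband tail — fall below τ and are zeroed.  The
positive DSNR says the cleaned channel moved 1.56 dB closer to the
reference; λ says 17 % of the attainable correlation headroom was
recovered.

The same chain is available from the shell:

```bash
gecca-eeg synth --seed 7 --out synth.csv --truth truth.json
gecca-eeg stats synth.csv
gecca-eeg run synth.csv --channel 5 --seed 7 --out cleaned.csv --report report.json
```

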