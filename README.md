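# cardiogate

Acoustic cardiac triggering (ACT) signal chain and trigger-fidelity
analysis for cardiovascular MR gating at ultrahigh field, with a synthetic
session generator providing ground truth.

The package covers:

- **`cardiogate.physio_io`** — plain-text multi-channel session logs
  (ECG 400 Hz, POX 50 Hz, ACT 200 Hz, respiration 50 Hz, microphone),
  per-modality trigger-tickmark trains, session metadata, and WAV
  microphone I/O.
- **`cardiogate.siggen`** — synthetic sessions: Gaussian R-R intervals, a
  29.65 ± 4.43 ms R-to-first-heart-tone delay, pulse-oximetry pulses with
  ~350 ms latency and amplitude/width scatter, a magneto-hydrodynamic
  T-wave elevation scaling with static field position (0.3 / 1.0 / 7.0 T),
  gradient-switching noise lines at k/TR and 1/TE calibrated to a peak
  third-octave SPL, breath-hold schedules, and an emulation of the
  scanner monitoring unit's threshold trigger detection.
- **`cardiogate.acoustics`** — SPL calibration against a 94 dB reference
  tone, Hann spectrograms in dB SPL, band SPL and acoustic SNR
  measurements, the 3rd-order inverse Chebyshev heart-sound low-pass
  (stopband edge 105 Hz, ≥ 30 dB), and first-heart-tone trigger detection
  (filter → rectified envelope → adaptive threshold → onset).
- **`cardiogate.trigfid`** — breath-hold gating of the traces,
  cross-correlation R-R segmentation with temporal realignment, tickmark
  reassignment, and the per-modality fidelity statistics: interval
  mean/SD, trigger-offset mean/SD, peak-to-peak jitter, failure rate.
- **`cardiogate.statrep`** — Bland-Altman limits of agreement, an exact
  Wilcoxon matched-pairs test (zeros dropped, midranks, full enumeration
  for small n), the paired t-test, consensus-score summaries, and CINE
  phase arithmetic.

Reference per-subject tables (trigger-variance and image-quality scores)
ship as CSV fixtures under `cardiogate/data/`.

## Command line

```sh
# synthesize a session log (+ optional WAV microphone and truth file)
cardiogate simulate --config config.yaml --out session.log \
    [--wav mic.wav] [--truth truth.json] [--seed 7]

# heart-sound filter coefficients
cardiogate filter-design --rate 2000 --cutoff 105 --order 3 --stopband 30 \
    --out filter.json

# calibrated SPL spectrogram from a WAV recording
cardiogate spectrogram --in mic.wav --cal 94db-tone.wav --out spec.csv

# first-heart-tone trigger detection on the ACT channel
cardiogate act-detect --in session.log --out triggers.txt

# full trigger-fidelity pipeline
cardiogate analyze --in session.log --out stats.json [--per-cycle offsets.csv]

# score summaries, Wilcoxon p-values and Bland-Altman agreement
cardiogate report --stats stats.json --scores table2.csv --out report.json
```

`config.yaml` mirrors `cardiogate.siggen.SimulationConfig` field names
(all fields optional), e.g.

```yaml
n_cycles: 200
rr_mean: 900.0
rr_sd: 50.0
field_position: isocenter
seed: 1
```

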