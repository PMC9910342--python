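# vocalps

Subglottal pressure (Ps) estimation from neck-surface accelerometry:
laboratory calibration against intraoral-pressure references, three Ps
estimation methods, glottal-airflow analysis via subglottal impedance-based
inverse filtering (IBIF), and a daylong ambulatory processing chain with
voice-activity detection and summary statistics. Because the underlying
human recordings are not distributable, the package ships first-class
synthetic-data generators that plant known ground truth for every pipeline
stage; the test suite closes the loop between generators and estimators.

## Modules

| Module | Role |
| --- | --- |
| `vocalps.core_signals` | physical-unit signal containers, sensor calibration lines, polyphase resampling (11,025 → 20,000 Hz), ACC↔mic cross-correlation alignment, WAV + sidecar-JSON I/O |
| `vocalps.lab_session` | vowel segmentation from the microphone energy contour, intraoral-pressure plateau detection, reference Ps per vowel |
| `vocalps.acc_features` | RMS, autocorrelation f0 with octave-error (subharmonic) correction, cepstral peak prominence, SPL @ 15 cm, low/high spectral ratio, log–log ACC→SPL mapping |
| `vocalps.ibif` | five-parameter trachea + neck-skin transfer model, forward/inverse filtering, PSO parameter fitting, glottal waveform measures (ACFL, MFDR, OQ, SQ, H1–H2, HRF, NAQ), physiological validity screen |
| `vocalps.ps_models` | Method 1 (empirical SPL/f0 formula), Method 2 (person-specific ACC-RMS line), Method 3 (forward-stepwise multiple regression with partial-F screening and five-fold cross-validation) |
| `vocalps.ambulatory` | 50-ms framing, five-criterion voice-activity detector, per-frame Ps tracking with a fixed participant IBIF model, daylong summaries and 5-min rolling profiles |
| `vocalps.synthetic` | glottal pulse trains with known shape quotients, simulated lab sessions with planted Ps laws, daylong voiced/unvoiced ACC streams, feature-level cohorts |
| `vocalps.evaluation` | per-participant RMSE (with the Method-1 outlier rule), paired Cohen's d, method-comparison tables |

## CLI

```bash
# synthetic four-channel lab session and a daylong ACC stream
vocalps simulate lab --seed 1 --out scratch/lab
vocalps simulate day --seed 1 --hours 0.1 --out scratch/day

# fit / apply Ps models from a per-segment feature TSV
vocalps fit --method 2 --features segments.tsv --out model.json
vocalps predict --model model.json --features segments.tsv --out pred.tsv

# ambulatory chain
vocalps process-day --acc scratch/day/day_acc.wav \
    --participant scratch/day/participant.json --out frames.tsv
vocalps summarize --frames frames.tsv
```

A participant spec for `simulate` may be given as YAML (`--spec spec.yaml`)
with any `vocalps.synthetic.ParticipantSpec` field, e.g.:

```yaml
sex: female
ps_slope: 2.0
ps_intercept: 3.0
vowels: [a, i, u]
pitches: [comfortable, higher, lower]
```

## Notes

- The IBIF realization (uniform lossy transmission line with a resistive
  lung termination plus a one-degree-of-freedom per-area skin oscillator) is
  an approximation consistent with the five named parameters, not a
  coefficient-level reproduction of the original subglottal impedance model.
- All generators are deterministic under a fixed seed; tests create their
  fixtures programmatically, so the repository contains no binary data.
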