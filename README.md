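# seqtime

Analysis pipeline for population calcium-imaging recordings from an
odor-cued delayed-non-match task in which the first odor's identity cues
the delay duration (2.5 s or 5.0 s), with occasional "reverse" trials
that swap the cue–delay contingency. The package covers everything from
the deconvolved activity matrix onward:

- **core_io** — task configuration, trial tables, session containers
  (HDF5 + sidecar trials CSV), aligned-tensor containers, validation.
- **synthetic** — a fully parameterized session generator: blocked
  pseudorandom trial schedules with an exact reverse-trial count, planted
  Gaussian-field sequence cells (with a tunable over-representation of
  fields just before the expected 2nd odor), lick behavior with plantable
  accuracy/latency effects, and sparse locomotion bouts. Ground truth is
  returned so every downstream stage can be tested by parameter recovery.
- **preprocessing** — signal conditioning (10-frame rolling mean,
  whole-session z-score, hard floor at 2 STD), trial alignment into a
  neurons × trials × bins tensor (5-frame bins, ~0.16 s at 30.9 Hz), and
  nearest-neighbor balancing of standard vs reverse trials.
- **sequence** — sequence-cell detection: preferred trial type by larger
  average peak, significance against the 95th percentile of 2000 circular
  shuffles within the odor + delay window (3.5 s / 6 s), a ≥ 20% trial
  reliability filter (≥ 2 STD event within 0.5 s of the peak), peak-sorted
  heatmaps, KS comparison of peak distributions, and 0.5-s-binned peak
  fractions with BH-corrected paired tests.
- **trajectory** — population-trajectory distance-from-baseline
  (−2 to 0 s baseline) and speed in full dimensional space, √n-normalized;
  PCA projections for visualization; per-bin condition tests with animal
  and day factors, BH-corrected at adjusted p < 0.01.
- **info_decoding** — per-neuron odor mutual information (20 activity
  levels, baseline bin at −1.5 s, bins in [−1, 11] s) and multiclass
  elapsed-time decoding in the 1.1–3.4 s window (7 classes of 1/3 s,
  linear one-vs-one SVM, trial-grouped 5-fold CV, score = correlation of
  actual vs predicted bins).
- **behavior** — trial scoring (3-s response window from 2nd-odor onset),
  accuracy and median lick-latency summaries, paired tests, locomotion
  z-binning and ≥ 1-s running-bout detection with per-trial flags.

## CLI

```bash
seqtime synth --seed 1 --out session.h5 --truth truth.csv
seqtime validate session.h5
seqtime align session.h5 --window -2 11 --bin-frames 5 --out aligned.h5
seqtime detect aligned.h5 --shuffles 2000 --percentile 95 --seed 1 --out cells.csv
seqtime trajectory aligned.h5 --cells cells.csv \
    --compare standard_short:reverse_short --out traj.csv
seqtime info aligned.h5 --out mi.csv
seqtime decode aligned.h5 --condition standard_short --folds 5 --seed 1 --out decode.json
seqtime behavior session.h5 --out behavior.csv
seqtime locomotion session.h5 --out running.csv
```

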