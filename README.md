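# sonoflow

Workflow analytics for multimodal obstetric ultrasound scanning.

Routine obstetric scanning can be instrumented end to end: the machine's
video output reveals every freeze, image/clip save and displayed measurement;
a remote eye tracker records where the sonographer looks on the 1920×1080
display; an IMU on the transducer records how the probe is moved; and a
microphone captures the sonographer's narration. `sonoflow` implements the
analysis chain that turns those streams into quantitative descriptions of
clinical workflow — and, because real scan recordings are governed by patient
data policies, it ships a first-class **synthetic session generator** whose
statistical structure matches a reference second-trimester workload, so every
stage is fully testable without clinical data.

It is intended for researchers studying sonography workflow, gaze behaviour
and probe motion, and for anyone building or validating similar multimodal
pipelines.

## What it computes

* **Machine events** — per-frame UI parsing (structured records, or rendered
  rasters read by exact glyph template matching) into a timeline of
  `freeze_on/off`, `image_save`, `clip_save` and `measurement_display`
  events; biometric displays (HC/AC/FL) are counted per type.
* **Event clips** — each important event anchors a 5-s clip
  `[max(0, t−5), t]`; windows overlapping an earlier clip by ≥ 50% are
  deduplicated; clips are labelled by the anatomy occupying the largest
  share of the window.
* **Fixation episodes** — an uninterrupted gaze run inside an AOI lasting
  ≥ 100 ms is a fixation; fixations separated by ≤ 400 ms merge into one
  episode (both thresholds inclusive, measured in time, not samples). Built
  on these: the thermal-safety audit (was the bioeffect box ever looked
  at?) and the biometry audit (fraction of measurement displays with a
  measurement-box episode within ±2 s).
* **Transducer orientation** — a gradient-descent complementary AHRS fuses
  gyroscope, accelerometer and magnetometer (Hamilton quaternions,
  sensor→world, world z up, gravity (0, 0, −9.81) m/s², horizontal +x
  magnetic reference, gain β = 0.1); world-frame linear acceleration is
  `R(q)·a_sensor + g`.
* **Workflow statistics** — per-scan label time shares (which sum to 1),
  cohort means with Student-t 95% CIs, time-normalized timeline matrices,
  confusion matrices and overall agreement between labelings, Pearson
  correlation of share vectors, and a nearest-centroid baseline classifier
  with a calibrated label-corruption model for agreement experiments.
* **Speech statistics** — lexicon-based part-of-speech fractions,
  vocabulary size and maximum sentence length of the narration transcript.

## Worked example

```python
from sonoflow import GeneratorConfig, simulate_session
from sonoflow.workflow import cohort_summary, shares_table

cfg = GeneratorConfig(seed=42, streams=())           # timelines only: fast
timelines = [simulate_session(cfg, i).timeline for i in range(50)]
print(cohort_summary(shares_table(timelines, cfg.label_set)).round(1).head(4))
```

```
              mean_pct  ci_lo_pct  ci_hi_pct  n_scans
thorax_heart      20.7       18.7       22.8       50
head_brain         9.3        7.9       10.7       50
mode_3d4d          3.0        2.2        3.7       50
unidentified      20.6       18.6       22.7       50
```

Each row is the cohort mean percentage of scan time spent on one anatomy
label with its 95% confidence interval — at 50 scans the cardiac share is
already close to the reference value of 21.5%. A full session carries every
stream:

```python
from sonoflow.ui_extraction import extract_event_timeline, count_biometric_measurements
from sonoflow.gaze import detect_fixation_episodes
from sonoflow.screen import MEASUREMENT_BOX

cfg = GeneratorConfig(seed=42, duration_mean=3.0, duration_sd=0.5,
                      duration_bounds=(2.0, 4.5))
s = simulate_session(cfg, 0)
events = extract_event_timeline(s.ui, s.frame_rate)
print(len(events), count_biometric_measurements(events))
print(detect_fixation_episodes(s.gaze, MEASUREMENT_BOX)[0])
```

```
16 {'HC': 1, 'AC': 2, 'FL': 1, 'total': 4}
FixationEpisode(aoi='measurement_box', t_start=126.12, t_end=126.91, n_fixations=1)
```

The 3-minute synthetic scan contains 16 machine events including four
biometric measurement displays, and the sonographer's gaze dwells on the
measurement box shortly after each display — the behaviour the biometry
audit quantifies.

The same chain is available from the shell:

```bash
sonoflow all --seed 7 --n-scans 5 --out runs/demo   # report in runs/demo/report.json
```

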