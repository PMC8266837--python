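"""Reference calibration tables for a routine second-trimester scanning workload.

These constants describe the statistical structure of routine obstetric
ultrasound sessions — how long scans take, which fetal anatomy the sonographer
dwells on and for what fraction of the scan, how often machine events
(freeze, image save, biometric measurement display) occur, and how
sonographers speak while scanning. They are cohort-level summaries of
real clinical practice and serve as the default parameters of the
synthetic session generator, so that simulated cohorts reproduce the
workload a downstream analysis would see in the clinic.

All percentages are expressed on a 0–100 scale exactly as a clinical
workflow report would print them.
"""

from __future__ import annotations

#: Canonical anatomy label set: the 12 most common standard-plane labels of a
#: second-trimester anomaly scan, plus a residual "other" category (mixed,
#: rare, or unidentifiable content).  Order is fixed and used everywhere a
#: label axis is needed (confusion matrices, share tables, feature vectors).
ANATOMY_LABELS: tuple[str, ...] = (
    "thorax_heart",
    "head_brain",
    "mode_3d4d",
    "unidentified",
    "spine",
    "abdomen",
    "maternal_anatomy",
    "coronal_face",
    "placenta_amniotic_fluid",
    "sagittal_face",
    "kidneys",
    "femur",
    "other",
)

#: Mean percentage of scan duration dedicated to each label across a cohort of
#: 341 full-length anomaly scans.  Sums to 100.2 due to per-label rounding in
#: the source table; the generator normalizes it to exactly 1.
SCAN_TIME_SHARE_PCT: dict[str, float] = {
    "thorax_heart": 21.5,
    "head_brain": 11.4,
    "mode_3d4d": 3.1,
    "unidentified": 17.7,
    "spine": 8.8,
    "abdomen": 5.9,
    "maternal_anatomy": 10.5,
    "coronal_face": 4.1,
    "placenta_amniotic_fluid": 4.3,
    "sagittal_face": 5.2,
    "kidneys": 1.6,
    "femur": 3.0,
    "other": 3.1,
}

#: 95% confidence intervals (percent) accompanying SCAN_TIME_SHARE_PCT.
SCAN_TIME_SHARE_CI_PCT: dict[str, tuple[float, float]] = {
    "thorax_heart": (20.4, 22.6),
    "head_brain": (10.8, 12.0),
    "mode_3d4d": (2.6, 3.6),
    "unidentified": (16.7, 18.7),
    "spine": (8.0, 9.5),
    "abdomen": (5.4, 6.4),
    "maternal_anatomy": (9.8, 11.1),
    "coronal_face": (3.7, 4.4),
    "placenta_amniotic_fluid": (3.9, 4.8),
    "sagittal_face": (4.7, 5.8),
    "kidneys": (1.3, 1.8),
    "femur": (2.7, 3.3),
    "other": (2.4, 3.8),
}

#: Prevalence (percent of 5-s event clips) of the 12 most common labels in a
#: manually annotated 62-scan training set.  The 12 printed values sum to
#: 87.9%; the residual 12.1% of clips carry rarer labels and are pooled under
#: "other" so that the distribution is a proper categorical over the full
#: label set while every named label keeps its printed prevalence.
CLIP_LABEL_PREVALENCE_PCT: dict[str, float] = {
    "thorax_heart": 19.6,
    "head_brain": 11.5,
    "mode_3d4d": 11.2,
    "unidentified": 11.0,
    "spine": 6.1,
    "abdomen": 5.5,
    "maternal_anatomy": 5.5,
    "coronal_face": 4.4,
    "placenta_amniotic_fluid": 4.2,
    "sagittal_face": 3.3,
    "kidneys": 2.9,
    "femur": 2.7,
    "other": 12.1,
}

#: Scan duration model (minutes): cohort mean and SD of full-length
#: second-trimester anomaly scans, truncated to plausible clinic bounds.
SCAN_DURATION_MEAN_MIN = 36.2
SCAN_DURATION_SD_MIN = 11.6
SCAN_DURATION_BOUNDS_MIN = (10.0, 90.0)

#: Acquisition rates.
VIDEO_FRAME_RATE_HZ = 30.0
IMU_SAMPLE_RATE_HZ = 100.0
#: Remote eye trackers in this class sample near 90 Hz; the device rate is a
#: generator default, not a clinical measurement.
GAZE_SAMPLE_RATE_HZ = 90.0

#: Screen geometry of the ultrasound display (full HD).
SCREEN_WIDTH = 1920
SCREEN_HEIGHT = 1080

#: Part-of-speech token distribution of sonographer speech during scanning
#: (percent of tokens): adjectives, determiners, nouns, verbs; the remainder
#: covers prepositions, pronouns, adverbs and other parts of speech.
POS_TAGS: tuple[str, ...] = ("adjective", "determiner", "noun", "verb", "other")
POS_TOKEN_PCT: dict[str, float] = {
    "adjective": 12.7,
    "determiner": 22.2,
    "noun": 28.0,
    "verb": 16.0,
    "other": 21.1,
}
#: Approximate sonographer working vocabulary (unique words) and the longest
#: observed utterance (words).
VOCABULARY_SIZE = 344
MAX_SENTENCE_WORDS = 83

#: Biometric measurement displays identified over 272 third-trimester growth
#: scans: head circumference (HC), abdominal circumference (AC), femur length
#: (FL).  Total 1409.
BIOMETRY_MEASUREMENT_COUNTS: dict[str, int] = {"HC": 354, "AC": 703, "FL": 352}
BIOMETRY_N_SCANS = 272

#: Thermal-safety gaze audit: number of routine scans in which the displayed
#: bioeffect (thermal index) box received at least one fixation episode, out
#: of the audited total.  27/637 = 4.2%.
BIOEFFECT_LOOKED_SCANS = 27
BIOEFFECT_AUDIT_SCANS = 637

#: Clip-label agreement benchmarks (percent): between human annotators, and
#: between manual and automatic labeling of the same scans.
INTER_ANNOTATOR_AGREEMENT_PCT = 76.1
MANUAL_AUTO_AGREEMENT_PCT = 76.4
MANUAL_AUTO_SHARE_CORRELATION = 0.98


def normalized_shares(pct: dict[str, float]) -> dict[str, float]:
    """Rescale a percentage table to fractions summing to exactly 1."""
    total = sum(pct.values())
    return {k: v / total for k, v in pct.items()}
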