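"""Scan timelines and cohort workflow statistics.

Turns per-frame or per-clip anatomy labels into scan timelines, per-scan
time shares, cohort summaries with 95% confidence intervals, normalized
timeline matrices for time-course visualization, and confusion/agreement
analyses between two labelings of the same clips.  A nearest-centroid
baseline classifier and a calibrated label-corruption model stand in for
the study-scale video classifier so that agreement machinery can be
exercised at a controlled error rate.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .session import LabelSegment

DEFAULT_MODE_WINDOW = 31     # frames
DEFAULT_MIN_SEGMENT_S = 1.0


# ---------------------------------------------------------------------------
# Frame-label regularization and timelines
# ---------------------------------------------------------------------------


def regularize_frame_labels(
    labels: Sequence[str],
    frame_rate: float,
    window: int = DEFAULT_MODE_WINDOW,
    min_segment: float = DEFAULT_MIN_SEGMENT_S,
) -> list[str]:
    """Temporally smooth a per-frame label sequence.

    A centered sliding-window mode filter removes frame-level flicker (ties
    keep the previously output label when it is among the modes, otherwise
    the tied label occurring earliest in the window), then segments shorter
    than ``min_segment`` seconds are absorbed into their longer neighbor.
    Output length equals input length and no label absent from the input
    window is ever introduced.
    """
    labels = list(labels)
    n = len(labels)
    if n == 0:
        return []
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd frame count")
    half = window // 2

    smoothed: list[str] = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        counts = Counter(labels[lo:hi])
        top = max(counts.values())
        modes = [lab for lab, c in counts.items() if c == top]
        if len(modes) == 1:
            pick = modes[0]
        elif smoothed and smoothed[-1] in modes:
            pick = smoothed[-1]
        else:
            order = {lab: labels[lo:hi].index(lab) for lab in modes}
            pick = min(modes, key=order.get)
        smoothed.append(pick)

    # Merge short segments into the longer neighbor until none remain.
    min_frames = max(1, int(round(min_segment * frame_rate)))
    runs: list[list] = []
    for lab in smoothed:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    while len(runs) > 1:
        short = [
            k for k, (_, length) in enumerate(runs) if length < min_frames
        ]
        if not short:
            break
        k = min(short, key=lambda j: (runs[j][1], j))
        if k == 0:
            target = 1
        elif k == len(runs) - 1:
            target = k - 1
        else:
            # longer neighbor absorbs; ties go to the later neighbor
            target = k + 1 if runs[k + 1][1] >= runs[k - 1][1] else k - 1
        runs[target][1] += runs[k][1]
        del runs[k]
        if target > k:
            target -= 1
        # absorbing may create adjacent equal-label runs; fuse them
        j = max(0, target - 1)
        while j < len(runs) - 1:
            if runs[j][0] == runs[j + 1][0]:
                runs[j][1] += runs[j + 1][1]
                del runs[j + 1]
            else:
                j += 1
    out: list[str] = []
    for lab, length in runs:
        out.extend([lab] * length)
    return out


def timeline_from_frames(
    labels: Sequence[str], frame_rate: float, scan_id: str = ""
) -> list[LabelSegment]:
    """Run-length encode a frame-label sequence into contiguous segments.

    Frame ``i`` covers ``[i / frame_rate, (i + 1) / frame_rate)``.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty frame-label sequence")
    segments: list[LabelSegment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append(
                LabelSegment(labels[start], start / frame_rate, i / frame_rate)
            )
            start = i
    return segments


def frames_from_timeline(
    timeline: Sequence[LabelSegment], frame_rate: float
) -> list[str]:
    """Inverse of :func:`timeline_from_frames`: label of each frame midpoint."""
    duration = timeline[-1].end
    n = int(round(duration * frame_rate))
    mids = (np.arange(n) + 0.5) / frame_rate
    ends = np.array([s.end for s in timeline])
    idx = np.minimum(np.searchsorted(ends, mids, side="right"), len(timeline) - 1)
    return [timeline[i].label for i in idx]


# ---------------------------------------------------------------------------
# Time shares and cohort summaries
# ---------------------------------------------------------------------------


def time_shares(
    timeline: Sequence[LabelSegment], label_set: Optional[Sequence[str]] = None
) -> dict[str, float]:
    """Per-label fraction of scan duration (fractions sum to 1).

    With ``label_set`` given, every listed label appears in the output
    (zero-share labels included), in the listed order.
    """
    if not timeline:
        raise ValueError("empty timeline")
    duration = sum(s.duration for s in timeline)
    if duration <= 0:
        raise ValueError("timeline has zero duration")
    acc: dict[str, float] = {}
    for s in timeline:
        acc[s.label] = acc.get(s.label, 0.0) + s.duration
    if label_set is None:
        return {lab: d / duration for lab, d in sorted(acc.items())}
    return {lab: acc.get(lab, 0.0) / duration for lab in label_set}


def cohort_summary(shares: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Cohort mean share and Student-t confidence interval per label.

    ``shares`` holds one row per scan and one column per label, as
    *percentages*.  Returns a DataFrame indexed by label with columns
    ``mean_pct, ci_lo_pct, ci_hi_pct, n_scans``.
    """
    n = len(shares)
    if n < 2:
        raise ValueError("cohort summary requires at least two scans")
    mean = shares.mean(axis=0)
    sem = shares.std(axis=0, ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    return pd.DataFrame(
        {
            "mean_pct": mean,
            "ci_lo_pct": mean - tcrit * sem,
            "ci_hi_pct": mean + tcrit * sem,
            "n_scans": n,
        }
    )


def shares_table(
    timelines: Sequence[Sequence[LabelSegment]], label_set: Sequence[str]
) -> pd.DataFrame:
    """Per-scan share percentages (rows = scans, columns = label_set)."""
    rows = [
        {lab: 100.0 * f for lab, f in time_shares(tl, label_set).items()}
        for tl in timelines
    ]
    return pd.DataFrame(rows, columns=list(label_set))


def normalized_timeline_matrix(
    timelines: Sequence[Sequence[LabelSegment]], n_bins: int = 100
) -> np.ndarray:
    """Resample each scan to ``n_bins`` equal time bins of majority labels.

    Returns an object array (n_scans, n_bins) of labels — each row is one
    scan's anatomy time-course normalized to percent of scan length.
    """
    out = np.empty((len(timelines), n_bins), dtype=object)
    for r, tl in enumerate(timelines):
        duration = tl[-1].end
        edges = np.linspace(0.0, duration, n_bins + 1)
        for b in range(n_bins):
            b0, b1 = edges[b], edges[b + 1]
            best_lab, best_ov, best_end = None, -1.0, -1.0
            for seg in tl:
                ov = min(seg.end, b1) - max(seg.start, b0)
                if ov > 0 and (ov > best_ov or (ov == best_ov and seg.end > best_end)):
                    best_lab, best_ov, best_end = seg.label, ov, seg.end
            out[r, b] = best_lab
    return out


# ---------------------------------------------------------------------------
# Agreement analyses
# ---------------------------------------------------------------------------


def confusion(
    labels_a: Sequence[str],
    labels_b: Sequence[str],
    label_set: Optional[Sequence[str]] = None,
) -> dict:
    """Confusion matrix and overall agreement between two labelings.

    Rows are ``labels_a`` (the reference), columns ``labels_b``.  Returns::

        {"labels": [...], "matrix": DataFrame counts,
         "agreement": matching fraction,
         "row_normalized": DataFrame (rows summing to 1 where occupied)}
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label lists differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    if len(labels_a) == 0:
        raise ValueError("empty label lists")
    if label_set is None:
        label_set = sorted(set(labels_a) | set(labels_b))
    label_set = list(label_set)
    a = pd.Categorical(labels_a, categories=label_set)
    b = pd.Categorical(labels_b, categories=label_set)
    matrix = pd.crosstab(a, b, dropna=False)
    matrix = matrix.reindex(index=label_set, columns=label_set, fill_value=0)
    agreement = float(np.trace(matrix.to_numpy()) / len(labels_a))
    row_sums = matrix.sum(axis=1).replace(0, 1)
    return {
        "labels": label_set,
        "matrix": matrix,
        "agreement": agreement,
        "row_normalized": matrix.div(row_sums, axis=0),
    }


def share_correlation(shares_a: np.ndarray, shares_b: np.ndarray) -> float:
    """Pearson correlation between two flattened per-scan-per-label share sets."""
    a = np.asarray(shares_a, dtype=float).ravel()
    b = np.asarray(shares_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("share arrays must have the same shape")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(a, b)[0])


def corrupt_labels(
    labels: Sequence[str],
    target_agreement: float,
    label_set: Sequence[str],
    rng: np.random.Generator,
) -> list[str]:
    """Corrupt a label list so expected agreement equals ``target_agreement``.

    Each label is independently replaced, with probability
    ``1 - target_agreement``, by a uniformly chosen *different* label from
    ``label_set`` — a flat error model whose expected confusion-matrix
    diagonal mass is exactly the target.
    """
    if not 0.0 <= target_agreement <= 1.0:
        raise ValueError("target_agreement must lie in [0, 1]")
    label_set = list(label_set)
    out = []
    for lab in labels:
        if rng.random() < 1.0 - target_agreement:
            others = [x for x in label_set if x != lab]
            out.append(others[rng.integers(len(others))])
        else:
            out.append(lab)
    return out


# ---------------------------------------------------------------------------
# Baseline clip classifier
# ---------------------------------------------------------------------------


def label_centroids(label_set: Sequence[str]) -> dict[str, np.ndarray]:
    """Unit one-hot feature centroid per label (the generator's convention)."""
    eye = np.eye(len(label_set))
    return {lab: eye[i] for i, lab in enumerate(label_set)}


def baseline_classify(
    features: np.ndarray, centroids: dict[str, np.ndarray]
) -> list[str]:
    """Nearest-centroid label prediction on clip feature vectors.

    Distance ties break to the lexicographically first label, making the
    classifier fully deterministic.
    """
    labs = sorted(centroids)
    cents = np.stack([centroids[lab] for lab in labs])
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != cents.shape[1]:
        raise ValueError("feature dimension does not match centroids")
    d2 = ((features[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    # argmin returns the first (lexicographically smallest) label on ties
    return [labs[i] for i in np.argmin(d2, axis=1)]


def calibrate_feature_noise(
    target_accuracy: float,
    label_set: Sequence[str],
    rng: np.random.Generator,
    n_mc: int = 4000,
    tol: float = 0.004,
) -> float:
    """Noise SD making nearest-centroid accuracy approximate a target.

    Bisects the isotropic Gaussian feature-noise sigma with a Monte-Carlo
    accuracy estimate at each step (balanced label draws).
    """
    if not 1.0 / len(label_set) < target_accuracy <= 1.0:
        raise ValueError("target_accuracy must exceed chance and be <= 1")
    cents = label_centroids(label_set)
    labs = list(label_set)

    def acc(sigma: float) -> float:
        truth = [labs[i % len(labs)] for i in range(n_mc)]
        feats = np.stack([cents[lab] for lab in truth]) + rng.normal(
            0.0, sigma, (n_mc, len(labs))
        )
        pred = baseline_classify(feats, cents)
        return float(np.mean([p == t for p, t in zip(pred, truth)]))

    lo, hi = 0.01, 3.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        a = acc(mid)
        if abs(a - target_accuracy) < tol:
            return mid
        if a > target_accuracy:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
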