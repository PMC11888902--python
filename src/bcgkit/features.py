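"""Segmentation into 30-s windows and per-channel summary statistics.

Each preprocessed recording is cut into non-overlapping windows (3,000 samples
at 100 Hz for the default 30-s window) and each window is summarised per
channel by 11 statistics: mean, standard deviation, median, maximum, minimum,
range, first and third quartiles, interquartile range, excess kurtosis and
skewness. Moments use the population (divisor-n) convention; quartiles use
linear interpolation between order statistics; constant channels get skewness
and kurtosis 0 by convention. These conventions are fixed so downstream
results are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bcgkit.recording import LABEL_CODES, SignalRecording

#: the 11 statistics, in table column order
FEATURE_STATS = (
    "mean",
    "std",
    "median",
    "max",
    "min",
    "range",
    "q1",
    "q3",
    "iqr",
    "kurtosis",
    "skewness",
)

META_COLUMNS = ("source_id", "start_sample", "label")


@dataclass
class Segment:
    """One fixed-length labeled window, traceable to its source recording."""

    source_id: str
    label: str
    start_sample: int
    samples: np.ndarray  # (window_samples, n_channels)
    sampling_rate_hz: float
    channel_names: list[str]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def name(self) -> str:
        """Stable identifier ``<source>_<index>_<label>`` used for filenames."""
        return f"{self.source_id}_{self.start_sample}_{self.label}"


def segment_recording(
    rec: SignalRecording, window_s: float = 30.0, overlap_s: float = 0.0
) -> list[Segment]:
    """Split a recording into consecutive windows of ``floor(window_s * fs)``
    samples, starting at sample 0.

    The default is non-overlapping windows; a trailing remainder shorter than
    one window is dropped. A recording shorter than one window yields an
    empty list. Each segment inherits the recording's label.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if overlap_s < 0 or overlap_s >= window_s:
        raise ValueError("overlap_s must lie in [0, window_s)")
    if not rec.is_uniform:
        raise ValueError("recording is not uniformly sampled")
    win = int(np.floor(window_s * rec.sampling_rate_hz))
    step = int(np.floor((window_s - overlap_s) * rec.sampling_rate_hz))
    segments = []
    for start in range(0, rec.n_samples - win + 1, step):
        segments.append(
            Segment(
                source_id=rec.subject_id,
                label=rec.label,
                start_sample=start,
                samples=rec.channels[start : start + win].copy(),
                sampling_rate_hz=rec.sampling_rate_hz,
                channel_names=list(rec.channel_names),
            )
        )
    return segments


def _channel_stats(x: np.ndarray) -> dict:
    """The 11 statistics of one channel, population-moment convention."""
    mean = float(np.mean(x))
    m2 = float(np.mean((x - mean) ** 2))
    std = float(np.sqrt(m2))
    q1, med, q3 = (float(v) for v in np.quantile(x, [0.25, 0.5, 0.75]))
    mx, mn = float(np.max(x)), float(np.min(x))
    if m2 > 0:
        m3 = float(np.mean((x - mean) ** 3))
        m4 = float(np.mean((x - mean) ** 4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0  # excess kurtosis
    else:
        skew = 0.0
        kurt = 0.0
    return {
        "mean": mean,
        "std": std,
        "median": med,
        "max": mx,
        "min": mn,
        "range": mx - mn,
        "q1": q1,
        "q3": q3,
        "iqr": q3 - q1,
        "kurtosis": kurt,
        "skewness": skew,
    }


def extract_features(seg: Segment) -> dict:
    """Compute the 11 statistics for every channel of one segment.

    Returns a flat dict with keys ``<channel>_<stat>`` plus the segment's
    ``source_id``, ``start_sample`` and integer ``label`` (hypertensive=1,
    normotensive=0).
    """
    if seg.n_samples == 0:
        raise ValueError("empty segment")
    out: dict = {
        "source_id": seg.source_id,
        "start_sample": seg.start_sample,
        "label": LABEL_CODES.get(seg.label, -1),
    }
    for c, name in enumerate(seg.channel_names):
        stats = _channel_stats(seg.samples[:, c])
        for stat in FEATURE_STATS:
            out[f"{name}_{stat}"] = stats[stat]
    return out


def build_feature_table(segments: list[Segment]) -> pd.DataFrame:
    """Feature table with one row per segment, in input order.

    Columns: ``source_id``, ``start_sample``, ``label`` then
    ``<channel>_<stat>`` for each channel and each of the 11 statistics
    (2 channels -> 22 feature columns). Column names are deterministic.
    """
    if not segments:
        raise ValueError("no segments")
    n_ch = segments[0].n_channels
    names = tuple(segments[0].channel_names)
    for seg in segments:
        if seg.n_channels != n_ch or tuple(seg.channel_names) != names:
            raise ValueError("segments have inconsistent channels")
    return pd.DataFrame([extract_features(s) for s in segments])


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a feature table into ``(X, y, groups)`` arrays.

    ``groups`` holds the source recording id of each row, used by
    group-aware splitters to keep sibling segments on one side.
    """
    feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    X = table[feature_cols].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    groups = table["source_id"].to_numpy()
    return X, y, groups


def standardize_features(
    train: np.ndarray, *others: np.ndarray
) -> tuple[list[np.ndarray], dict]:
    """Standardize columns to zero mean / unit variance using train statistics.

    The scaler is fitted on ``train`` only (population SD; constant columns
    use SD 1) and then applied unchanged to every other matrix, so no test
    information leaks into the scaling.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("empty training matrix")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    params = {"mean": mean, "sd": sd}
    results = [(m - mean) / sd for m in (train, *others)]
    return results, params
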