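"""Container and CSV I/O for uniformly sampled multi-channel BCG recordings."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LABELS = ("hypertensive", "normotensive", "unlabeled")

#: integer encoding used throughout: hypertensive is the positive class
LABEL_CODES = {"normotensive": 0, "hypertensive": 1}

_UNIFORM_TOL_S = 1e-9


@dataclass
class SignalRecording:
    """A multi-channel pressure-sensor time series with a class label.

    ``channels`` is an ``(n_samples, n_channels)`` array in arbitrary pressure
    units; ``time_s`` holds the sample times. Recordings produced by the
    generator are uniformly sampled; dropping anomalous rows (see
    :func:`bcgkit.preprocess.remove_anomalies`) may break uniformity, which
    downstream filters detect via :attr:`is_uniform`.
    """

    subject_id: str
    label: str
    sampling_rate_hz: float
    time_s: np.ndarray
    channels: np.ndarray
    channel_names: list[str]
    #: ground-truth beat centre times (s), kept by the synthetic generator
    beat_times_s: np.ndarray | None = None
    #: free-form provenance (generator parameters, preprocessing stages, ...)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.channels.shape[0] != self.time_s.shape[0]:
            raise ValueError(
                f"channels has {self.channels.shape[0]} rows but time_s has "
                f"{self.time_s.shape[0]} samples"
            )
        if len(self.channel_names) != self.channels.shape[1]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_samples(self) -> int:
        return self.time_s.shape[0]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def is_uniform(self) -> bool:
        """True when sample times form a constant 1/fs grid (1 ns tolerance)."""
        if self.n_samples < 2:
            return True
        steps = np.diff(self.time_s)
        return bool(np.all(np.abs(steps - 1.0 / self.sampling_rate_hz) < _UNIFORM_TOL_S))

    def replace_channels(self, channels: np.ndarray, **meta) -> "SignalRecording":
        """Copy of this recording with new channel data (same time axis)."""
        return SignalRecording(
            subject_id=self.subject_id,
            label=self.label,
            sampling_rate_hz=self.sampling_rate_hz,
            time_s=self.time_s.copy(),
            channels=np.asarray(channels, dtype=float),
            channel_names=list(self.channel_names),
            beat_times_s=None if self.beat_times_s is None else self.beat_times_s.copy(),
            meta={**self.meta, **meta},
        )

    # ------------------------------------------------------------------ I/O

    def to_csv(self, directory: str | Path) -> Path:
        """Write ``<subject>_<label>.csv`` plus a JSON metadata sidecar.

        The CSV has a ``time`` column followed by one column per sensor
        channel; the class label is encoded in the filename.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / f"{self.subject_id}_{self.label}.csv"
        df = pd.DataFrame({"time": self.time_s})
        for i, name in enumerate(self.channel_names):
            df[name] = self.channels[:, i]
        df.to_csv(path, index=False, float_format="%.10g")
        sidecar = {
            "subject_id": self.subject_id,
            "label": self.label,
            "sampling_rate_hz": self.sampling_rate_hz,
            "channel_names": list(self.channel_names),
            "beat_times_s": None
            if self.beat_times_s is None
            else [round(float(t), 10) for t in self.beat_times_s],
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SignalRecording":
        """Read a recording written by :meth:`to_csv`.

        Without a sidecar the label is parsed from the ``<subject>_<label>``
        filename convention and the sampling rate inferred from the time axis.
        """
        path = Path(path)
        df = pd.read_csv(path)
        if "time" not in df.columns:
            raise ValueError(f"{path} has no 'time' column")
        sidecar_path = path.with_suffix(".json")
        if sidecar_path.exists():
            side = json.loads(sidecar_path.read_text())
            label = side["label"]
            subject_id = side["subject_id"]
            fs = float(side["sampling_rate_hz"])
            beat_times = side.get("beat_times_s")
            beat_times = None if beat_times is None else np.asarray(beat_times, float)
            meta = side.get("meta", {})
        else:
            stem = path.stem
            label = next((l for l in LABELS if stem.endswith("_" + l)), "unlabeled")
            subject_id = stem[: -len(label) - 1] if stem.endswith("_" + label) else stem
            t = df["time"].to_numpy()
            fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
            beat_times, meta = None, {}
        channel_names = [c for c in df.columns if c != "time"]
        return cls(
            subject_id=subject_id,
            label=label,
            sampling_rate_hz=fs,
            time_s=df["time"].to_numpy(),
            channels=df[channel_names].to_numpy(),
            channel_names=channel_names,
            beat_times_s=beat_times,
            meta=meta,
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
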