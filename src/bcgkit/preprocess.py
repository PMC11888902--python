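"""Four-stage BCG preprocessing: filter cascade, anomaly removal, baseline
correction, min-max normalization.

The chain (in fixed order) is: 1 Hz high-pass -> 50 Hz low-pass (clamped below
Nyquist) -> threshold anomaly detection/removal -> 0.5 Hz baseline high-pass ->
per-channel min-max scaling to [0, 1]. Filters are order-4 Butterworth applied
forward-backward (zero phase) so waveform timing is preserved; the time column
is never filtered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from bcgkit.recording import SignalRecording

#: cutoffs at or above Nyquist are clamped to this fraction of Nyquist
NYQUIST_CLAMP = 0.99

STAGE_ORDER = ("highpass", "lowpass", "anomaly", "baseline", "normalize")


@dataclass
class FilterSpec:
    """A one-sided Butterworth filter: high- or low-pass at ``cutoff_hz``."""

    kind: str  # "highpass" | "lowpass"
    cutoff_hz: float
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError(f"kind must be 'highpass' or 'lowpass', got {self.kind!r}")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def effective_cutoff(self, sampling_rate_hz: float, clamp: bool = True) -> float:
        """Cutoff actually used, clamping at 0.99x Nyquist when necessary.

        A stated cutoff at or above Nyquist (e.g. 50 Hz at 100 Hz sampling) is
        unrealizable; clamping honors the intent of removing high-frequency
        noise while keeping the design well-posed.
        """
        nyq = sampling_rate_hz / 2.0
        if self.cutoff_hz < nyq:
            return self.cutoff_hz
        if not clamp:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz is not below Nyquist ({nyq} Hz) "
                "and clamping is disabled"
            )
        clamped = NYQUIST_CLAMP * nyq
        warnings.warn(
            f"{self.kind} cutoff {self.cutoff_hz} Hz >= Nyquist {nyq} Hz; "
            f"clamped to {clamped} Hz",
            stacklevel=2,
        )
        return clamped

    def design_sos(self, sampling_rate_hz: float, clamp: bool = True) -> np.ndarray:
        cutoff = self.effective_cutoff(sampling_rate_hz, clamp=clamp)
        return signal.butter(
            self.order, cutoff, btype=self.kind, fs=sampling_rate_hz, output="sos"
        )


@dataclass
class AnomalyMask:
    """Per-sample, per-channel flags where value > channel mean + k*std."""

    flags: np.ndarray  # boolean, (n_samples, n_channels)
    threshold_per_channel: np.ndarray
    k: float = 2.0

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


@dataclass
class PreprocessConfig:
    highpass_hz: float = 1.0
    lowpass_hz: float = 50.0
    anomaly_k: float = 2.0
    anomaly_mode: str = "interpolate"  # "interpolate" | "drop"
    baseline_hz: float = 0.5
    filter_order: int = 4
    #: stage order is fixed; accepted only if it matches STAGE_ORDER
    stage_order: tuple = field(default_factory=lambda: STAGE_ORDER)

    def __post_init__(self) -> None:
        if tuple(self.stage_order) != STAGE_ORDER:
            raise ValueError(f"stage order is fixed: {STAGE_ORDER}")
        if self.anomaly_mode not in ("interpolate", "drop"):
            raise ValueError("anomaly_mode must be 'interpolate' or 'drop'")


def apply_filter(rec: SignalRecording, spec: FilterSpec, clamp: bool = True) -> SignalRecording:
    """Filter every sensor channel independently; the time axis is untouched.

    Zero-phase specs use forward-backward filtering (``sosfiltfilt``), which
    doubles the effective order and removes group delay. Requires a uniformly
    sampled recording longer than the filter warm-up length.
    """
    if not rec.is_uniform:
        raise ValueError("recording is not uniformly sampled; cannot filter")
    sos = spec.design_sos(rec.sampling_rate_hz, clamp=clamp)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if spec.zero_phase and rec.n_samples <= padlen:
        raise ValueError(
            f"recording too short ({rec.n_samples} samples) for zero-phase "
            f"filtering (needs > {padlen})"
        )
    if spec.zero_phase:
        out = signal.sosfiltfilt(sos, rec.channels, axis=0)
    else:
        out = signal.sosfilt(sos, rec.channels, axis=0)
    return rec.replace_channels(out)


def detect_anomalies(rec: SignalRecording, k: float = 2.0) -> AnomalyMask:
    """Flag samples strictly above their channel's mean + k*std.

    Statistics are computed per channel over the whole (unmodified) recording
    with population standard deviation. The rule is one-sided: only positive
    excursions count, as large pressure spikes from body movement are upward.
    """
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples per channel")
    mean = rec.channels.mean(axis=0)
    std = rec.channels.std(axis=0)
    thresholds = mean + k * std
    flags = rec.channels > thresholds[None, :]
    return AnomalyMask(flags=flags, threshold_per_channel=thresholds, k=k)


def remove_anomalies(
    rec: SignalRecording, mask: AnomalyMask, mode: str = "interpolate"
) -> SignalRecording:
    """Remove flagged samples.

    ``interpolate`` (default) replaces each flagged sample by linear
    interpolation between its nearest unflagged neighbours (edge flags take
    the nearest unflagged value), preserving the uniform grid the later
    filters require. ``drop`` deletes any row with a flag in some channel —
    faithful to "removed from the dataset" but it breaks uniform sampling,
    so downstream filters will refuse the result.
    """
    if mask.flags.shape != rec.channels.shape:
        raise ValueError("mask shape does not match recording")
    if mode == "interpolate":
        out = rec.channels.copy()
        idx = np.arange(rec.n_samples)
        for c in range(rec.n_channels):
            flagged = mask.flags[:, c]
            if not flagged.any():
                continue
            if flagged.all():
                raise ValueError(f"all samples flagged in channel {c}; nothing to interpolate from")
            # np.interp extends with edge values outside the known range
            out[flagged, c] = np.interp(idx[flagged], idx[~flagged], out[~flagged, c])
        return rec.replace_channels(out, anomalies_interpolated=int(mask.flags.sum()))
    if mode == "drop":
        keep = ~mask.flags.any(axis=1)
        if not keep.any():
            raise ValueError("all samples flagged; empty recording")
        return SignalRecording(
            subject_id=rec.subject_id,
            label=rec.label,
            sampling_rate_hz=rec.sampling_rate_hz,
            time_s=rec.time_s[keep],
            channels=rec.channels[keep],
            channel_names=list(rec.channel_names),
            meta={**rec.meta, "anomalies_dropped": int((~keep).sum())},
        )
    raise ValueError(f"unknown mode {mode!r}")


def baseline_correct(
    rec: SignalRecording, cutoff_hz: float = 0.5, order: int = 4
) -> SignalRecording:
    """Remove slow baseline wander with a zero-phase high-pass filter."""
    return apply_filter(rec, FilterSpec("highpass", cutoff_hz, order=order))


def minmax_normalize(rec: SignalRecording) -> SignalRecording:
    """Scale each channel affinely onto [0, 1]; constant channels map to zeros."""
    lo = rec.channels.min(axis=0)
    hi = rec.channels.max(axis=0)
    span = hi - lo
    out = np.zeros_like(rec.channels)
    nonconst = span > 0
    out[:, nonconst] = (rec.channels[:, nonconst] - lo[nonconst]) / span[nonconst]
    return rec.replace_channels(out)


def preprocess_pipeline(
    rec: SignalRecording, cfg: PreprocessConfig | None = None
) -> SignalRecording:
    """Run the full fixed-order preprocessing chain on one recording.

    Stage parameters are logged into the output's ``meta["preprocess_stages"]``.
    """
    cfg = cfg or PreprocessConfig()
    stages = []

    hp = FilterSpec("highpass", cfg.highpass_hz, order=cfg.filter_order)
    rec = apply_filter(rec, hp)
    stages.append({"stage": "highpass", "cutoff_hz": cfg.highpass_hz, "order": cfg.filter_order})

    lp = FilterSpec("lowpass", cfg.lowpass_hz, order=cfg.filter_order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the clamp is recorded in the stage log
        eff = lp.effective_cutoff(rec.sampling_rate_hz)
        rec = apply_filter(rec, lp)
    stages.append(
        {"stage": "lowpass", "cutoff_hz": cfg.lowpass_hz, "effective_cutoff_hz": eff,
         "order": cfg.filter_order}
    )

    mask = detect_anomalies(rec, k=cfg.anomaly_k)
    rec = remove_anomalies(rec, mask, mode=cfg.anomaly_mode)
    stages.append(
        {"stage": "anomaly", "k": cfg.anomaly_k, "mode": cfg.anomaly_mode,
         "n_flagged": mask.n_flagged}
    )

    rec = baseline_correct(rec, cutoff_hz=cfg.baseline_hz, order=cfg.filter_order)
    stages.append({"stage": "baseline", "cutoff_hz": cfg.baseline_hz, "order": cfg.filter_order})

    rec = minmax_normalize(rec)
    stages.append({"stage": "normalize", "method": "minmax"})

    rec.meta["preprocess_stages"] = stages
    return rec
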