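"""Synthetic ballistocardiogram generator with class-dependent parameters.

Emulates 100 Hz mattress pressure-sensor signals: a quasi-periodic train of
heartbeat complexes (each a Gaussian-windowed cosine standing in for the BCG
IJK waveform), sinusoidal respiratory baseline wander, slow drift, broadband
Gaussian noise and sparse large-amplitude artifact spikes. The two classes
("hypertensive" / "normotensive") differ in mean heart rate and in beat
amplitude, giving downstream classifiers a learnable but nontrivial signal.

Default per-class heart rates (77.1 ± 9.2 vs 73.6 ± 8.3 bpm) follow typical
cohort statistics for hypertensive vs normotensive adults; they are simulation
parameters only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from bcgkit.recording import SignalRecording


def _class_dict(normo: float, hyper: float) -> dict:
    return {"normotensive": normo, "hypertensive": hyper}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic BCG process.

    Per-class fields are dicts keyed by ``"normotensive"`` / ``"hypertensive"``.
    Heart-rate means/SDs describe between-recording variation; within one
    recording, beat-to-beat intervals jitter by ``beat_jitter_fraction`` of the
    mean period. Artifacts arrive as a Poisson process in time with signed
    amplitude ``±artifact_amplitude``.
    """

    sampling_rate_hz: float = 100.0
    duration_s: float = 300.0
    n_channels: int = 2
    heart_rate_bpm_mean: dict = field(default_factory=lambda: _class_dict(73.6, 77.1))
    heart_rate_bpm_sd: dict = field(default_factory=lambda: _class_dict(8.3, 9.2))
    beat_jitter_fraction: float = 0.05
    beat_amplitude: dict = field(default_factory=lambda: _class_dict(1.0, 1.4))
    #: centre frequency (Hz) and Gaussian width (s) of the beat template
    beat_freq_hz: float = 7.0
    beat_width_s: float = 0.04
    resp_rate_hz: float = 0.25
    resp_amplitude: float = 0.3
    drift_amplitude: float = 0.2
    noise_sd: float = 0.1
    artifact_rate_per_min: float = 2.0
    artifact_amplitude: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling_rate_hz and duration_s must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not 0.0 <= self.beat_jitter_fraction <= 0.2:
            raise ValueError("beat_jitter_fraction must lie in [0, 0.2]")
        if not 0.1 <= self.resp_rate_hz <= 0.5:
            raise ValueError("resp_rate_hz must lie in [0.1, 0.5]")
        for name in ("resp_amplitude", "drift_amplitude", "noise_sd", "artifact_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.artifact_amplitude <= 0:
            raise ValueError("artifact_amplitude must be positive")
        for cls in ("normotensive", "hypertensive"):
            hr = self.heart_rate_bpm_mean[cls]
            if not 30.0 <= hr <= 200.0:
                raise ValueError(f"heart-rate mean for {cls} must lie in [30, 200] bpm")
            if self.heart_rate_bpm_sd[cls] < 0:
                raise ValueError("heart-rate SD must be nonnegative")
            if self.beat_amplitude[cls] <= 0:
                raise ValueError("beat_amplitude must be positive")

    @property
    def n_samples(self) -> int:
        return int(math.floor(self.duration_s * self.sampling_rate_hz))

    def without_class_separation(self) -> "SyntheticConfig":
        """Copy in which both classes share the normotensive parameters.

        Used for null experiments: labels carry no signal, so any classifier
        should perform at chance.
        """
        return replace(
            self,
            heart_rate_bpm_mean=_class_dict(
                self.heart_rate_bpm_mean["normotensive"],
                self.heart_rate_bpm_mean["normotensive"],
            ),
            heart_rate_bpm_sd=_class_dict(
                self.heart_rate_bpm_sd["normotensive"],
                self.heart_rate_bpm_sd["normotensive"],
            ),
            beat_amplitude=_class_dict(
                self.beat_amplitude["normotensive"],
                self.beat_amplitude["normotensive"],
            ),
        )


def generate_recording(
    cfg: SyntheticConfig,
    label: str,
    subject_id: str = "subj000",
    seed: int | np.random.SeedSequence | None = None,
) -> SignalRecording:
    """Simulate one labeled multi-channel BCG recording.

    The signal is the sum of beat templates placed at quasi-periodic times,
    a respiratory sinusoid, a very-low-frequency drift sinusoid, white noise
    and Poisson-placed spikes. Channels share the physiological components
    with channel-specific gains and independent noise, mimicking two sensors
    under one mattress. Deterministic given ``(cfg, label, seed)``; ``seed``
    defaults to ``cfg.seed``. Ground-truth beat times and the drawn heart
    rate are kept in the recording metadata.
    """
    if label not in ("hypertensive", "normotensive"):
        raise ValueError(f"label must be 'hypertensive' or 'normotensive', got {label!r}")
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)

    fs = cfg.sampling_rate_hz
    n = cfg.n_samples
    t = np.arange(n) / fs

    # recording-level heart rate from the class distribution
    hr_bpm = float(
        np.clip(
            rng.normal(cfg.heart_rate_bpm_mean[label], cfg.heart_rate_bpm_sd[label]),
            30.0,
            200.0,
        )
    )
    period = 60.0 / hr_bpm

    # quasi-periodic beat times: first beat at half a period, then jittered gaps
    beat_times = []
    t_beat = period / 2.0
    while t_beat < cfg.duration_s:
        beat_times.append(t_beat)
        gap = period * (1.0 + cfg.beat_jitter_fraction * rng.standard_normal())
        t_beat += max(gap, 0.2 * period)
    beat_times = np.asarray(beat_times)

    amp = cfg.beat_amplitude[label]
    beat_train = np.zeros(n)
    half_support = 4.0 * cfg.beat_width_s
    for tb in beat_times:
        i0 = max(0, int((tb - half_support) * fs))
        i1 = min(n, int((tb + half_support) * fs) + 1)
        tt = t[i0:i1] - tb
        beat_train[i0:i1] += (
            amp
            * np.cos(2.0 * math.pi * cfg.beat_freq_hz * tt)
            * np.exp(-0.5 * (tt / cfg.beat_width_s) ** 2)
        )

    resp_phase = rng.uniform(0.0, 2.0 * math.pi)
    resp = cfg.resp_amplitude * np.sin(2.0 * math.pi * cfg.resp_rate_hz * t + resp_phase)

    drift_freq = rng.uniform(0.01, 0.05)
    drift_phase = rng.uniform(0.0, 2.0 * math.pi)
    drift = cfg.drift_amplitude * np.sin(2.0 * math.pi * drift_freq * t + drift_phase)

    physio = beat_train + resp + drift

    channels = np.empty((n, cfg.n_channels))
    gains = rng.uniform(0.8, 1.0, size=cfg.n_channels)
    for c in range(cfg.n_channels):
        noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
        channels[:, c] = gains[c] * physio + noise

    # sparse artifact spikes, shared across channels (whole-body movement)
    n_artifacts = rng.poisson(cfg.artifact_rate_per_min * cfg.duration_s / 60.0)
    if n_artifacts > 0:
        idx = rng.integers(0, n, size=n_artifacts)
        signs = rng.choice([-1.0, 1.0], size=n_artifacts)
        for i, s in zip(idx, signs):
            channels[i, :] += s * cfg.artifact_amplitude

    return SignalRecording(
        subject_id=subject_id,
        label=label,
        sampling_rate_hz=fs,
        time_s=t,
        channels=channels,
        channel_names=[f"sensor{c + 1}" for c in range(cfg.n_channels)],
        beat_times_s=beat_times,
        meta={"heart_rate_bpm": hr_bpm, "channel_gains": gains.tolist()},
    )


def generate_dataset(cfg: SyntheticConfig, n_per_class: int) -> list[SignalRecording]:
    """Generate a balanced labeled dataset of ``2 * n_per_class`` recordings.

    Per-recording seeds are spawned deterministically from ``cfg.seed`` so the
    whole dataset is reproducible from a single integer while recordings stay
    statistically independent.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    children = np.random.SeedSequence(cfg.seed).spawn(2 * n_per_class)
    recordings = []
    i = 0
    for label in ("normotensive", "hypertensive"):
        for k in range(n_per_class):
            recordings.append(
                generate_recording(cfg, label, subject_id=f"subj{i:03d}", seed=children[i])
            )
            i += 1
    return recordings
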