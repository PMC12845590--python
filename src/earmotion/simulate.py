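"""Synthetic multi-subject ear-EEG cohorts with known, recoverable effects.

Each session mirrors the recording protocol the analysis expects: a
2-min eyes-closed (EC) and a 2-min eyes-open (EO) baseline followed by
~2-min video stimuli drawn from the five Circumplex quadrants, presented
in a per-subject randomized order, with one SAM valence/arousal rating
per video.

The signal model is a sum of band-limited stochastic oscillations (one
per canonical band, each filtered Gaussian noise with a configurable
band power), a 1/f pink background, and a broadband "complexity"
component whose mixing weight is modulated per class without changing
total power.  Class effects are per-band power multipliers applied
during the video; EC boosts alpha power by a configurable factor
relative to EO and the videos.  Amplitude jumps, EMG-like 30–45 Hz
bursts and low-frequency drift epochs are injected at configurable
per-minute rates and logged so tests can assert their detection.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

CLASSES = ("LV-HA", "HV-HA", "LV-LA", "HV-LA", "Neutral")

# SAM prototypes per Circumplex quadrant, (valence, arousal) before noise.
SAM_PROTOTYPES = {
    "LV-HA": (2, 8),
    "HV-HA": (8, 8),
    "LV-LA": (2, 2),
    "HV-LA": (8, 2),
    "Neutral": (5, 5),
}

CANONICAL_BANDS = {"δ": (1.0, 4.0), "θ": (4.0, 8.0), "α": (8.0, 12.0), "β": (12.0, 30.0), "γ": (30.0, 42.0)}

# Sub-band synthesis layout: each canonical band is realized as the sum of
# its sub-band components so that within-band spectral redistribution
# (individual peak-frequency drift) can be emulated by jittering sub-band
# powers independently while the parent band power stays coherent.
SUB_BANDS: dict[str, list[tuple[float, float]]] = {
    "δ": [(1.0, 4.0)],
    "θ": [(4.0, 8.0)],
    "α": [(8.0, 10.0), (10.0, 12.0)],
    "β": [(12.0, 18.0), (18.0, 24.0), (24.0, 30.0)],
    "γ": [(30.0, 38.0), (38.0, 42.0)],
}

# Baseline band powers in µV² — ear-EEG-ish amplitudes that keep the
# artifact-free signal comfortably inside the 100 µV rejection bound.
DEFAULT_BAND_POWER = {"δ": 25.0, "θ": 16.0, "α": 20.0, "β": 9.0, "γ": 4.0}


@dataclass
class ClassEffect:
    """Per-class modulation: band-power multipliers and complexity factor."""

    band_multipliers: dict[str, float] = field(default_factory=dict)
    complexity: float = 1.0

    def multiplier(self, band: str) -> float:
        return self.band_multipliers.get(band, 1.0)


def default_effect_profile() -> dict[str, ClassEffect]:
    """High-arousal classes raise β/γ power and signal complexity;
    low-arousal classes raise α slightly and damp the fast bands."""
    return {
        "LV-HA": ClassEffect({"β": 1.4, "γ": 1.4}, complexity=1.2),
        "HV-HA": ClassEffect({"β": 1.4, "γ": 1.4}, complexity=1.2),
        "LV-LA": ClassEffect({"α": 1.2, "β": 0.9, "γ": 0.9}, complexity=0.9),
        "HV-LA": ClassEffect({"α": 1.2, "β": 0.9, "γ": 0.9}, complexity=0.9),
        "Neutral": ClassEffect(),
    }


@dataclass
class CohortSpec:
    n_subjects: int = 16
    fs: float = 250.0
    classes: tuple[str, ...] = CLASSES
    videos_per_class: int = 5
    video_duration_s: float = 120.0
    baseline_duration_s: float = 120.0
    effect_profile: dict[str, ClassEffect] = field(default_factory=default_effect_profile)
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: {"jump": 0.5, "emg": 0.3, "drift": 0.3}
    )
    rating_noise_sd: float = 1.0
    ec_alpha_factor: float = 2.0
    band_power_uv2: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_POWER))
    pink_fraction: float = 0.05
    complexity_fraction: float = 0.08
    # Between-block spontaneous band-power variability: each block draws an
    # independent log-normal factor per canonical band (SD on the natural-log
    # scale).  Real EEG band power fluctuates strongly between 2-min stimuli,
    # most of all in the slow and alpha bands (vigilance/attention lability),
    # while artifact-free fast-band power is comparatively stable; without
    # this the synthetic class effects separate unrealistically.
    power_jitter_sd: dict[str, float] = field(
        default_factory=lambda: {"δ": 0.4, "θ": 0.35, "α": 0.5, "β": 0.1, "γ": 0.1}
    )
    # Within-band spectral redistribution between blocks (peak-frequency
    # drift): independent log-normal jitter per sub-band on top of the
    # coherent canonical-band factor.
    subband_jitter_sd: float = 0.25
    channels: tuple[str, ...] = ("R4a", "AF7", "AF8", "L4a")
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.video_duration_s < 15:
            raise ValueError("video_duration_s must be >= 15 s (one feature window)")
        if self.videos_per_class < 1:
            raise ValueError("videos_per_class must be >= 1")
        for cls in self.effect_profile:
            if cls not in self.classes:
                raise ValueError(f"unknown class label in effect profile: {cls!r}")
        for cls, eff in self.effect_profile.items():
            if any(m <= 0 for m in eff.band_multipliers.values()) or eff.complexity <= 0:
                raise ValueError(f"multipliers must be > 0 (class {cls!r})")
        if any(r < 0 for r in self.artifact_rates.values()):
            raise ValueError("artifact rates must be >= 0")


@dataclass
class RawSession:
    subject_id: str
    fs: float
    channel_labels: tuple[str, ...]
    signal: np.ndarray                    # (n_channels, n_samples), µV
    events: pd.DataFrame                  # video_id, class_label, onset, duration
    ratings: pd.DataFrame                 # video_id, valence, arousal
    baselines: dict[str, tuple[int, int]]  # "EC"/"EO" -> (start, stop) samples
    ground_truth: dict
    artifact_log: list[dict] = field(default_factory=list)


def _subseed(seed: int, subject_id: str) -> int:
    """64-bit sub-seed from (cohort seed, subject id), stable across runs."""
    h = hashlib.sha256(f"{seed}:{subject_id}".encode()).digest()
    return int.from_bytes(h[:8], "little")


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise via FFT spectral shaping.

    Sharp raised-cosine band edges (0.5 Hz transition) keep neighbouring
    synthetic bands from leaking power into each other, so per-band
    power modulations stay recoverable band by band.
    """
    lo, hi = band
    hi = min(hi, 0.99 * fs / 2)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    roll = 0.5
    shape = np.zeros_like(freqs)
    inside = (freqs >= lo) & (freqs <= hi)
    shape[inside] = 1.0
    lo_edge = (freqs >= lo - roll) & (freqs < lo)
    shape[lo_edge] = 0.5 * (1 + np.cos(np.pi * (lo - freqs[lo_edge]) / roll))
    hi_edge = (freqs > hi) & (freqs <= hi + roll)
    shape[hi_edge] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_edge] - hi) / roll))
    spectrum = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    x = np.fft.irfft(spectrum * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f noise restricted to the 1–45 Hz analysis band."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spectrum = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)).astype(complex)
    shaping = np.zeros_like(freqs)
    mask = (freqs >= 1.0) & (freqs <= 45.0)
    shaping[mask] = 1.0 / np.sqrt(freqs[mask])
    x = np.fft.irfft(spectrum * shaping, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _synthesize_block(
    rng: np.random.Generator,
    n: int,
    spec: CohortSpec,
    band_multipliers: dict[str, float],
    complexity: float = 1.0,
) -> np.ndarray:
    """One contiguous signal block (baseline or video) in µV."""
    jitter = spec.power_jitter_sd
    if not isinstance(jitter, dict):
        jitter = {b: float(jitter) for b in CANONICAL_BANDS}
    powers = {
        b: spec.band_power_uv2[b]
        * band_multipliers.get(b, 1.0)
        * float(np.exp(rng.normal(0.0, jitter.get(b, 0.0))))
        for b in CANONICAL_BANDS
    }
    total = sum(powers.values())
    w_pink = spec.pink_fraction
    w_white = min(spec.complexity_fraction * complexity, 0.5)
    w_osc = max(1.0 - w_pink - w_white, 0.0)
    x = np.zeros(n)
    for b, (b_lo, b_hi) in CANONICAL_BANDS.items():
        subs = SUB_BANDS[b]
        # split the band power over sub-bands by bandwidth, each with its
        # own redistribution factor, renormalized so the parent-band power
        # keeps the coherent canonical factor
        shares = np.array([(hi - lo) / (b_hi - b_lo) for lo, hi in subs])
        drift = np.exp(rng.normal(0.0, spec.subband_jitter_sd, size=len(subs)))
        weights = shares * drift
        weights *= 1.0 / weights.sum() if weights.sum() > 0 else 1.0
        for (lo, hi), w in zip(subs, weights):
            x += _band_noise(rng, n, spec.fs, (lo, hi)) * np.sqrt(w_osc * powers[b] * w)
    x += _pink_noise(rng, n, spec.fs) * np.sqrt(w_pink * total)
    x += _band_noise(rng, n, spec.fs, (1.0, 45.0)) * np.sqrt(w_white * total)
    return x


def inject_artifacts(
    signal: np.ndarray, fs: float, rates: dict[str, float], seed: int
) -> tuple[np.ndarray, list[dict]]:
    """Add amplitude jumps, EMG bursts and low-frequency drift epochs.

    ``rates`` are expected event counts per minute for keys ``jump``,
    ``emg`` and ``drift``; each realized event is logged with its type,
    onset sample, duration and amplitude.  All-zero rates return the
    signal unchanged with an empty log.
    """
    if any(r < 0 for r in rates.values()):
        raise ValueError("artifact rates must be >= 0")
    x = np.asarray(signal, dtype=float).copy()
    rng = np.random.default_rng(seed)
    minutes = x.size / fs / 60.0
    log: list[dict] = []

    def onset_for(duration_samples: int) -> int:
        return int(rng.integers(0, max(x.size - duration_samples, 1)))

    for _ in range(rng.poisson(rates.get("jump", 0.0) * minutes)):
        dur = int(rng.uniform(0.2, 0.8) * fs)
        onset = onset_for(dur)
        amp = rng.uniform(120.0, 250.0) * rng.choice((-1.0, 1.0))
        x[onset : onset + dur] += amp
        log.append({"type": "jump", "onset": onset, "duration": dur, "amplitude": float(amp)})

    for _ in range(rng.poisson(rates.get("emg", 0.0) * minutes)):
        dur = int(rng.uniform(1.0, 5.0) * fs)
        onset = onset_for(dur)
        amp = rng.uniform(20.0, 35.0)
        burst = _band_noise(rng, dur, fs, (30.0, min(45.0, 0.99 * fs / 2))) * amp
        taper = sps.windows.tukey(dur, 0.2)
        x[onset : onset + dur] += burst * taper
        log.append({"type": "emg", "onset": onset, "duration": dur, "amplitude": float(amp)})

    for _ in range(rng.poisson(rates.get("drift", 0.0) * minutes)):
        dur = int(rng.uniform(5.0, 15.0) * fs)
        onset = onset_for(dur)
        amp = rng.uniform(40.0, 90.0)
        f_drift = rng.uniform(0.5, 2.0)
        t = np.arange(dur) / fs
        wave = amp * np.sin(2 * np.pi * f_drift * t + rng.uniform(0, 2 * np.pi))
        taper = sps.windows.tukey(dur, 0.3)
        x[onset : onset + dur] += wave * taper
        log.append({"type": "drift", "onset": onset, "duration": dur, "amplitude": float(amp)})

    log.sort(key=lambda e: e["onset"])
    return x, log


def generate_session(spec: CohortSpec, subject_id: str) -> RawSession:
    """One subject's full recording, reproducible from (spec.seed, subject_id)."""
    spec.validate()
    master = np.random.default_rng(_subseed(spec.seed, subject_id))
    n_video = int(round(spec.video_duration_s * spec.fs))
    n_base = int(round(spec.baseline_duration_s * spec.fs))

    # randomized per-subject video order
    video_plan = [
        (f"{cls}_{k:02d}", cls) for cls in spec.classes for k in range(spec.videos_per_class)
    ]
    order = master.permutation(len(video_plan))
    video_plan = [video_plan[i] for i in order]

    # per-video ratings from class prototypes + noise
    ratings_rows = []
    for video_id, cls in video_plan:
        v_proto, a_proto = SAM_PROTOTYPES.get(cls, (5, 5))
        v = int(np.clip(np.round(v_proto + master.normal(0, spec.rating_noise_sd)), 1, 9))
        a = int(np.clip(np.round(a_proto + master.normal(0, spec.rating_noise_sd)), 1, 9))
        ratings_rows.append({"video_id": video_id, "valence": v, "arousal": a})

    n_total = 2 * n_base + len(video_plan) * n_video
    chan_signals = []
    artifact_log_all: list[dict] = []
    for ch_idx, _ch in enumerate(spec.channels):
        rng = np.random.default_rng(
            _subseed(spec.seed, f"{subject_id}/ch{ch_idx}")
        )
        blocks = [
            _synthesize_block(rng, n_base, spec, {"α": spec.ec_alpha_factor}),  # EC
            _synthesize_block(rng, n_base, spec, {}),                            # EO
        ]
        for _video_id, cls in video_plan:
            eff = spec.effect_profile.get(cls, ClassEffect())
            blocks.append(
                _synthesize_block(rng, n_video, spec, eff.band_multipliers, eff.complexity)
            )
        x = np.concatenate(blocks)
        x, log = inject_artifacts(
            x, spec.fs, spec.artifact_rates, _subseed(spec.seed, f"{subject_id}/art{ch_idx}")
        )
        for entry in log:
            entry["channel"] = spec.channels[ch_idx]
        artifact_log_all.extend(log)
        chan_signals.append(x)

    events_rows = []
    cursor = 2 * n_base
    for video_id, cls in video_plan:
        events_rows.append(
            {"video_id": video_id, "class_label": cls, "onset": cursor, "duration": n_video}
        )
        cursor += n_video
    assert cursor == n_total

    return RawSession(
        subject_id=subject_id,
        fs=spec.fs,
        channel_labels=spec.channels,
        signal=np.vstack(chan_signals),
        events=pd.DataFrame(events_rows),
        ratings=pd.DataFrame(ratings_rows),
        baselines={"EC": (0, n_base), "EO": (n_base, 2 * n_base)},
        ground_truth={
            "effect_profile": {
                cls: {"band_multipliers": dict(e.band_multipliers), "complexity": e.complexity}
                for cls, e in spec.effect_profile.items()
            },
            "seed": spec.seed,
        },
        artifact_log=artifact_log_all,
    )


def generate_cohort(spec: CohortSpec) -> list[RawSession]:
    """One session per subject (ids s01..sNN), deterministically sub-seeded."""
    spec.validate()
    return [
        generate_session(spec, f"s{k + 1:02d}") for k in range(spec.n_subjects)
    ]


def quiet_spec(**overrides) -> CohortSpec:
    """Convenience: a cohort spec with no artifacts and no class effects."""
    base = CohortSpec(
        effect_profile={cls: ClassEffect() for cls in CLASSES},
        artifact_rates={"jump": 0.0, "emg": 0.0, "drift": 0.0},
    )
    return replace(base, **overrides)
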