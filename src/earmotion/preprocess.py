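"""Preprocessing and quality control for single-channel ear-EEG.

Pipeline order: zero-phase Butterworth band-pass (1–45 Hz) plus 50 Hz
notch, non-overlapping 1-s segmentation with a 100 µV absolute-amplitude
rejection rule, normalized 0–100 QC scoring per video with an all-metrics
≥ 60 gate, SAM rating binning into low/mid/high labels, and class
balancing (V videos per label, E_min windows per video).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import features as feat


@dataclass
class FilterSpec:
    band: tuple[float, float] = (1.0, 45.0)
    butter_order: int = 4
    notch_freq: float = 50.0
    notch_q: float = 30.0
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        lo, hi = self.band
        if not (0 < lo < hi < fs / 2):
            raise ValueError(f"band {self.band} invalid for fs={fs}")
        if not (0 < self.notch_freq < fs / 2):
            raise ValueError(f"notch {self.notch_freq} above Nyquist for fs={fs}")


def bandpass_notch(x: np.ndarray, fs: float, filt: FilterSpec | None = None) -> np.ndarray:
    """Band-pass + notch filter one channel, zero-phase by default.

    Zero-phase means forward–backward application of the order-4
    Butterworth design (effective magnitude order 8) and of a
    second-order IIR notch (Q = 30).  Raises if the signal is too short
    for stable filtering instead of silently truncating.
    """
    filt = filt or FilterSpec()
    x = np.asarray(x, dtype=float)
    filt.validate(fs)
    sos = sps.butter(filt.butter_order, filt.band, btype="bandpass", fs=fs, output="sos")
    b_notch, a_notch = sps.iirnotch(filt.notch_freq, filt.notch_q, fs=fs)
    if filt.zero_phase:
        padlen = 3 * (2 * sos.shape[0] + 1)
        pad_notch = 3 * max(len(b_notch), len(a_notch))
        if x.size <= max(padlen, pad_notch):
            raise ValueError(
                f"signal of {x.size} samples too short for zero-phase filtering "
                f"(needs > {max(padlen, pad_notch)})"
            )
        y = sps.sosfiltfilt(sos, x)
        y = sps.filtfilt(b_notch, a_notch, y)
    else:
        y = sps.sosfilt(sos, x)
        y = sps.lfilter(b_notch, a_notch, y)
    return y


@dataclass
class SegmentedRecording:
    segments: np.ndarray          # (n_retained, fs) retained 1-s windows
    segment_flags: list[tuple[bool, str]]
    retention_index: float
    clean_signal: np.ndarray
    fs: float


def segment_and_reject(
    signal: np.ndarray, fs: float, threshold_uv: float = 100.0
) -> SegmentedRecording:
    """Cut into non-overlapping 1-s segments and drop amplitude violations.

    A segment is rejected iff max |amplitude| > threshold on any channel;
    a trailing partial second is excluded from segmentation.  Retained
    segments are concatenated in temporal order into ``clean_signal``.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    n_fs = int(round(fs))
    if x.shape[1] < n_fs:
        raise ValueError("signal shorter than one 1-s segment")
    n_seg = x.shape[1] // n_fs
    flags: list[tuple[bool, str]] = []
    kept = []
    for i in range(n_seg):
        seg = x[:, i * n_fs : (i + 1) * n_fs]
        if np.max(np.abs(seg)) > threshold_uv:
            flags.append((False, "amplitude"))
        else:
            flags.append((True, ""))
            kept.append(seg)
    retained = np.concatenate(kept, axis=1) if kept else np.empty((x.shape[0], 0))
    if np.asarray(signal).ndim == 1:
        retained_1d = retained[0]
        segments = retained_1d.reshape(-1, n_fs) if retained_1d.size else np.empty((0, n_fs))
        clean = retained_1d
    else:
        segments = retained.T.reshape(-1, x.shape[0], n_fs) if retained.size else np.empty((0, x.shape[0], n_fs))
        clean = retained
    return SegmentedRecording(
        segments=segments,
        segment_flags=flags,
        retention_index=len(kept) / n_seg,
        clean_signal=clean,
        fs=fs,
    )


@dataclass
class QCConstants:
    """Exposed constants of the six QC metric formulas (all monotone 0–100)."""

    jump_diff_uv: float = 25.0
    jump_count_max_per_min: float = 30.0
    amp_threshold_uv: float = 100.0
    amp_frac_max: float = 0.05
    p2p_threshold_uv: float = 150.0
    p2p_frac_max: float = 0.05
    hf_band: tuple[float, float] = (30.0, 45.0)
    hf_pivot: float = 0.5
    hf_scale: float = 0.3
    lf_band: tuple[float, float] = (1.0, 4.0)
    lf_pivot: float = 0.6
    lf_scale: float = 0.3
    full_band: tuple[float, float] = (1.0, 45.0)
    gate: float = 60.0


QC_METRICS = ("jump_rate", "amplitude", "peak_to_peak", "hf_contamination", "lf_contamination", "retention")
EVENT_RATE_METRICS = ("jump_rate", "amplitude", "peak_to_peak")


@dataclass
class QCReport:
    video_id: str
    scores: dict[str, float]
    passed: bool
    reasons: list[str]
    retention_index: float


def _band_fraction(x: np.ndarray, fs: float, band: tuple[float, float], full: tuple[float, float]) -> float:
    freqs, psd = feat.welch_psd(x, fs)

    def integrate(lo, hi):
        mask = (freqs >= lo) & (freqs <= hi)
        return float(np.trapezoid(psd[mask], freqs[mask])) if mask.sum() >= 2 else 0.0

    total = integrate(*full)
    if total <= 0:
        return 0.0
    return integrate(*band) / total


def qc_score(
    video_signal: np.ndarray,
    fs: float,
    seg: SegmentedRecording,
    video_id: str = "",
    constants: QCConstants | None = None,
) -> QCReport:
    """Six normalized 0–100 quality scores for one (filtered) video.

    Event-rate scores look at abrupt sample-to-sample jumps, excessive
    amplitude and 1-s peak-to-peak range; spectral scores at HF (EMG
    surrogate) and LF (motion/drift) power fractions of the 1–45 Hz
    total; retention is the 1-s segment-retention index.  A video passes
    iff every score reaches the gate (60 by default).
    """
    c = constants or QCConstants()
    x = np.asarray(video_signal, dtype=float).ravel()
    minutes = x.size / fs / 60.0
    n_fs = int(round(fs))
    n_seg = max(x.size // n_fs, 1)

    jumps = int(np.count_nonzero(np.abs(np.diff(x)) > c.jump_diff_uv))
    jump_score = 100.0 * max(0.0, 1.0 - (jumps / max(minutes, 1e-9)) / c.jump_count_max_per_min)

    amp_frac = float(np.mean(np.abs(x) > c.amp_threshold_uv))
    amp_score = 100.0 * max(0.0, 1.0 - amp_frac / c.amp_frac_max)

    p2p = np.array(
        [np.ptp(x[i * n_fs : (i + 1) * n_fs]) for i in range(x.size // n_fs)] or [0.0]
    )
    p2p_frac = float(np.mean(p2p > c.p2p_threshold_uv))
    p2p_score = 100.0 * max(0.0, 1.0 - p2p_frac / c.p2p_frac_max)

    if x.size >= 2 and np.ptp(x) > 0:
        hf_frac = _band_fraction(x, fs, c.hf_band, c.full_band)
        lf_frac = _band_fraction(x, fs, c.lf_band, c.full_band)
    else:  # constant input: defined scores, not NaN
        hf_frac = lf_frac = 0.0
    hf_score = 100.0 * max(0.0, 1.0 - max(0.0, hf_frac - c.hf_pivot) / c.hf_scale)
    lf_score = 100.0 * max(0.0, 1.0 - max(0.0, lf_frac - c.lf_pivot) / c.lf_scale)

    retention_score = 100.0 * seg.retention_index

    scores = {
        "jump_rate": jump_score,
        "amplitude": amp_score,
        "peak_to_peak": p2p_score,
        "hf_contamination": hf_score,
        "lf_contamination": lf_score,
        "retention": retention_score,
    }
    reasons = [k for k, v in scores.items() if v < c.gate]
    return QCReport(
        video_id=video_id,
        scores=scores,
        passed=not reasons,
        reasons=reasons,
        retention_index=seg.retention_index,
    )


def bin_sam(rating: int) -> int:
    """SAM 1–9 rating to intensity label: 1–3 → 0, 4–6 → 1, 7–9 → 2."""
    r = int(rating)
    if r != rating or not 1 <= r <= 9:
        raise ValueError(f"SAM rating must be an integer in 1..9, got {rating!r}")
    return (r - 1) // 3


@dataclass
class LabeledDataset:
    """Balanced video/window selection for one affective dimension."""

    dimension: str
    selection: pd.DataFrame       # rows: subject, video_id, label, qc_mean, n_windows
    v_per_label: int              # V
    windows_per_video: int        # E_min
    excluded_subjects: list[str] = field(default_factory=list)
    required_labels: tuple[int, ...] = (0, 1, 2)


def balance_dataset(
    video_table: pd.DataFrame,
    dimension: str,
    required_labels: tuple[int, ...] = (0, 1, 2),
) -> LabeledDataset:
    """Balanced selection: V videos per label per subject, E_min windows each.

    ``video_table`` needs one row per QC-passing video with columns
    ``subject``, ``video_id``, ``label`` (the binned rating for this
    dimension), ``qc_mean`` and ``n_windows``.  V is the minimum video
    count over all (subject, required label) cells; when more than V
    videos qualify the V with the highest mean QC score are kept (ties
    by video_id order).  E_min is the minimum window count over retained
    videos; downstream consumers use the chronologically first E_min
    windows.  Subjects missing a required label entirely are excluded.
    """
    df = video_table.copy()
    excluded = []
    for subject, grp in df.groupby("subject"):
        present = set(grp["label"].unique())
        if not set(required_labels) <= present:
            excluded.append(str(subject))
    df = df[~df["subject"].isin(excluded) & df["label"].isin(required_labels)]
    if df.empty:
        raise ValueError(f"no subject has videos for all required labels {required_labels}")
    v = int(df.groupby(["subject", "label"]).size().min())
    picks = []
    for (_, _), grp in df.groupby(["subject", "label"]):
        grp = grp.sort_values(["qc_mean", "video_id"], ascending=[False, True], kind="stable")
        picks.append(grp.head(v))
    selection = pd.concat(picks, ignore_index=True)
    e_min = int(selection["n_windows"].min())
    return LabeledDataset(
        dimension=dimension,
        selection=selection,
        v_per_label=v,
        windows_per_video=e_min,
        excluded_subjects=sorted(excluded),
        required_labels=tuple(required_labels),
    )


EXCLUSION_CATEGORIES = ("event_rate", "hf", "lf", "combined", "retention")


def exclusion_category(reasons: list[str]) -> str | None:
    """Mutually exclusive reason bucket for one failed video.

    Event-rate-only failures map to ``event_rate``; spectral-only to
    ``hf`` (dominant) or ``lf``; joint event-rate + spectral failures to
    ``combined``; a pure retention failure to ``retention``.
    """
    if not reasons:
        return None
    event = any(r in EVENT_RATE_METRICS for r in reasons)
    hf = "hf_contamination" in reasons
    lf = "lf_contamination" in reasons
    if event and (hf or lf):
        return "combined"
    if event:
        return "event_rate"
    if hf:
        return "hf"
    if lf:
        return "lf"
    return "retention"


def retention_summary(reports: list[QCReport]) -> dict:
    """Cohort retention mean/SD and mutually exclusive exclusion counts."""
    if not reports:
        raise ValueError("no QC reports")
    retention = np.array([r.retention_index for r in reports])
    counts = {c: 0 for c in EXCLUSION_CATEGORIES}
    for r in reports:
        if not r.passed:
            counts[exclusion_category(r.reasons)] += 1
    return {
        "mean_retention": float(retention.mean()),
        "sd_retention": float(retention.std(ddof=1)) if retention.size > 1 else 0.0,
        "n_videos": len(reports),
        "n_excluded": int(sum(counts.values())),
        "excluded_by_reason": counts,
    }
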