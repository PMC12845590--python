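"""39-feature extraction from single-channel EEG windows.

Features are computed on 15-s sliding windows with a 2-s shift and fall
into three groups:

* 27 spectral features — absolute (ASP) and relative (RSP) spectral
  power in 12 canonical bands and sub-bands, two cross-band ratios in
  dB, and total power;
* 9 non-linear / time-domain features — the three Hjorth parameters,
  zero-crossing rate, Petrosian and Higuchi fractal dimensions,
  Lempel–Ziv complexity, permutation entropy and sample entropy;
* 3 statistical descriptors — coefficient of variation, skewness and
  excess kurtosis.

Power spectra come from Welch's method with a Hamming taper and segment
length ``nperseg = min(N, max(128, fs))``.  Every ratio denominator is
floored so that degenerate (near-constant) windows yield finite, flagged
values rather than NaN/Inf.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from ._kernels import lz76_phrases, sampen_counts

# Band layout: five canonical bands partitioned further into sub-bands.
BANDS: dict[str, tuple[float, float]] = {
    "δ": (1.0, 4.0),
    "θ": (4.0, 8.0),
    "α": (8.0, 12.0),
    "α1": (8.0, 10.0),
    "α2": (10.0, 12.0),
    "β": (12.0, 30.0),
    "β1": (12.0, 18.0),
    "β2": (18.0, 24.0),
    "β3": (24.0, 30.0),
    "γ": (30.0, 42.0),
    "γ1": (30.0, 38.0),
    "γ2": (38.0, 42.0),
}
CANONICAL_BANDS: tuple[str, ...] = ("δ", "θ", "α", "β", "γ")

SPECTRAL_FEATURES: tuple[str, ...] = tuple(
    [f"{b}a" for b in BANDS] + [f"{b}r" for b in BANDS] + ["ABR", "AGR", "TotalPower"]
)
NONLINEAR_FEATURES: tuple[str, ...] = (
    "Hjorth_Activity",
    "Hjorth_Mobility",
    "Hjorth_Complexity",
    "TD_ZCR",
    "TD_PFD",
    "TD_HFD",
    "TD_LZC",
    "TD_PermEn",
    "TD_SampEn",
)
STATISTICAL_FEATURES: tuple[str, ...] = ("TD_CV", "TD_Skewness", "TD_Kurtosis")
FEATURE_NAMES: tuple[str, ...] = SPECTRAL_FEATURES + NONLINEAR_FEATURES + STATISTICAL_FEATURES

METADATA_COLUMNS = ("subject", "video_id", "window_idx", "start_s", "degenerate")


@dataclass
class FeatureParams:
    """Tunable constants of the feature extractor.

    eps: power-denominator floor (µV²); eps_cv: CV mean-denominator
    floor (µV); ratio_scale: the 0.6 regularization constant of the
    ABR/AGR dB ratios; abr_uses_beta: ABR computed as β/γ per the
    printed formula (the name-faithful α/β variant when False);
    total_power_all_bands: sum TotalPower over all 12 listed bands
    (double-counting sub-bands) instead of the 5 canonical ones.
    """

    win_s: float = 15.0
    shift_s: float = 2.0
    eps: float = 1e-12
    eps_cv: float = 1e-6
    ratio_scale: float = 0.6
    abr_uses_beta: bool = True
    total_power_all_bands: bool = False
    welch_overlap_frac: float = 0.5
    hfd_kmax: int = 10
    permen_order: int = 3
    permen_delay: int = 1
    sampen_m: int = 2
    sampen_r: float = 0.2
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))


DEFAULT_PARAMS = FeatureParams()


def sliding_windows(
    clean_signal: np.ndarray, fs: float, win_s: float = 15.0, shift_s: float = 2.0
) -> list[np.ndarray]:
    """Cut a cleaned signal into ``win_s``-second windows every ``shift_s`` s.

    Returns an empty list (with a warning) when the signal is shorter
    than one window.
    """
    x = np.asarray(clean_signal, dtype=float)
    n_win_samp = int(round(win_s * fs))
    n_shift = int(round(shift_s * fs))
    if x.size < n_win_samp:
        warnings.warn(
            f"signal of {x.size / fs:.1f} s is shorter than the {win_s:.0f}-s window; "
            "no feature windows produced",
            stacklevel=2,
        )
        return []
    n_windows = (x.size - n_win_samp) // n_shift + 1
    return [x[i * n_shift : i * n_shift + n_win_samp] for i in range(n_windows)]


def welch_nperseg(n: int, fs: float) -> int:
    return int(min(n, max(128, int(round(fs)))))


def welch_psd(window: np.ndarray, fs: float, overlap_frac: float = 0.5):
    """Welch PSD (µV²/Hz) with a Hamming taper and the adaptive segment rule."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    nperseg = welch_nperseg(x.size, fs)
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap_frac),
        detrend="constant",
    )
    return freqs, psd


def band_powers(
    freqs: np.ndarray,
    psd: np.ndarray,
    params: FeatureParams = DEFAULT_PARAMS,
):
    """Integrate the PSD per band.

    Returns (asp, rsp, total_power, degenerate).  Integration is
    trapezoidal over the closed interval [f_lo, f_hi]; adjacent bands
    share the common edge frequency, which makes sub-band integrals add
    up exactly to their parent band.  RSP is ASP over total power
    (floored); a window whose total power underflows the floor is
    flagged degenerate and reports all-zero RSP.
    """
    asp: dict[str, float] = {}
    for name, (lo, hi) in params.bands.items():
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() >= 2:
            asp[name] = float(np.trapezoid(psd[mask], freqs[mask]))
        elif mask.sum() == 1:
            asp[name] = float(psd[mask][0] * (hi - lo))
        else:
            asp[name] = 0.0
    if params.total_power_all_bands:
        total = float(sum(asp.values()))
    else:
        total = float(sum(asp[b] for b in CANONICAL_BANDS))
    degenerate = total < params.eps
    denom = max(total, params.eps)
    rsp = {name: (0.0 if degenerate else asp[name] / denom) for name in asp}
    return asp, rsp, total, degenerate


def spectral_ratios(asp: dict[str, float], params: FeatureParams = DEFAULT_PARAMS):
    """ABR and AGR in dB: 20·log10(0.6·β/γ) and 20·log10(0.6·α/γ).

    Numerator and denominator are both floored at ``eps`` so the ratios
    stay finite for silent bands.
    """
    eps = params.eps
    gamma = max(asp["γ"], eps)
    abr_num = asp["β"] if params.abr_uses_beta else asp["α"]
    abr_den = gamma if params.abr_uses_beta else max(asp["β"], eps)
    abr = 20.0 * math.log10(params.ratio_scale * max(abr_num, eps) / abr_den)
    agr = 20.0 * math.log10(params.ratio_scale * max(asp["α"], eps) / gamma)
    return abr, agr


def hjorth(window: np.ndarray, eps: float = 1e-12):
    """Hjorth Activity (variance), Mobility and Complexity.

    A constant window reports (0, 0, 0) with the degenerate flag rather
    than NaN.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 3:
        raise ValueError("hjorth needs at least 3 samples")
    var_x = float(np.var(x))
    if var_x < eps:
        return 0.0, 0.0, 0.0, True
    dx = np.diff(x)
    var_dx = float(np.var(dx))
    mobility = math.sqrt(var_dx / var_x)
    if var_dx < eps:
        return var_x, mobility, 0.0, True
    ddx = np.diff(dx)
    mobility_dx = math.sqrt(float(np.var(ddx)) / var_dx)
    complexity = mobility_dx / max(mobility, eps)
    return var_x, mobility, complexity, False


def zero_crossing_rate(window: np.ndarray, fs: float) -> float:
    """Sign changes per second."""
    x = np.asarray(window, dtype=float)
    crossings = int(np.count_nonzero(np.diff(np.signbit(x))))
    return crossings / (x.size / fs)


def petrosian_fd(window: np.ndarray) -> float:
    x = np.asarray(window, dtype=float)
    n = x.size
    n_delta = int(np.count_nonzero(np.diff(np.signbit(np.diff(x)))))
    log_n = math.log10(n)
    return log_n / (log_n + math.log10(n / (n + 0.4 * n_delta)))


def higuchi_fd(window: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension: slope of log curve length vs log(1/k)."""
    x = np.asarray(window, dtype=float)
    n = x.size
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / ((idx.size - 1) * k)
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths) if lengths else 0.0
    valid = lk > 0
    if valid.sum() < 2:
        return 0.0
    ks = np.arange(1, kmax + 1)[valid]
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(lk[valid]), 1)
    return float(slope)


def lempel_ziv_complexity(window: np.ndarray) -> float:
    """Normalized LZ76 complexity of the median-binarized window: c·log2(n)/n."""
    x = np.asarray(window, dtype=float)
    n = x.size
    bits = (x > np.median(x)).astype(np.uint8)
    c = int(lz76_phrases(bits))
    return c * math.log2(n) / n


def permutation_entropy(window: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Ordinal-pattern Shannon entropy, normalized to [0, 1] by log2(order!).

    Computed on the z-scored window; ties broken by index order (stable
    argsort), so a constant window maps to a single pattern and zero
    entropy.
    """
    x = np.asarray(window, dtype=float)
    sd = x.std()
    if sd > 1e-12:
        x = (x - x.mean()) / sd
    n_patterns = x.size - (order - 1) * delay
    if n_patterns < 1:
        raise ValueError("window too short for the embedding")
    emb = np.lib.stride_tricks.sliding_window_view(x, (order - 1) * delay + 1)[:, ::delay]
    ranks = np.argsort(emb, axis=1, kind="stable")
    codes = ranks @ (order ** np.arange(order))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log2(p)).sum())
    return h / math.log2(math.factorial(order))


def sample_entropy(
    window: np.ndarray, m: int = 2, r: float = 0.2, cap: float | None = None
) -> float:
    """Sample entropy −ln(A/B) with Chebyshev distance on the z-scored window.

    ``r`` is in units of the (unit) standard deviation.  When no
    length-(m+1) match exists the value is capped at ln(B); a window
    with no matches at all (or a constant window) reports the configured
    cap, defaulting to ln of the number of template pairs.
    """
    x = np.asarray(window, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError("window too short for sample entropy")
    total_pairs = (n - m) * (n - m - 1) / 2
    if cap is None:
        cap = math.log(total_pairs)
    sd = x.std()
    if sd < 1e-12:
        return cap
    x = (x - x.mean()) / sd
    a, b = sampen_counts(np.ascontiguousarray(x), m, r)
    if b == 0:
        return cap
    if a == 0:
        return math.log(b)
    return -math.log(a / b)


def complexity_features(window: np.ndarray, fs: float, params: FeatureParams = DEFAULT_PARAMS):
    """The six time-domain complexity descriptors as a dict."""
    x = np.asarray(window, dtype=float)
    if x.size < 100:
        raise ValueError("complexity features need at least 100 samples")
    return {
        "TD_ZCR": zero_crossing_rate(x, fs),
        "TD_PFD": petrosian_fd(x),
        "TD_HFD": higuchi_fd(x, params.hfd_kmax),
        "TD_LZC": lempel_ziv_complexity(x),
        "TD_PermEn": permutation_entropy(x, params.permen_order, params.permen_delay),
        "TD_SampEn": sample_entropy(x, params.sampen_m, params.sampen_r),
    }


def stat_descriptors(window: np.ndarray, eps_cv: float = 1e-6):
    """CV, Fisher–Pearson skewness, and excess kurtosis; zeros for constants."""
    x = np.asarray(window, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    sd = float(x.std())
    if sd < 1e-12:
        return 0.0, 0.0, 0.0, True
    cv = sd / max(abs(float(x.mean())), eps_cv)
    skew = float(spstats.skew(x))
    kurt = float(spstats.kurtosis(x, fisher=True))
    return cv, skew, kurt, False


def feature_vector(window: np.ndarray, fs: float, params: FeatureParams = DEFAULT_PARAMS):
    """Compute the full 39-value feature vector for one window.

    Returns (values dict keyed by FEATURE_NAMES, degenerate flag).
    """
    freqs, psd = welch_psd(window, fs, params.welch_overlap_frac)
    asp, rsp, total, degenerate = band_powers(freqs, psd, params)
    abr, agr = spectral_ratios(asp, params)
    activity, mobility, complexity, deg_h = hjorth(window, params.eps)
    cv, skew, kurt, deg_s = stat_descriptors(window, params.eps_cv)
    values: dict[str, float] = {}
    for b in params.bands:
        values[f"{b}a"] = asp[b]
    for b in params.bands:
        values[f"{b}r"] = rsp[b]
    values["ABR"] = abr
    values["AGR"] = agr
    values["TotalPower"] = total
    values["Hjorth_Activity"] = activity
    values["Hjorth_Mobility"] = mobility
    values["Hjorth_Complexity"] = complexity
    if deg_s:
        values.update(
            TD_ZCR=0.0,
            TD_PFD=0.0,
            TD_HFD=0.0,
            TD_LZC=0.0,
            TD_PermEn=0.0,
            TD_SampEn=sample_entropy(window, params.sampen_m, params.sampen_r),
        )
    else:
        values.update(complexity_features(window, fs, params))
    values["TD_CV"] = cv
    values["TD_Skewness"] = skew
    values["TD_Kurtosis"] = kurt
    degenerate = degenerate or deg_h or deg_s
    for name in FEATURE_NAMES:
        v = values[name]
        if not np.isfinite(v):
            values[name] = 0.0
            degenerate = True
    return values, degenerate


def extract_features(
    videos: dict[str, np.ndarray],
    fs: float,
    subject: str = "s01",
    params: FeatureParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """FeatureMatrix for one subject: one 39-feature row per sliding window.

    ``videos`` maps video_id to its cleaned (artifact-rejected,
    concatenated) single-channel signal.  Videos too short for a single
    window are skipped with a warning.
    """
    rows = []
    for video_id, clean in videos.items():
        wins = sliding_windows(clean, fs, params.win_s, params.shift_s)
        for w_idx, win in enumerate(wins):
            values, degenerate = feature_vector(win, fs, params)
            row = {
                "subject": subject,
                "video_id": video_id,
                "window_idx": w_idx,
                "start_s": w_idx * params.shift_s,
                "degenerate": degenerate,
            }
            row.update(values)
            rows.append(row)
    columns = list(METADATA_COLUMNS) + list(FEATURE_NAMES)
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns)
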