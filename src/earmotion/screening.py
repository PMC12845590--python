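"""Nonparametric feature screening with a composite ranking score.

Per subject and affective dimension, every feature is tested with a
Kruskal–Wallis omnibus over the three intensity labels; significant
features proceed to two-sided Mann–Whitney pairwise contrasts
(low-vs-mid, mid-vs-high, low-vs-high) with Benjamini–Hochberg FDR
correction across the feature × contrast family and Cliff's delta as
effect size.  For purely binary comparisons a parametric branch
(Welch t + Cohen's d) fires when Shapiro–Wilk normality and Levene
homoscedasticity both hold.

Cohort-level screening keeps a (feature, contrast) cell when a
significant and large effect appears in at least 30% of subjects and at
least 50% of those subjects agree on the direction; survivors are
ranked by

    score = −log10(max(median_p, 1e-12)) × normalized_effect × consistency

where the normalized effect size is the median |delta| over affected
subjects divided by the large-effect threshold 0.474 (|d|/0.8 for the
parametric branch) and consistency is the modal-direction fraction.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_NAMES

COMPARISONS = {
    "Low_vs_Mid": (0, 1),
    "Mid_vs_High": (1, 2),
    "Low_vs_High": (0, 2),
}

CLIFF_LARGE = 0.474
CLIFF_MEDIUM = 0.33
CLIFF_SMALL = 0.147
COHEN_LARGE = 0.8
COHEN_MEDIUM = 0.5
COHEN_SMALL = 0.2
P_FLOOR = 1e-12


def classify_effect(effect: float, kind: str = "cliffs_delta") -> str:
    a = abs(effect)
    if kind == "cliffs_delta":
        large, medium, small = CLIFF_LARGE, CLIFF_MEDIUM, CLIFF_SMALL
    else:
        large, medium, small = COHEN_LARGE, COHEN_MEDIUM, COHEN_SMALL
    if a >= large:
        return "large"
    if a >= medium:
        return "medium"
    if a >= small:
        return "small"
    return "negligible"


def cliffs_delta(x: np.ndarray, y: np.ndarray) -> float:
    """delta = (#(x>y) − #(x<y)) / (n·m), computed from the U statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("empty sample")
    u1 = spstats.mannwhitneyu(x, y, alternative="two-sided").statistic
    return float(2.0 * u1 / (n * m) - 1.0)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-SD Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    sp = math.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / max(n1 + n2 - 2, 1)
    )
    if sp == 0:
        return 0.0
    return float((x.mean() - y.mean()) / sp)


def omnibus_3group(groups: list[np.ndarray]) -> float:
    """Kruskal–Wallis p-value over the three label groups (tie-corrected)."""
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 1.0
    return float(spstats.kruskal(*groups).pvalue)


def mannwhitney_contrast(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(two-sided p, Cliff's delta); all-tied samples give (1.0, 0.0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    both = np.concatenate([x, y])
    if np.all(both == both[0]):
        return 1.0, 0.0
    res = spstats.mannwhitneyu(x, y, alternative="two-sided")
    delta = float(2.0 * res.statistic / (x.size * y.size) - 1.0)
    return float(res.pvalue), delta


def gated_binary_test(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> dict:
    """Welch t + Cohen's d when both samples pass Shapiro–Wilk and Levene;
    otherwise Mann–Whitney + Cliff's delta.  Records which branch fired."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per sample")
    parametric = False
    if np.ptp(x) > 0 and np.ptp(y) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_x = spstats.shapiro(x).pvalue
            sw_y = spstats.shapiro(y).pvalue
            lev = spstats.levene(x, y).pvalue
        parametric = sw_x > alpha and sw_y > alpha and lev > alpha
    if parametric:
        p = float(spstats.ttest_ind(x, y, equal_var=False).pvalue)
        effect = cohens_d(x, y)
        kind = "cohens_d"
    else:
        p, effect = mannwhitney_contrast(x, y)
        kind = "cliffs_delta"
    return {
        "p_raw": p,
        "effect": effect,
        "effect_kind": kind,
        "effect_class": classify_effect(effect, kind),
        "branch": "parametric" if parametric else "nonparametric",
    }


def subject_contrasts(
    features_df: pd.DataFrame,
    label_col: str,
    dimension: str,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All per-feature pairwise contrasts for one subject and dimension.

    The Kruskal–Wallis omnibus gates the pairwise Mann–Whitney tests;
    BH-FDR is applied across the feature × contrast family actually
    tested within this (subject, dimension).
    """
    subject = str(features_df["subject"].iloc[0]) if "subject" in features_df else ""
    labels = features_df[label_col].to_numpy()
    rows = []
    for feature in feature_names:
        values = features_df[feature].to_numpy(dtype=float)
        groups = {lab: values[labels == lab] for lab in (0, 1, 2)}
        usable = {lab: g for lab, g in groups.items() if g.size >= 2}
        if len(usable) >= 3:
            p_omni = omnibus_3group([groups[0], groups[1], groups[2]])
            if p_omni >= alpha:
                continue
        elif len(usable) < 2:
            continue
        else:
            p_omni = np.nan
        for comparison, (la, lb) in COMPARISONS.items():
            if groups[la].size < 2 or groups[lb].size < 2:
                continue
            p, delta = mannwhitney_contrast(groups[la], groups[lb])
            rows.append(
                {
                    "subject": subject,
                    "dimension": dimension,
                    "feature": feature,
                    "comparison": comparison,
                    "p_omnibus": p_omni,
                    "p_raw": p,
                    "effect": delta,
                    "effect_kind": "cliffs_delta",
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_fdr"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    df["direction"] = np.sign(df["effect"])
    df["effect_class"] = [
        classify_effect(e, k) for e, k in zip(df["effect"], df["effect_kind"])
    ]
    return df


def cohort_contrasts(
    features_df: pd.DataFrame,
    label_col: str,
    dimension: str,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Concatenate subject_contrasts over every subject in the matrix."""
    parts = []
    for _, grp in features_df.groupby("subject", sort=True):
        part = subject_contrasts(grp, label_col, dimension, feature_names, alpha)
        if not part.empty:
            parts.append(part)
    if not parts:
        return pd.DataFrame(
            columns=["subject", "dimension", "feature", "comparison", "p_raw", "p_fdr", "effect", "effect_kind", "effect_class", "direction"]
        )
    return pd.concat(parts, ignore_index=True)


def composite_score(consistency: float, normalized_effect_size: float, median_p: float) -> float:
    """score = −log10(max(median_p, 1e-12)) × normalized effect × consistency."""
    return -math.log10(max(median_p, P_FLOOR)) * normalized_effect_size * consistency


def _normalizer(kind: str) -> float:
    return CLIFF_LARGE if kind == "cliffs_delta" else COHEN_LARGE


def screen_features(
    contrasts: pd.DataFrame,
    n_subjects: int,
    min_subject_frac: float = 0.30,
    min_direction_frac: float = 0.50,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Multi-step screen over cohort contrasts; one row per surviving cell.

    A cell (dimension, comparison, feature) survives when the fraction
    of subjects with an FDR-significant large effect reaches
    ``min_subject_frac`` and the modal direction holds in at least
    ``min_direction_frac`` of those subjects.  median_p is the median
    raw p over affected subjects, bottom-capped before the logarithm.
    """
    if contrasts.empty:
        return pd.DataFrame(
            columns=["dimension", "comparison", "feature", "n_significant_subjects", "subject_fraction", "consistency", "normalized_effect_size", "median_p", "score"]
        )
    rows = []
    for (dimension, comparison, feature), grp in contrasts.groupby(
        ["dimension", "comparison", "feature"], sort=True
    ):
        affected = grp[(grp["p_fdr"] < alpha) & (grp["effect_class"] == "large")]
        n_aff = len(affected)
        frac = n_aff / n_subjects
        if frac < min_subject_frac or n_aff == 0:
            continue
        signs = np.sign(affected["effect"].to_numpy())
        n_modal = max(np.sum(signs > 0), np.sum(signs < 0))
        consistency = float(n_modal / n_aff)
        if consistency < min_direction_frac:
            continue
        norm_eff = float(
            np.median(
                [abs(e) / _normalizer(k) for e, k in zip(affected["effect"], affected["effect_kind"])]
            )
        )
        median_p = float(np.median(affected["p_raw"]))
        rows.append(
            {
                "dimension": dimension,
                "comparison": comparison,
                "feature": feature,
                "n_significant_subjects": n_aff,
                "subject_fraction": frac,
                "consistency": consistency,
                "normalized_effect_size": norm_eff,
                "median_p": max(median_p, P_FLOOR),
                "score": composite_score(consistency, norm_eff, median_p),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(
            ["dimension", "comparison", "score"], ascending=[True, True, False]
        ).reset_index(drop=True)
    return out


def proportion_heatmap(
    contrasts: pd.DataFrame,
    n_subjects: int,
    alpha: float = 0.05,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Feature × contrast matrix: % of subjects with significant + large effects."""
    mat = pd.DataFrame(0.0, index=list(feature_names), columns=list(COMPARISONS))
    if contrasts.empty:
        return mat
    hits = contrasts[(contrasts["p_fdr"] < alpha) & (contrasts["effect_class"] == "large")]
    counts = hits.groupby(["feature", "comparison"]).size()
    for (feature, comparison), n in counts.items():
        if feature in mat.index:
            mat.loc[feature, comparison] = 100.0 * n / n_subjects
    return mat


def exclude_unreliable_raters(
    ratings: pd.DataFrame,
    dev_threshold: float = 3.0,
    video_frac: float = 0.30,
) -> list[str]:
    """Subjects whose SAM ratings deviate ≥ ``dev_threshold`` points from the
    leave-one-out group mean on more than ``video_frac`` of videos, for
    either dimension.  ``ratings`` columns: subject, video_id, valence, arousal."""
    subjects = sorted(ratings["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    excluded = []
    for dim in ("valence", "arousal"):
        pivot = ratings.pivot_table(index="video_id", columns="subject", values=dim)
        total = pivot.sum(axis=1)
        n = pivot.notna().sum(axis=1)
        for subject in subjects:
            loo_mean = (total - pivot[subject].fillna(0.0)) / (n - pivot[subject].notna())
            dev = (pivot[subject] - loo_mean).abs()
            frac = float((dev >= dev_threshold).mean())
            if frac > video_frac:
                excluded.append(subject)
    return sorted(set(excluded))


def exclude_feature_outliers(
    subject_means: pd.DataFrame,
    sd_threshold: float = 2.0,
    feature_frac: float = 0.30,
) -> list[str]:
    """Subjects whose mean feature values sit more than ``sd_threshold``
    group SDs from the group mean for more than ``feature_frac`` of
    features.  ``subject_means``: rows = subjects, columns = features."""
    if len(subject_means) < 3:
        raise ValueError("need at least 3 subjects")
    mu = subject_means.mean(axis=0)
    sd = subject_means.std(axis=0, ddof=1).replace(0.0, np.inf)
    z = (subject_means - mu).abs() / sd
    frac = (z > sd_threshold).mean(axis=1)
    return sorted(frac[frac > feature_frac].index.tolist())
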