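"""Statistical screening unit and property tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earmotion import screening as S

import _oracles


# ---------------------------------------------------------------- omnibus


def test_omnibus_identical_groups_not_significant():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    assert S.omnibus_3group([g, g, g]) > 0.9


def test_omnibus_separated_groups_highly_significant():
    groups = [np.arange(1, 21), np.arange(21, 41), np.arange(41, 61)]
    assert S.omnibus_3group(groups) < 1e-6


def test_omnibus_matches_bruteforce_h():
    from scipy import stats as spstats

    groups = [np.array([1.0, 5.0, 8.0, 2.0, 9.0]),
              np.array([3.0, 3.0, 7.0, 6.0, 4.0]),
              np.array([10.0, 2.0, 5.0, 11.0, 12.0])]
    h_oracle = _oracles.kruskal_h_bruteforce([g.tolist() for g in groups])
    h_scipy = spstats.kruskal(*groups).statistic
    assert h_scipy == pytest.approx(h_oracle, abs=1e-9)
    assert S.omnibus_3group(groups) == pytest.approx(
        spstats.chi2.sf(h_oracle, 2), abs=1e-9
    )


def test_omnibus_requires_two_per_group():
    with pytest.raises(ValueError):
        S.omnibus_3group([np.array([1.0]), np.array([1.0, 2.0]), np.array([3.0, 4.0])])


# ---------------------------------------------------------------- Cliff's delta


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 2, 3], [4, 5, 6], -1.0),
        ([1, 3, 5], [2, 4, 6], -1.0 / 3.0),
        ([4, 5, 6], [1, 2, 3], 1.0),
    ],
)
def test_cliffs_delta_known_values(x, y, expected):
    assert S.cliffs_delta(np.array(x, float), np.array(y, float)) == pytest.approx(expected)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    x=st.lists(st.integers(-5, 5), min_size=2, max_size=12),
    y=st.lists(st.integers(-5, 5), min_size=2, max_size=12),
)
def test_cliffs_delta_antisymmetric_bounded_and_matches_bruteforce(x, y):
    xa, ya = np.array(x, float), np.array(y, float)
    d = S.cliffs_delta(xa, ya)
    assert d == pytest.approx(_oracles.cliffs_delta_bruteforce(x, y), abs=1e-9)
    assert d == pytest.approx(-S.cliffs_delta(ya, xa), abs=1e-9)
    assert -1.0 <= d <= 1.0


def test_all_tied_samples_give_null_contrast():
    p, delta = S.mannwhitney_contrast(np.full(5, 2.0), np.full(7, 2.0))
    assert p == 1.0 and delta == 0.0


# ---------------------------------------------------------------- gated test


def test_gated_test_parametric_branch_on_gaussians():
    rng = np.random.default_rng(42)
    x = rng.normal(0.0, 1.0, 50)
    y = rng.normal(1.0, 1.0, 50)
    res = S.gated_binary_test(x, y)
    assert res["branch"] == "parametric"
    assert res["effect_kind"] == "cohens_d"
    assert abs(res["effect"]) == pytest.approx(1.0, rel=0.3)


def test_gated_test_nonparametric_on_heavy_tails():
    rng = np.random.default_rng(0)
    x = rng.standard_cauchy(60)
    y = rng.standard_cauchy(60) + 1.0
    res = S.gated_binary_test(x, y)
    assert res["branch"] == "nonparametric"
    assert res["effect_kind"] == "cliffs_delta"


def test_gated_test_identical_samples_zero_effect():
    x = np.arange(10.0)
    res = S.gated_binary_test(x, x.copy())
    assert res["effect"] == pytest.approx(0.0, abs=1e-12)


def test_gated_test_requires_three_observations():
    with pytest.raises(ValueError):
        S.gated_binary_test(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------- FDR family


def _toy_features(n_subjects=4, n_windows=12, effect_feature="f1", shift=3.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for label in (0, 1, 2):
            for _ in range(n_windows):
                rows.append(
                    {
                        "subject": f"s{s}",
                        "lab": label,
                        "f1": rng.normal(shift * label, 1.0),
                        "f2": rng.normal(0.0, 1.0),
                        "f3": rng.normal(0.0, 1.0),
                    }
                )
    return pd.DataFrame(rows)


def test_bh_adjustment_never_below_raw_p():
    df = _toy_features()
    contrasts = S.cohort_contrasts(df, "lab", "arousal", feature_names=("f1", "f2", "f3"))
    assert not contrasts.empty
    assert (contrasts["p_fdr"] >= contrasts["p_raw"] - 1e-15).all()


def test_omnibus_gates_pairwise_tests():
    df = _toy_features(shift=0.0, seed=3)
    sub = S.subject_contrasts(df[df.subject == "s0"], "lab", "arousal", feature_names=("f1", "f2", "f3"))
    # with no effect, most features fail the omnibus and produce no contrasts
    assert len(sub) <= 9


# ---------------------------------------------------------------- Eq. 1 score


def test_composite_score_cap_boundary():
    assert S.composite_score(1.0, 1.0, 1e-12) == pytest.approx(12.0)
    assert S.composite_score(1.0, 1.0, 1e-30) == pytest.approx(12.0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    c=st.floats(0.0, 1.0),
    e=st.floats(0.0, 3.0),
    p=st.floats(1e-30, 0.05),
    dc=st.floats(0.0, 0.3),
    dp=st.floats(1.0, 100.0),
)
def test_composite_score_monotonicity(c, e, p, dc, dp):
    base = S.composite_score(c, e, p)
    assert S.composite_score(min(c + dc, 1.0), e, p) >= base - 1e-12
    assert S.composite_score(c, e + 0.5, p) >= base - 1e-12
    assert S.composite_score(c, e, min(p * dp, 1.0)) <= base + 1e-12
    assert base <= 12.0 * e * 1.0 + 1e-9


# ---------------------------------------------------------------- screen


def _contrast_rows(n_sig, n_subjects, positive=None, feature="f", p=1e-6):
    positive = n_sig if positive is None else positive
    rows = []
    for s in range(n_subjects):
        sig = s < n_sig
        direction = 1.0 if s < positive else -1.0
        rows.append(
            {
                "subject": f"s{s}",
                "dimension": "arousal",
                "feature": feature,
                "comparison": "Low_vs_High",
                "p_raw": p if sig else 0.5,
                "p_fdr": p * 2 if sig else 0.6,
                "effect": direction * (0.8 if sig else 0.1),
                "effect_kind": "cliffs_delta",
                "effect_class": "large" if sig else "negligible",
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def test_screen_drops_rare_effects():
    out = S.screen_features(_contrast_rows(2, 16), n_subjects=16)
    assert out.empty


def test_screen_consistency_arithmetic():
    out = S.screen_features(_contrast_rows(8, 16, positive=7), n_subjects=16)
    assert len(out) == 1
    row = out.iloc[0]
    assert row.n_significant_subjects == 8
    assert row.consistency == pytest.approx(7 / 8)
    assert row.normalized_effect_size == pytest.approx(0.8 / 0.474)
    assert row.score == pytest.approx(
        S.composite_score(7 / 8, 0.8 / 0.474, 1e-6)
    )


def test_screen_drops_direction_inconsistent_features():
    out = S.screen_features(_contrast_rows(10, 16, positive=4), n_subjects=16)
    # 6/10 vs 4/10: modal fraction 0.6 >= 0.5, retained with that consistency
    assert len(out) == 1 and out.iloc[0].consistency == pytest.approx(0.6)
    out2 = S.screen_features(
        _contrast_rows(10, 16, positive=4), n_subjects=16, min_direction_frac=0.7
    )
    assert out2.empty


# ---------------------------------------------------------------- heatmap


def test_heatmap_zero_when_nothing_significant():
    mat = S.proportion_heatmap(_contrast_rows(0, 16), 16, feature_names=("f",))
    assert (mat.to_numpy() == 0).all()


def test_heatmap_percentage_arithmetic():
    mat = S.proportion_heatmap(_contrast_rows(6, 16), 16, feature_names=("f",))
    assert mat.loc["f", "Low_vs_High"] == pytest.approx(37.5)


# ---------------------------------------------------------------- exclusions


def _ratings_cohort(n_subjects=24, n_videos=20, deviants=(), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    means = rng.integers(2, 8, size=n_videos)
    for s in range(n_subjects):
        for v in range(n_videos):
            base = int(means[v])
            if f"s{s:02d}" in deviants and v < int(0.4 * n_videos):
                val = 9 if base <= 5 else 1
            else:
                val = int(np.clip(base + rng.integers(-1, 2), 1, 9))
            rows.append(
                {"subject": f"s{s:02d}", "video_id": f"v{v}", "valence": val, "arousal": val}
            )
    return pd.DataFrame(rows)


def test_conforming_rater_retained():
    df = _ratings_cohort()
    assert S.exclude_unreliable_raters(df) == []


def test_planted_deviant_raters_recovered():
    deviants = ("s03", "s07", "s11", "s20")
    df = _ratings_cohort(deviants=deviants)
    assert S.exclude_unreliable_raters(df) == sorted(deviants)


def test_feature_outlier_exclusion():
    rng = np.random.default_rng(1)
    means = pd.DataFrame(
        rng.normal(0, 1, (10, 39)),
        index=[f"s{k:02d}" for k in range(10)],
        columns=[f"feat{k}" for k in range(39)],
    )
    assert S.exclude_feature_outliers(means) == []
    shifted = means.copy()
    shifted.iloc[4, :15] += 5.0 * means.std(axis=0).iloc[:15].to_numpy()  # 15/39 ≈ 38%
    assert S.exclude_feature_outliers(shifted) == ["s04"]
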