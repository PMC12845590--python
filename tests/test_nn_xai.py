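"""ANN grid/training and attribution tests."""

import numpy as np
import pandas as pd
import pytest

from earmotion import nn, xai
from earmotion.nn import MLP, NetConfig


def gaussian_fixture(n_per_class=200, n_features=39, n_informative=3, shift=2.0, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0, 1, (n_per_class, n_features))
    x1 = rng.normal(0, 1, (n_per_class, n_features))
    x1[:, :n_informative] += shift
    x = np.vstack([x0, x1])
    y = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    return x, y


# ---------------------------------------------------------------- grid


def test_grid_has_112_configurations():
    grid = nn.grid_configs()
    assert len(grid) == 112
    assert len(set(c.config_id for c in grid)) == 112


def test_fourteen_node_arrangements_strictly_decreasing():
    arr = nn.node_arrangements()
    assert len(arr) == 14
    for widths in arr:
        assert all(a > b for a, b in zip(widths, widths[1:]))
        assert set(widths) <= {16, 32, 64, 128}
    assert sum(1 for a in arr if len(a) == 1) == 4
    assert sum(1 for a in arr if len(a) == 2) == 6
    assert sum(1 for a in arr if len(a) == 3) == 4


def test_single_layer_restriction_gives_32_configs():
    grid = [c for c in nn.grid_configs() if len(c.hidden_widths) == 1]
    assert len(grid) == 32


# ---------------------------------------------------------------- training


def test_separable_data_classified_accurately():
    x, y = gaussian_fixture(n_informative=5, shift=2.5)
    out = nn.train_ann(NetConfig((32,)), x, y, seed=1, n_rotations=5)
    assert out.test_accuracy >= 0.95
    assert out.confusion.sum() == len(y)  # 5 rotations cover every fold once


def test_permuted_labels_give_chance_accuracy():
    x, y = gaussian_fixture()
    accs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        out = nn.train_ann(
            NetConfig((32,)), x, rng.permutation(y), seed=seed, n_rotations=1, max_epochs=60
        )
        accs.append(out.test_accuracy)
    assert np.mean(accs) == pytest.approx(0.5, abs=0.1)


def test_training_is_deterministic():
    x, y = gaussian_fixture(n_per_class=80)
    a = nn.train_ann(NetConfig((16,)), x, y, seed=5, n_rotations=2, max_epochs=40)
    b = nn.train_ann(NetConfig((16,)), x, y, seed=5, n_rotations=2, max_epochs=40)
    assert a.test_accuracy == b.test_accuracy
    assert a.rotation_metrics == b.rotation_metrics


def test_confusion_rows_sum_to_class_counts():
    x, y = gaussian_fixture(n_per_class=100)
    out = nn.train_ann(NetConfig((16,)), x, y, seed=2, n_rotations=5, max_epochs=40)
    assert out.confusion[0].sum() == 100
    assert out.confusion[1].sum() == 100


def test_no_training_fold_leakage():
    """Shifting rows outside the training folds changes predictions on them
    but leaves the training-fold scaler untouched."""
    x, y = gaussian_fixture(n_per_class=80)
    out = nn.train_ann(NetConfig((16,)), x, y, seed=3, n_rotations=1, max_epochs=30)
    train_mask = np.zeros(len(y), bool)
    train_mask[out.train_index] = True
    x_shift = x.copy()
    x_shift[~train_mask] += 100.0
    out2 = nn.train_ann(NetConfig((16,)), x_shift, y, seed=3, n_rotations=1, max_epochs=30)
    assert np.allclose(out.scaler.mean_, out2.scaler.mean_)
    assert np.allclose(out.scaler.scale_, out2.scaler.scale_)


# ---------------------------------------------------------------- selection


def _outcome(test_acc, train_acc, widths=(64,)):
    return nn.TrainOutcome(
        config=NetConfig(widths), train_accuracy=train_acc, val_accuracy=test_acc,
        test_accuracy=test_acc, train_loss=0.1, val_loss=0.1, test_loss=0.1,
        confusion=np.zeros((2, 2), int), per_class={}, selected_epoch=10,
    )


def test_selection_gates_on_training_accuracy():
    best, warn = nn.select_best_model([_outcome(0.80, 0.95), _outcome(0.85, 0.85)])
    assert best.test_accuracy == 0.80 and not warn


def test_selection_tie_prefers_smaller_network():
    best, _ = nn.select_best_model([_outcome(0.9, 0.95, (128, 64)), _outcome(0.9, 0.95, (16,))])
    assert best.config.hidden_widths == (16,)


def test_selection_falls_back_with_warning():
    best, warn = nn.select_best_model([_outcome(0.7, 0.5), _outcome(0.8, 0.6)])
    assert warn and best.test_accuracy == 0.8


# ---------------------------------------------------------------- dataset


def test_build_dataset_row_count_and_binary_filter():
    from earmotion.features import FEATURE_NAMES
    from earmotion.preprocess import LabeledDataset

    rng = np.random.default_rng(0)
    rows = []
    for label, videos in ((0, ["a", "b", "c", "d"]), (1, ["m"]), (2, ["w", "x", "y", "z"])):
        for vid in videos:
            for w in range(50):
                row = {"subject": "s01", "video_id": vid, "window_idx": w}
                row.update({f: rng.normal() for f in FEATURE_NAMES})
                rows.append(row)
    fdf = pd.DataFrame(rows)
    sel = pd.DataFrame(
        [
            {"subject": "s01", "video_id": v, "label": lab, "qc_mean": 90.0, "n_windows": 50}
            for lab, vids in ((0, "abcd"), (2, "wxyz"))
            for v in vids
        ]
    )
    labeled = LabeledDataset("arousal", sel, v_per_label=4, windows_per_video=43)
    x, y, meta = nn.build_dataset(fdf, labeled, "arousal", mode="binary")
    assert x.shape == (2 * 4 * 43, 39)  # N*C*V*E_min = 1*2*4*43 = 344
    assert set(y) == {0, 1}
    assert meta.window_idx.max() == 42  # chronologically first E_min windows


# ---------------------------------------------------------------- baselines


def test_baselines_on_separable_and_permuted_data():
    x, y = gaussian_fixture(n_informative=5, shift=2.5)
    accs = nn.baseline_classifiers(x, y, seed=1, n_rotations=2)
    assert set(accs) == {"svm_rbf", "knn5", "logreg"}
    assert all(a >= 0.9 for a in accs.values())
    rng = np.random.default_rng(0)
    perm = [nn.baseline_classifiers(x, rng.permutation(y), seed=s, n_rotations=1) for s in range(5)]
    for name in accs:
        assert np.mean([p[name] for p in perm]) == pytest.approx(0.5, abs=0.1)


def test_baselines_deterministic():
    x, y = gaussian_fixture(n_per_class=60)
    assert nn.baseline_classifiers(x, y, seed=4) == nn.baseline_classifiers(x, y, seed=4)


# ---------------------------------------------------------------- attribution


def linear_mlp(weights):
    """A no-hidden-layer network: logits = x @ W (linear model)."""
    m = MLP(weights.shape[0], NetConfig(hidden_widths=()), seed=0)
    m.weights = [weights.astype(float)]
    m.biases = [np.zeros(weights.shape[1])]
    return m


def test_gradient_x_input_exact_on_linear_model():
    rng = np.random.default_rng(0)
    w = rng.normal(0, 1, (6, 2))
    w[3, :] = 0.0  # ignored feature
    m = linear_mlp(w)
    x = rng.normal(0, 1, (10, 6))
    rel = xai.gradient_x_input(m, x, class_idx=1)
    assert np.allclose(rel, np.mean(np.abs(x * w[:, 1]), axis=0))
    assert rel[3] == 0.0


@pytest.mark.parametrize("steps", [1, 5, 50])
def test_integrated_gradients_exact_on_linear_model(steps):
    rng = np.random.default_rng(1)
    w = rng.normal(0, 1, (6, 2))
    m = linear_mlp(w)
    x = rng.normal(0, 1, (4, 6))
    ig = xai.integrated_gradients(m, x, steps=steps, class_idx=1)
    assert np.allclose(ig, x * w[:, 1], atol=1e-12)


def test_ig_zero_at_baseline_and_rejects_bad_steps():
    m = linear_mlp(np.ones((3, 2)))
    x = np.zeros((2, 3))
    assert np.allclose(xai.integrated_gradients(m, x, steps=10), 0.0)
    with pytest.raises(ValueError):
        xai.integrated_gradients(m, np.ones((1, 3)), steps=0)


def test_ig_completeness_on_trained_network():
    x, y = gaussian_fixture(n_per_class=150, n_features=10)
    out = nn.train_ann(NetConfig((32, 16), activation="tanh"), x, y, seed=7, n_rotations=1)
    m = out.model
    xs = out.scaler.transform(x[:30])
    ig = xai.integrated_gradients(m, xs, steps=50, class_idx=1)
    f = lambda z: m.logits(z)[:, 1]
    delta = f(xs) - f(np.zeros_like(xs))
    rel_err = np.abs(ig.sum(axis=1) - delta) / np.maximum(np.abs(delta), 1e-9)
    assert rel_err.max() < 0.01


def test_input_gradients_match_finite_differences():
    x, y = gaussian_fixture(n_per_class=100, n_features=8)
    out = nn.train_ann(NetConfig((16,), activation="tanh"), x, y, seed=9, n_rotations=1)
    m = out.model
    xs = out.scaler.transform(x[:20])
    g = m.input_gradients(xs, 1)
    eps = 1e-4
    f = lambda z: m.logits(z)[:, 1]
    for j in range(xs.shape[1]):
        xp, xm = xs.copy(), xs.copy()
        xp[:, j] += eps
        xm[:, j] -= eps
        fd = (f(xp) - f(xm)) / (2 * eps)
        scale = np.maximum(np.abs(fd), 1e-6)
        assert (np.abs(g[:, j] - fd) / scale).max() < 1e-3


# ---------------------------------------------------------------- selection/aggregation


def test_select_subject_features_rules():
    names = tuple(f"f{k}" for k in range(12))
    high = np.zeros(12)
    low = np.zeros(12)
    high[:9] = 0.9
    low[:9] = 0.8
    sel = xai.select_subject_features({0: low, 1: high}, names)
    assert sel == [f"f{k}" for k in range(9)]
    # only 3 qualify in both classes -> topped up to 8
    high2 = np.zeros(12)
    low2 = np.zeros(12)
    high2[:3] = 0.9
    low2[:3] = 0.9
    high2[3:] = np.linspace(0.45, 0.1, 9)
    low2[3:] = np.linspace(0.44, 0.09, 9)
    sel2 = xai.select_subject_features({0: low2, 1: high2}, names)
    assert len(sel2) == 8
    assert set(sel2[:3]) == {"f0", "f1", "f2"}
    # one-sided relevance does not qualify
    high3 = np.full(12, 0.9)
    low3 = np.full(12, 0.1)
    low3[:8] = 0.6
    sel3 = xai.select_subject_features({0: low3, 1: high3}, names)
    assert "f8" not in sel3


def test_group_level_relevance_threshold_and_totals():
    names = ("fa", "fb", "fc")
    per_subject = {}
    for k in range(16):
        selected = ["fa"] if k < 5 else []
        if k < 4:
            selected.append("fb")
        per_subject[f"s{k}"] = {
            "selected": selected,
            "relevance": {0: np.array([0.5, 0.3, 0.1]), 1: np.array([0.6, 0.2, 0.0])},
        }
    table = xai.group_level_relevance(per_subject, names)
    # ceil(0.3*16) = 5: fa retained (5 subjects), fb dropped (4)
    assert list(table.columns) == ["fa"]
    assert table.loc["Low", "fa"] == pytest.approx(5 * 0.5)
    assert table.loc["High", "fa"] == pytest.approx(5 * 0.6)
    assert table.loc["Total", "fa"] == pytest.approx(table.loc["Low", "fa"] + table.loc["High", "fa"])


def test_planted_features_dominate_attributions():
    """With 3 informative features, those 3 rank in the top 8 of both
    attribution methods in at least 80% of seeds."""
    hits_gxi = hits_ig = 0
    n_seeds = 10
    for seed in range(n_seeds):
        x, y = gaussian_fixture(n_per_class=120, shift=1.5, seed=seed)
        out = nn.train_ann(NetConfig((32,)), x, y, seed=seed, n_rotations=1, max_epochs=80)
        xs = out.scaler.transform(x[out.train_index])
        ys = y[out.train_index]
        for method, counter in (("gxi", "gxi"), ("ig", "ig")):
            rel = xai.subject_relevance(out.model, xs, ys, method=method)
            mean_rel = (rel[0] + rel[1]) / 2
            top8 = set(np.argsort(mean_rel)[-8:])
            ok = {0, 1, 2} <= top8
            if method == "gxi":
                hits_gxi += ok
            else:
                hits_ig += ok
    assert hits_gxi >= 0.8 * n_seeds
    assert hits_ig >= 0.8 * n_seeds
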