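"""Gradient-based feature attribution for the trained classifier.

Two methods over the pre-softmax class logits:

* Gradient × Input — per row, R_i = |x_i · ∂y_c/∂x_i|;
* Integrated Gradients — IG_i = (x_i − x'_i) · ∫₀¹ ∂F(x' + α(x−x'))/∂x_i dα,
  approximated by a midpoint Riemann sum (50 steps by default) from a
  zero baseline in standardized feature space.

Per subject, attributions are averaged over the rows of each class and
min–max normalized to [0, 1] across the 39 features.  A subject's
feature set is those with relevance > 0.5 in both classes, topped up to
a minimum of eight by the features closest to the cutoff (ranked by
min-over-classes relevance).  Group-level aggregation retains features
selected in ≥ 30% of subjects and sums their per-class relevance
(Total = Low + High).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .nn import MLP


def gradient_x_input(model: MLP, x: np.ndarray, class_idx: int) -> np.ndarray:
    """Mean |x_i · ∂logit_c/∂x_i| over the rows of x (one value per feature)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    grads = model.input_gradients(x, class_idx)
    return np.mean(np.abs(x * grads), axis=0)


def integrated_gradients(
    model: MLP,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 50,
    class_idx: int = 1,
) -> np.ndarray:
    """Per-row IG attributions (rows × features) for the class logit."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x0 = np.zeros_like(x) if baseline is None else np.broadcast_to(
        np.asarray(baseline, dtype=float), x.shape
    )
    diff = x - x0
    total = np.zeros_like(x)
    for k in range(steps):
        alpha = (k + 0.5) / steps
        total += model.input_gradients(x0 + alpha * diff, class_idx)
    return diff * total / steps


def ig_relevance(
    model: MLP,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 50,
    class_idx: int = 1,
) -> np.ndarray:
    """Mean |IG_i| over rows."""
    return np.mean(np.abs(integrated_gradients(model, x, baseline, steps, class_idx)), axis=0)


def minmax_normalize(relevance: np.ndarray) -> np.ndarray:
    r = np.asarray(relevance, dtype=float)
    lo, hi = r.min(), r.max()
    if hi - lo < 1e-15:
        return np.zeros_like(r)
    return (r - lo) / (hi - lo)


def subject_relevance(
    model: MLP,
    x_std: np.ndarray,
    y: np.ndarray,
    method: str = "gxi",
    steps: int = 50,
) -> dict[int, np.ndarray]:
    """Per-class normalized relevance for one subject's trained model.

    ``x_std`` must already be in the model's (standardized) input space;
    rows are grouped by true class label and attributions for class c
    are averaged over that class's rows.
    """
    out: dict[int, np.ndarray] = {}
    for c in sorted(np.unique(y)):
        rows = x_std[y == c]
        if method == "gxi":
            rel = gradient_x_input(model, rows, int(c))
        elif method == "ig":
            rel = ig_relevance(model, rows, steps=steps, class_idx=int(c))
        else:
            raise ValueError(f"unknown attribution method {method!r}")
        out[int(c)] = minmax_normalize(rel)
    return out


def select_subject_features(
    relevance_by_class: dict[int, np.ndarray],
    feature_names: tuple[str, ...],
    threshold: float = 0.5,
    min_features: int = 8,
) -> list[str]:
    """Features with normalized relevance > threshold in both classes,
    topped up to ``min_features`` by min-over-classes relevance."""
    rel = np.vstack([relevance_by_class[c] for c in sorted(relevance_by_class)])
    min_rel = rel.min(axis=0)
    qualified = [i for i in range(len(feature_names)) if np.all(rel[:, i] > threshold)]
    if len(qualified) < min_features:
        ranked = sorted(
            (i for i in range(len(feature_names)) if i not in set(qualified)),
            key=lambda i: (-min_rel[i], i),
        )
        qualified = qualified + ranked[: min_features - len(qualified)]
    return [feature_names[i] for i in sorted(qualified)]


def group_level_relevance(
    per_subject: dict[str, dict],
    feature_names: tuple[str, ...],
    min_frac: float = 0.30,
    class_names: tuple[str, str] = ("Low", "High"),
) -> pd.DataFrame:
    """Group table: per-class cumulative relevance for features selected
    in at least ``ceil(min_frac × n_subjects)`` subjects.

    ``per_subject`` maps subject id to a dict with keys ``selected``
    (feature list) and ``relevance`` (class index → normalized vector).
    Returns rows Low / High / Total / n_subjects, columns = retained
    features.
    """
    n_subjects = len(per_subject)
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    threshold = math.ceil(min_frac * n_subjects)
    counts: dict[str, int] = {f: 0 for f in feature_names}
    sums = {c: {f: 0.0 for f in feature_names} for c in (0, 1)}
    for info in per_subject.values():
        selected = set(info["selected"])
        rel = info["relevance"]
        for f in selected:
            i = feature_names.index(f)
            counts[f] += 1
            for c in (0, 1):
                sums[c][f] += float(rel[c][i])
    retained = [f for f in feature_names if counts[f] >= threshold]
    data = {
        class_names[0]: [sums[0][f] for f in retained],
        class_names[1]: [sums[1][f] for f in retained],
    }
    table = pd.DataFrame(data, index=retained).T
    if retained:
        table.loc["Total"] = table.loc[class_names[0]] + table.loc[class_names[1]]
        table.loc["n_subjects"] = [counts[f] for f in retained]
    return table
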