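"""End-to-end pipeline: simulate → preprocess → features → screen → classify.

Holds the configuration object (every stage constant overridable, echoed
into a run manifest), the per-session preprocessing driver, and report
rendering (EC/EO spectra, QC table, proportion heatmaps, screening and
relevance tables, confusion matrix).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import nn, preprocess, screening, simulate, xai


@dataclass
class PipelineConfig:
    seed: int = 0
    dimensions: tuple[str, ...] = ("arousal", "valence")
    analysis_channel: str = "R4a"
    cohort: simulate.CohortSpec = field(default_factory=simulate.CohortSpec)
    filter: preprocess.FilterSpec = field(default_factory=preprocess.FilterSpec)
    qc: preprocess.QCConstants = field(default_factory=preprocess.QCConstants)
    amp_threshold_uv: float = 100.0
    feature_params: feat.FeatureParams = field(default_factory=feat.FeatureParams)
    alpha: float = 0.05
    min_subject_frac: float = 0.30
    min_direction_frac: float = 0.50
    grid: list[nn.NetConfig] | None = None       # None -> full 112-config grid
    n_rotations: int = 5
    max_epochs: int = 200
    xai_methods: tuple[str, ...] = ("gxi", "ig")
    ig_steps: int = 50
    relevance_threshold: float = 0.5
    min_features: int = 8

    def to_manifest(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): encode(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        d = {f.name: encode(getattr(self, f.name)) for f in dataclasses.fields(self)}
        if self.grid is not None:
            d["grid"] = [c.config_id for c in self.grid]
        blob = json.dumps(d, sort_keys=True, default=str)
        return {"config": d, "config_hash": hashlib.sha256(blob.encode()).hexdigest()}


@dataclass
class SessionResult:
    subject: str
    features: pd.DataFrame          # per-window 39-feature rows (QC-passing videos)
    qc_reports: list[preprocess.QCReport]
    video_table: pd.DataFrame       # per passing video: labels, qc_mean, n_windows
    ratings: pd.DataFrame


def preprocess_session(
    session: simulate.RawSession, config: PipelineConfig
) -> SessionResult:
    """Filter, reject, QC-gate and featurize one session's analysis channel."""
    ch = list(session.channel_labels).index(config.analysis_channel)
    raw = session.signal[ch]
    filtered = preprocess.bandpass_notch(raw, session.fs, config.filter)
    qc_reports = []
    video_rows = []
    videos_clean = {}
    for _, ev in session.events.iterrows():
        vid = ev["video_id"]
        seg_sig = filtered[int(ev["onset"]) : int(ev["onset"]) + int(ev["duration"])]
        seg = preprocess.segment_and_reject(seg_sig, session.fs, config.amp_threshold_uv)
        report = preprocess.qc_score(seg_sig, session.fs, seg, vid, config.qc)
        qc_reports.append(report)
        if not report.passed:
            continue
        videos_clean[vid] = seg.clean_signal
        rating = session.ratings[session.ratings["video_id"] == vid].iloc[0]
        n_windows = max(
            (seg.clean_signal.size - int(config.feature_params.win_s * session.fs))
            // int(config.feature_params.shift_s * session.fs)
            + 1,
            0,
        ) if seg.clean_signal.size >= int(config.feature_params.win_s * session.fs) else 0
        video_rows.append(
            {
                "subject": session.subject_id,
                "video_id": vid,
                "class_label": ev["class_label"],
                "valence_label": preprocess.bin_sam(rating["valence"]),
                "arousal_label": preprocess.bin_sam(rating["arousal"]),
                "qc_mean": float(np.mean(list(report.scores.values()))),
                "n_windows": n_windows,
            }
        )
    video_table = pd.DataFrame(video_rows)
    fmat = feat.extract_features(
        videos_clean, session.fs, session.subject_id, config.feature_params
    )
    if not fmat.empty and not video_table.empty:
        fmat = fmat.merge(
            video_table[["video_id", "valence_label", "arousal_label"]],
            on="video_id",
            how="left",
        )
    ratings = session.ratings.assign(subject=session.subject_id)
    return SessionResult(session.subject_id, fmat, qc_reports, video_table, ratings)


def screen_stage(
    features_all: pd.DataFrame, dimension: str, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(contrasts, screening table, proportion heatmap) for one dimension."""
    n_subjects = features_all["subject"].nunique()
    contrasts = screening.cohort_contrasts(
        features_all, f"{dimension}_label", dimension, alpha=config.alpha
    )
    table = screening.screen_features(
        contrasts,
        n_subjects,
        config.min_subject_frac,
        config.min_direction_frac,
        config.alpha,
    )
    heatmap = screening.proportion_heatmap(contrasts, n_subjects, config.alpha)
    return contrasts, table, heatmap


def classify_stage(
    features_all: pd.DataFrame,
    video_tables: pd.DataFrame,
    dimension: str,
    config: PipelineConfig,
) -> dict:
    """Per-subject ANN grid + XAI relevance + baselines for one dimension."""
    grid = config.grid if config.grid is not None else nn.grid_configs()
    vt = video_tables.rename(columns={f"{dimension}_label": "label"})[
        ["subject", "video_id", "label", "qc_mean", "n_windows"]
    ]
    labeled = preprocess.balance_dataset(vt, dimension, required_labels=(0, 2))
    per_subject_outcomes = {}
    per_subject_relevance: dict[str, dict[str, dict]] = {m: {} for m in config.xai_methods}
    baselines = {}
    for subject in sorted(labeled.selection["subject"].unique()):
        sub_sel = dataclasses.replace(
            labeled, selection=labeled.selection[labeled.selection["subject"] == subject]
        )
        x, y, _meta = nn.build_dataset(features_all, sub_sel, dimension, mode="binary")
        sub_seed = config.seed + int(hashlib.sha256(subject.encode()).hexdigest()[:4], 16)
        outcomes = [
            nn.train_ann(
                cfg, x, y, seed=sub_seed, n_rotations=config.n_rotations,
                max_epochs=config.max_epochs,
            )
            for cfg in grid
        ]
        best, warn = nn.select_best_model(outcomes)
        per_subject_outcomes[subject] = {
            "best_config": best.config.config_id,
            "test_accuracy": best.test_accuracy,
            "train_accuracy": best.train_accuracy,
            "gate_warning": warn,
            "confusion": best.confusion.tolist(),
            "per_class": best.per_class,
        }
        x_train = best.scaler.transform(x[best.train_index])
        y_train = y[best.train_index]
        for method in config.xai_methods:
            rel = xai.subject_relevance(
                best.model, x_train, y_train, method=method, steps=config.ig_steps
            )
            selected = xai.select_subject_features(
                rel, feat.FEATURE_NAMES, config.relevance_threshold, config.min_features
            )
            per_subject_relevance[method][subject] = {"selected": selected, "relevance": rel}
        baselines[subject] = nn.baseline_classifiers(
            x, y, seed=sub_seed, n_rotations=config.n_rotations
        )
    group_tables = {
        method: xai.group_level_relevance(
            per_subject_relevance[method], feat.FEATURE_NAMES, config.min_subject_frac
        )
        for method in config.xai_methods
    }
    return {
        "labeled": labeled,
        "outcomes": per_subject_outcomes,
        "relevance": per_subject_relevance,
        "group_tables": group_tables,
        "baselines": baselines,
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages on a synthetic cohort and write CSV/JSON outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log: list[dict] = []

    def stage(name):
        log.append({"stage": name, "t": round(time.time() - t0, 2)})

    cohort_spec = dataclasses.replace(config.cohort, seed=config.seed)
    sessions = simulate.generate_cohort(cohort_spec)
    stage("simulate")

    results = [preprocess_session(s, config) for s in sessions]
    stage("preprocess+features")

    features_all = pd.concat([r.features for r in results], ignore_index=True)
    video_tables = pd.concat([r.video_table for r in results], ignore_index=True)
    if video_tables.empty or features_all.empty:
        raise RuntimeError("preprocessing: every video was excluded by the QC gate")
    features_all.to_csv(out / "feature_matrix.csv", index=False)
    qc_rows = [
        {"subject": r.subject, "video_id": q.video_id, **q.scores, "passed": q.passed}
        for r in results
        for q in r.qc_reports
    ]
    pd.DataFrame(qc_rows).to_csv(out / "qc_reports.csv", index=False)
    summary = preprocess.retention_summary([q for r in results for q in r.qc_reports])
    (out / "retention_summary.json").write_text(json.dumps(summary, indent=1))

    for dimension in config.dimensions:
        contrasts, table, heatmap = screen_stage(features_all, dimension, config)
        contrasts.to_csv(out / f"contrasts_{dimension}.csv", index=False)
        table.to_csv(out / f"screening_{dimension}.csv", index=False)
        heatmap.to_csv(out / f"heatmap_{dimension}.csv")
        stage(f"screen:{dimension}")
        clf = classify_stage(features_all, video_tables, dimension, config)
        (out / f"classification_{dimension}.json").write_text(
            json.dumps({"outcomes": clf["outcomes"], "baselines": clf["baselines"]}, indent=1)
        )
        for method, table_g in clf["group_tables"].items():
            table_g.to_csv(out / f"relevance_{method}_{dimension}.csv")
        stage(f"classify:{dimension}")

    manifest = config.to_manifest()
    manifest["stages"] = log
    manifest["n_subjects"] = len(sessions)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def render_reports(run_dir: str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """Regenerate figure-style artifacts from a completed run directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    out = Path(out_dir) if out_dir else run_dir / "reports"
    out.mkdir(parents=True, exist_ok=True)
    written = []
    qc_path = run_dir / "qc_reports.csv"
    if qc_path.exists():
        qc = pd.read_csv(qc_path)
        fig, ax = plt.subplots(figsize=(8, 4))
        metric_cols = [c for c in qc.columns if c not in ("subject", "video_id", "passed")]
        ax.imshow(qc[metric_cols].to_numpy(), aspect="auto", vmin=0, vmax=100, cmap="viridis")
        ax.set_xticks(range(len(metric_cols)), metric_cols, rotation=45, ha="right")
        ax.set_ylabel("video")
        fig.tight_layout()
        p = out / "qc_heatmap.png"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)
    for dimension in ("arousal", "valence"):
        hm_path = run_dir / f"heatmap_{dimension}.csv"
        if hm_path.exists():
            hm = pd.read_csv(hm_path, index_col=0)
            fig, ax = plt.subplots(figsize=(5, 9))
            ax.imshow(hm.to_numpy(), aspect="auto", cmap="magma", vmin=0, vmax=100)
            ax.set_xticks(range(len(hm.columns)), hm.columns, rotation=45, ha="right")
            ax.set_yticks(range(len(hm.index)), hm.index, fontsize=6)
            fig.tight_layout()
            p = out / f"proportion_heatmap_{dimension}.png"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)
        sc_path = run_dir / f"screening_{dimension}.csv"
        if sc_path.exists():
            sc = pd.read_csv(sc_path)
            if sc.empty:
                (out / f"screening_{dimension}_note.txt").write_text("no features retained\n")
    return written


def ec_eo_spectra(session: simulate.RawSession, config: PipelineConfig) -> pd.DataFrame:
    """Welch spectra of the EC and EO baselines (physiological-validity check)."""
    ch = list(session.channel_labels).index(config.analysis_channel)
    raw = session.signal[ch]
    rows = {}
    for name, (start, stop) in session.baselines.items():
        filtered = preprocess.bandpass_notch(raw[start:stop], session.fs, config.filter)
        freqs, psd = feat.welch_psd(filtered, session.fs)
        rows["frequency_hz"] = freqs
        rows[f"psd_{name.lower()}"] = psd
    return pd.DataFrame(rows)
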