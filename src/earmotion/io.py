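"""Session file I/O: long-format CSV + JSON sidecar (canonical), EDF read.

A session is stored as ``<subject>_signal.csv`` with columns
``sample_index, channel, microvolts`` and ``<subject>_meta.json``
holding sampling rate, events, ratings, baselines, artifact log and the
generator's ground truth.  EDF recordings can be ingested through mne
when it is installed; all interchange between pipeline stages is CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import RawSession


def write_session(session: RawSession, out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig_path = out_dir / f"{session.subject_id}_signal.csv"
    meta_path = out_dir / f"{session.subject_id}_meta.json"
    n_ch, n_samp = session.signal.shape
    frames = []
    for ch_idx, label in enumerate(session.channel_labels):
        frames.append(
            pd.DataFrame(
                {
                    "sample_index": np.arange(n_samp),
                    "channel": label,
                    "microvolts": session.signal[ch_idx],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        sig_path, index=False, float_format="%.17g"
    )
    meta = {
        "subject_id": session.subject_id,
        "fs": session.fs,
        "channel_labels": list(session.channel_labels),
        "events": session.events.to_dict(orient="records"),
        "ratings": session.ratings.to_dict(orient="records"),
        "baselines": {k: list(v) for k, v in session.baselines.items()},
        "ground_truth": session.ground_truth,
        "artifact_log": session.artifact_log,
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return sig_path, meta_path


def read_session(path: str | Path, fs_expected: float | None = None) -> RawSession:
    """Read a session from CSV+JSON (path = the signal CSV or the meta JSON)
    or from an EDF file (metadata sidecar still required for events/ratings)."""
    path = Path(path)
    if path.suffix == ".json":
        meta_path = path
        sig_path = path.with_name(path.name.replace("_meta.json", "_signal.csv"))
    else:
        sig_path = path
        meta_path = path.with_name(
            path.name.replace("_signal.csv", "_meta.json").replace(".edf", "_meta.json")
        )
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {meta_path}")
    meta = json.loads(meta_path.read_text())
    fs = float(meta["fs"])
    if fs_expected is not None and abs(fs - fs_expected) > 1e-9:
        raise ValueError(f"fs mismatch: file has {fs}, config expects {fs_expected}")
    channels = meta["channel_labels"]
    if sig_path.suffix == ".edf":
        import mne

        raw = mne.io.read_raw_edf(sig_path, preload=True, verbose="error")
        signal = raw.get_data(picks=channels) * 1e6  # volts -> microvolts
    else:
        df = pd.read_csv(sig_path)
        signal = np.vstack(
            [df.loc[df["channel"] == ch, "microvolts"].to_numpy() for ch in channels]
        )
    events = pd.DataFrame(meta["events"])
    ratings = pd.DataFrame(meta["ratings"])
    rated = set(ratings["video_id"]) if not ratings.empty else set()
    missing = [v for v in events["video_id"] if v not in rated]
    if missing:
        raise ValueError(f"missing SAM ratings for videos: {missing}")
    return RawSession(
        subject_id=meta["subject_id"],
        fs=fs,
        channel_labels=tuple(channels),
        signal=signal,
        events=events,
        ratings=ratings,
        baselines={k: tuple(v) for k, v in meta["baselines"].items()},
        ground_truth=meta.get("ground_truth", {}),
        artifact_log=meta.get("artifact_log", []),
    )


def list_sessions(in_dir: str | Path) -> list[Path]:
    return sorted(Path(in_dir).glob("*_meta.json"))
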