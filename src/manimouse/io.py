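"""Readers and writers for the package's on-disk formats.

Everything user-facing is plain text: calcium matrices as CSV (neurons as
rows) or compressed ``.npz``, behavior labels and key points as per-frame
CSV, arena geometry as JSON, feature tables and classifier reports as CSV.
The key-point reader accepts two dialects: a wide single-header form
(``x_nose, y_nose, ...``) and the 3-row scorer/bodypart/coord header used by
common pose-estimation exports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ArenaGeometry
from .classify import ClassifierReport, FeatureTable, METRICS
from .errors import InputError
from .synthetic import BEHAVIORS, BehaviorLabelTrack, CalciumRecording, KeypointTrack


# -- calcium ---------------------------------------------------------------

def write_calcium_csv(recording: CalciumRecording, path) -> None:
    """Write a recording as CSV: one row per neuron, columns are frames."""
    df = pd.DataFrame(
        recording.fluorescence,
        index=[f"neuron_{i}" for i in range(recording.n_neurons)],
    )
    df.index.name = "neuron"
    df.to_csv(path)


def read_calcium_csv(path, fps: float = 15.0, **meta) -> CalciumRecording:
    df = pd.read_csv(path, index_col=0)
    return CalciumRecording(fluorescence=df.to_numpy(dtype=float), fps=fps, **meta)


def write_calcium_npz(recording: CalciumRecording, path) -> None:
    np.savez_compressed(
        path,
        fluorescence=recording.fluorescence,
        fps=recording.fps,
        session_id=recording.session_id,
        mouse_id=recording.mouse_id,
        group_tag=recording.group_tag,
    )


def read_calcium_npz(path) -> CalciumRecording:
    with np.load(path, allow_pickle=False) as z:
        return CalciumRecording(
            fluorescence=z["fluorescence"],
            fps=float(z["fps"]),
            session_id=str(z["session_id"]),
            mouse_id=str(z["mouse_id"]),
            group_tag=str(z["group_tag"]),
        )


# -- behavior labels -------------------------------------------------------

def write_behavior_csv(track: BehaviorLabelTrack, path) -> None:
    data = {"frame": np.arange(track.n_frames), "label": track.labels.astype(str)}
    if track.probabilities is not None:
        for j, b in enumerate(BEHAVIORS):
            data[f"p_{b}"] = track.probabilities[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_behavior_csv(path) -> BehaviorLabelTrack:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise InputError(f"{path}: behavior CSV needs a 'label' column")
    prob_cols = [f"p_{b}" for b in BEHAVIORS]
    probs = df[prob_cols].to_numpy(dtype=float) if all(c in df.columns for c in prob_cols) else None
    return BehaviorLabelTrack(labels=df["label"].to_numpy(dtype=object), probabilities=probs)


# -- key points ------------------------------------------------------------

def write_keypoints_csv(track: KeypointTrack, path) -> None:
    """Wide form: frame, x_<name>, y_<name>, ... (+ c_<name> if confidence)."""
    data = {"frame": np.arange(track.n_frames)}
    for k, name in enumerate(track.keypoint_names):
        data[f"x_{name}"] = track.coordinates[:, k, 0]
        data[f"y_{name}"] = track.coordinates[:, k, 1]
        if track.confidence is not None:
            data[f"c_{name}"] = track.confidence[:, k]
    pd.DataFrame(data).to_csv(path, index=False)


def read_keypoints_csv(path) -> KeypointTrack:
    """Read either the wide dialect or a 3-row scorer/bodypart/coord header."""
    head = pd.read_csv(path, nrows=3, header=None)
    first_cell = str(head.iloc[0, 0]).lower()
    if first_cell in ("scorer",):  # multi-row pose-estimation export
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        bodyparts = list(dict.fromkeys(c[1] for c in df.columns))
        n = len(df)
        coords = np.empty((n, len(bodyparts), 2))
        conf = None
        scorer = df.columns[0][0]
        for k, bp in enumerate(bodyparts):
            coords[:, k, 0] = df[(scorer, bp, "x")].to_numpy(dtype=float)
            coords[:, k, 1] = df[(scorer, bp, "y")].to_numpy(dtype=float)
            if (scorer, bp, "likelihood") in df.columns:
                if conf is None:
                    conf = np.empty((n, len(bodyparts)))
                conf[:, k] = df[(scorer, bp, "likelihood")].to_numpy(dtype=float)
        return KeypointTrack(coordinates=coords, keypoint_names=bodyparts, confidence=conf)

    df = pd.read_csv(path)
    names = [c[2:] for c in df.columns if c.startswith("x_")]
    if not names:
        raise InputError(f"{path}: no x_<name> columns found in key-point CSV")
    coords = np.empty((len(df), len(names), 2))
    conf_cols = [f"c_{n}" for n in names]
    conf = np.empty((len(df), len(names))) if all(c in df.columns for c in conf_cols) else None
    for k, name in enumerate(names):
        coords[:, k, 0] = df[f"x_{name}"].to_numpy(dtype=float)
        coords[:, k, 1] = df[f"y_{name}"].to_numpy(dtype=float)
        if conf is not None:
            conf[:, k] = df[f"c_{name}"].to_numpy(dtype=float)
    return KeypointTrack(coordinates=coords, keypoint_names=names, confidence=conf)


# -- geometry & reports ----------------------------------------------------

def write_arena_json(arena: ArenaGeometry, path) -> None:
    Path(path).write_text(
        json.dumps(
            {"center": list(arena.center), "zone_radii": list(arena.zone_radii)},
            indent=2,
        )
    )


def read_arena_json(path) -> ArenaGeometry:
    obj = json.loads(Path(path).read_text())
    return ArenaGeometry(center=tuple(obj["center"]), zone_radii=tuple(obj["zone_radii"]))


def write_feature_table_csv(table: FeatureTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_feature_table_csv(path, feature_names=None) -> FeatureTable:
    df = pd.read_csv(path)
    if feature_names is None:
        feature_names = [
            c for c in df.columns
            if c not in ("group", "mouse_id", "session_id")
            and pd.api.types.is_numeric_dtype(df[c])
        ]
    return FeatureTable(data=df, feature_names=tuple(feature_names))


def report_row(report: ClassifierReport) -> dict:
    """Flatten a report to one summary row (mean ± SEM per metric)."""
    row = {
        "comparison": f"{report.group_a} vs {report.group_b}",
        "condition": report.condition,
        "n_repeats": report.n_repeats,
    }
    for m in METRICS:
        row[f"{m}_mean"] = report.mean(m)
        row[f"{m}_sem"] = report.sem(m)
    return row


def write_reports_csv(reports, path) -> None:
    pd.DataFrame([report_row(r) for r in reports]).to_csv(path, index=False)


def write_report_json(report: ClassifierReport, path) -> None:
    obj = {
        "comparison": f"{report.group_a} vs {report.group_b}",
        "condition": report.condition,
        "n_repeats": report.n_repeats,
        "seed": report.seed,
        "per_repeat": {m: list(map(float, getattr(report, m))) for m in METRICS},
    }
    Path(path).write_text(json.dumps(obj, indent=2))
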