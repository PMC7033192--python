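"""Readers and writers binding the pipeline stages.

Formats: trajectory CSV (``segment_id, frame, agent_id, role, x_m, y_m``)
with a segments manifest CSV (``segment_id, fps, label``); HDF5 stores
for adjacency tensors and per-window decompositions (complex arrays split
into ``_re``/``_im`` datasets for portability); eigenvalue summaries,
feature tables, curves and model coefficients as CSV; metrics and
resolved configuration as JSON/YAML.  All CSV numbers are written in full
double precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .adjacency import TrajectorySegment
from .errors import ValidationError
from .features import WindowDecomposition
from .spectral import SnapshotTensor

_CSV_FLOAT = "%.17g"


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def write_trajectory_csv(
    segments: Sequence[TrajectorySegment], csv_path, manifest_path
) -> None:
    """Write segments to a long-format trajectory CSV plus a manifest CSV."""
    frames = []
    manifest = []
    for seg in segments:
        n, T, _ = seg.positions.shape
        frames.append(
            pd.DataFrame(
                {
                    "segment_id": np.repeat(seg.segment_id, n * T),
                    "frame": np.tile(np.arange(T), n),
                    "agent_id": np.repeat(np.arange(n), T),
                    "role": np.repeat(seg.roles, T),
                    "x_m": seg.positions[:, :, 0].ravel(),
                    "y_m": seg.positions[:, :, 1].ravel(),
                }
            )
        )
        manifest.append(
            {"segment_id": seg.segment_id, "fps": seg.fps,
             "label": "" if seg.label is None else seg.label}
        )
    pd.concat(frames, ignore_index=True).to_csv(
        csv_path, index=False, float_format=_CSV_FLOAT
    )
    pd.DataFrame(manifest).to_csv(manifest_path, index=False, float_format=_CSV_FLOAT)


def read_trajectory_csv(csv_path, manifest_path) -> List[TrajectorySegment]:
    """Read segments written by :func:`write_trajectory_csv`."""
    table = pd.read_csv(csv_path)
    required = {"segment_id", "frame", "agent_id", "role", "x_m", "y_m"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"trajectory CSV lacks columns {sorted(missing)}")
    manifest = pd.read_csv(manifest_path).set_index("segment_id")
    segments = []
    for seg_id, group in table.groupby("segment_id", sort=False):
        if seg_id not in manifest.index:
            raise ValidationError(f"segment {seg_id} missing from manifest")
        agents = np.sort(group["agent_id"].unique())
        frames = np.sort(group["frame"].unique())
        if not np.array_equal(frames, np.arange(frames.size)):
            raise ValidationError(f"segment {seg_id}: frames must be contiguous from 0")
        n, T = agents.size, frames.size
        pos = np.full((n, T, 2), np.nan)
        roles = [None] * n
        pivot = group.sort_values(["agent_id", "frame"])
        if len(pivot) != n * T:
            raise ValidationError(f"segment {seg_id}: missing agent/frame rows")
        pos[:, :, 0] = pivot["x_m"].to_numpy().reshape(n, T)
        pos[:, :, 1] = pivot["y_m"].to_numpy().reshape(n, T)
        roles = tuple(pivot.groupby("agent_id", sort=True)["role"].first())
        row = manifest.loc[seg_id]
        label = None if pd.isna(row.get("label")) or row.get("label") == "" else int(row["label"])
        segments.append(
            TrajectorySegment(pos, roles, fps=float(row["fps"]),
                              segment_id=str(seg_id), label=label)
        )
    return segments


# ---------------------------------------------------------------------------
# HDF5 tensor / decomposition store
# ---------------------------------------------------------------------------


def save_adjacency_h5(path, tensors: Dict[str, SnapshotTensor]) -> None:
    with h5py.File(path, "w") as f:
        for seg_id, tensor in tensors.items():
            grp = f.require_group(f"segments/{seg_id}")
            ds = grp.create_dataset("adjacency", data=tensor.values, dtype="float64")
            ds.attrs["dt"] = tensor.dt


def load_adjacency_h5(path) -> Dict[str, SnapshotTensor]:
    out = {}
    with h5py.File(path, "r") as f:
        if "segments" not in f:
            raise ValidationError(f"{path}: no /segments group")
        for seg_id, grp in f["segments"].items():
            ds = grp["adjacency"]
            out[seg_id] = SnapshotTensor(ds[()], dt=float(ds.attrs["dt"]))
    return out


def save_windows_h5(path, windows_by_segment: Dict[str, Sequence[WindowDecomposition]]) -> None:
    """Persist per-window decompositions (complex data as paired re/im)."""
    with h5py.File(path, "a") as f:
        for seg_id, windows in windows_by_segment.items():
            for k, w in enumerate(windows):
                grp = f.require_group(f"segments/{seg_id}/windows/{k}")
                grp.attrs["start"], grp.attrs["end"] = w.start, w.end
                grp.attrs["valid"] = bool(w.valid)
                grp.create_dataset("vaf", data=np.asarray(w.mode_vaf, dtype="float64"))
                if w.result is None:
                    continue
                r = w.result
                grp.attrs["r1"], grp.attrs["r2"] = r.r1, r.r2
                for name, arr in (
                    ("eigenvalues", r.eigenvalues),
                    ("modes", r.modes),
                    ("amplitudes", r.amplitudes),
                ):
                    grp.create_dataset(f"{name}_re", data=np.real(arr))
                    grp.create_dataset(f"{name}_im", data=np.imag(arr))


def eigenvalue_summary(
    windows_by_segment: Dict[str, Sequence[WindowDecomposition]]
) -> pd.DataFrame:
    """Long-format eigenvalue table across segments, windows and modes."""
    rows = []
    for seg_id, windows in windows_by_segment.items():
        for k, w in enumerate(windows):
            if w.result is None:
                continue
            r = w.result
            for j in range(r.n_modes):
                rows.append(
                    {
                        "segment_id": seg_id,
                        "window": k,
                        "mode": j,
                        "lambda_re": r.eigenvalues[j].real,
                        "lambda_im": r.eigenvalues[j].imag,
                        "freq_hz": r.frequencies_hz[j],
                        "growth_per_s": r.growth_per_s[j],
                        "amp_abs": abs(r.amplitudes[j]),
                        "vaf": w.mode_vaf[j],
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# features, metrics, config
# ---------------------------------------------------------------------------


def write_feature_csv(table: pd.DataFrame, path) -> None:
    """Feature table CSV: first column segment_id, last column label."""
    cols = [c for c in table.columns if c != "label"] + ["label"]
    table[cols].to_csv(path, index=True, float_format=_CSV_FLOAT)


def read_feature_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path).set_index("segment_id")
    if "label" not in table.columns:
        raise ValidationError(f"{path}: feature CSV lacks a label column")
    return table


def write_metrics_json(reports, summary: pd.DataFrame, path) -> None:
    payload = {
        "folds": [r.to_dict() for r in reports],
        "summary": {
            metric: {"mean": float(row["mean"]), "sd": float(row["sd"])}
            for metric, row in summary.iterrows()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_curves_csv(reports, roc_path, pr_path) -> None:
    roc = pd.concat(
        [r.roc.assign(fold=i) for i, r in enumerate(reports)], ignore_index=True
    )
    pr = pd.concat(
        [r.pr.assign(fold=i) for i, r in enumerate(reports)], ignore_index=True
    )
    roc.to_csv(roc_path, index=False, float_format=_CSV_FLOAT)
    pr.to_csv(pr_path, index=False, float_format=_CSV_FLOAT)


def write_coefficients_csv(odds_table: pd.DataFrame, path) -> None:
    odds_table.to_csv(path, index=True, float_format=_CSV_FLOAT)


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a YAML mapping")
    return data


def dump_yaml(data: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
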