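"""Delimited-text readers and writers for every pipeline artifact.

Dialect: comma-separated, UTF-8, '.' decimal, mandatory header row. Units are
embedded in column names (``position_um``, ``soma_area_um2``). Each writer
has a paired reader that round-trips its content (floats to 1e-9).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import FOVRecording, Shaft, SpineSession
from .errors import DataError, FormatError

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# trace tables: one file per FOV, first column = frame, header = ROI ids
# ---------------------------------------------------------------------------

def write_traces(rec: FOVRecording, path) -> None:
    df = pd.DataFrame(
        rec.fluorescence,
        columns=[f"roi{j}" for j in range(rec.n_rois)],
    )
    df.insert(0, "frame", np.arange(rec.n_frames))
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    meta = {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "fov_id": rec.fov_id,
        "animal_id": rec.animal_id,
        "group": rec.group,
        "roi_labels": list(rec.roi_labels),
    }
    Path(path).with_suffix(".meta.json").write_text(
        json.dumps(meta, indent=1))


def read_traces(path) -> FOVRecording:
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns[0] != "frame":
        raise FormatError(f"{path.name}: first column must be 'frame'")
    meta_path = path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise FormatError(f"missing metadata file {meta_path.name}")
    meta = json.loads(meta_path.read_text())
    return FOVRecording(
        fluorescence=df.iloc[:, 1:].to_numpy(dtype=float),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        roi_labels=tuple(meta["roi_labels"]),
        fov_id=meta["fov_id"],
        animal_id=meta["animal_id"],
        group=meta["group"],
    )


# ---------------------------------------------------------------------------
# spine tables: session, shaft_id, shaft_length_um, spine_id, position_um
# ---------------------------------------------------------------------------

def write_spines(sessions: list[SpineSession], path) -> None:
    rows = []
    for sess in sessions:
        for shaft in sess.shafts:
            if shaft.n_spines == 0:
                rows.append({
                    "session": sess.session_index, "shaft_id": shaft.shaft_id,
                    "shaft_length_um": shaft.shaft_length_um,
                    "spine_id": "", "position_um": np.nan,
                    "animal_id": sess.animal_id, "group": sess.group,
                })
            for i, p in enumerate(shaft.positions_um):
                rows.append({
                    "session": sess.session_index, "shaft_id": shaft.shaft_id,
                    "shaft_length_um": shaft.shaft_length_um,
                    "spine_id": f"{shaft.shaft_id}_s{sess.session_index}_{i}",
                    "position_um": float(p),
                    "animal_id": sess.animal_id, "group": sess.group,
                })
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_spines(path) -> list[SpineSession]:
    df = pd.read_csv(Path(path))
    required = {"session", "shaft_id", "shaft_length_um", "position_um"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"spine table missing columns {sorted(missing)}")
    sessions = []
    for sidx, sub in df.groupby("session", sort=True):
        shafts = []
        for shaft_id, ssub in sub.groupby("shaft_id", sort=True):
            pos = ssub["position_um"].dropna().to_numpy(dtype=float)
            shafts.append(Shaft(str(shaft_id),
                                float(ssub["shaft_length_um"].iloc[0]), pos))
        animal = str(sub["animal_id"].iloc[0]) if "animal_id" in sub else "animal0"
        group = str(sub["group"].iloc[0]) if "group" in sub else ""
        if group == "nan":
            group = ""
        sessions.append(SpineSession(shafts, int(sidx), animal, group))
    return sessions


# ---------------------------------------------------------------------------
# tidy tables, correlation matrices, reports
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_corr_matrix(corr: np.ndarray, path) -> None:
    n = corr.shape[0]
    ids = [f"roi{j}" for j in range(n)]
    df = pd.DataFrame(corr, columns=ids)
    df.insert(0, "roi_id", ids)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_corr_matrix(path) -> np.ndarray:
    df = pd.read_csv(Path(path))
    if df.columns[0] != "roi_id":
        raise FormatError("correlation matrix must start with 'roi_id'")
    return df.iloc[:, 1:].to_numpy(dtype=float)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_jsonify))
    # trailing newline keeps the file friendly to text tools
    with open(path, "a") as fh:
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def tidy_from_measurements(measurements: pd.DataFrame,
                           measure: str) -> pd.DataFrame:
    """Extract one endpoint from the study measurement table as a tidy
    (unit_id, group, value) frame."""
    sub = measurements[measurements["measure"] == measure]
    if sub.empty:
        raise DataError(f"no rows for measure {measure!r}")
    return sub[["unit_id", "group", "value"]].reset_index(drop=True)
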