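"""Calcium-trace metrics: dF/Fmin normalization, transient detection,
integrated calcium, and FOV synchrony.

The activity unit throughout is dF/Fmin: the fluorescence change relative to
the minimum reading of the whole recording, Fmin = min_t F(t), so
dff(t) = (F(t) - Fmin) / Fmin. A calcium transient is a maximal run of
consecutive frames whose dF/Fmin exceeds ``threshold_multiple`` times the
baseline level; the baseline level is estimated from the trace itself (the
scaled median absolute deviation by default, see :func:`baseline_level`).
Total integrated calcium is the sum of dF/Fmin over *all* frames of the
recording, not only frames inside transients.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    CalciumTransient,
    DffTrace,
    FOVRecording,
    FOVSynchrony,
)
from .errors import DataError, DegenerateBaselineError, InsufficientDataError

logger = logging.getLogger(__name__)

#: floor for the baseline-level estimate so the threshold is never exactly 0
BASELINE_EPS = 1e-6


def normalize_trace(raw: np.ndarray) -> DffTrace:
    """Convert a raw fluorescence vector to dF/Fmin.

    Parameters
    ----------
    raw : 1-D array
        Raw fluorescence readings; must be finite with min(raw) > 0.

    Returns
    -------
    DffTrace
        dff(t) = (raw(t) - Fmin) / Fmin with Fmin the minimum over all
        frames; dff is 0 exactly at the arg-min frame and >= 0 everywhere.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise DataError("trace must be a 1-D vector with >= 2 frames")
    if not np.all(np.isfinite(raw)):
        raise DataError("trace contains NaN or infinite values")
    fmin = float(raw.min())
    if fmin <= 0:
        raise DegenerateBaselineError(
            f"min(raw) = {fmin}; dF/Fmin requires a positive minimum"
        )
    return DffTrace(dff=(raw - fmin) / fmin, fmin=fmin)


def baseline_level(
    dff: np.ndarray, method: str = "mad", eps: float = BASELINE_EPS
) -> float:
    """Estimate the baseline level of a dF/Fmin trace.

    ``"mad"`` (default) returns 1.4826 x median absolute deviation — a robust
    noise scale that ignores sparse events. ``"submedian_mean"`` returns the
    mean of the frames at or below the trace median, an alternative reading of
    "baseline" as the resting dF/F level. Both are floored at ``eps`` so the
    detection threshold is strictly positive on constant traces.
    """
    dff = np.asarray(dff, dtype=float)
    if method == "mad":
        med = np.median(dff)
        b = 1.4826 * float(np.median(np.abs(dff - med)))
    elif method == "submedian_mean":
        med = np.median(dff)
        b = float(dff[dff <= med].mean())
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return max(b, eps)


def detect_transients(
    trace: DffTrace,
    threshold_multiple: float = 3.0,
    min_duration_frames: int = 1,
    baseline_method: str = "mad",
    roi_id: str = "roi0",
) -> list[CalciumTransient]:
    """Detect calcium transients as maximal supra-threshold runs.

    A frame is active when dff > threshold_multiple x baseline level; a
    transient is a maximal run of >= ``min_duration_frames`` consecutive
    active frames. Transients are returned in time order and never overlap.
    A constant trace yields an empty list.
    """
    if threshold_multiple <= 0:
        raise ValueError("threshold_multiple must be > 0")
    if min_duration_frames < 1:
        raise ValueError("min_duration_frames must be >= 1")
    dff = np.asarray(trace.dff, dtype=float)
    thr = threshold_multiple * baseline_level(dff, method=baseline_method)
    active = dff > thr
    if not active.any():
        return []
    # run-length encode the active mask
    starts = np.flatnonzero(active & ~np.r_[False, active[:-1]])
    ends = np.flatnonzero(active & ~np.r_[active[1:], False])
    out: list[CalciumTransient] = []
    for s, e in zip(starts, ends):
        if e - s + 1 < min_duration_frames:
            continue
        seg = dff[s : e + 1]
        out.append(
            CalciumTransient(
                roi_id=roi_id,
                start_frame=int(s),
                end_frame=int(e),
                peak_dff=float(seg.max()),
                integral_dff=float(seg.sum()),
            )
        )
    return out


def integrated_calcium(trace: DffTrace) -> float:
    """Total integrated calcium: the sum of dF/Fmin over all frames."""
    return float(np.asarray(trace.dff, dtype=float).sum())


def fov_synchrony(
    recording: FOVRecording, fisher_z: bool = False
) -> FOVSynchrony:
    """Pairwise Pearson correlation of dF/Fmin traces within one FOV.

    ``mean_corr`` averages the C(n,2) upper-triangle entries. Pairs involving
    a constant trace have undefined correlation; they are excluded from the
    mean and counted in ``n_excluded_pairs``. With ``fisher_z`` the average is
    taken on the Fisher-z scale and transformed back.
    """
    if recording.n_rois < 2:
        raise InsufficientDataError("synchrony needs >= 2 ROIs")
    dffs = np.column_stack(
        [normalize_trace(recording.fluorescence[:, j]).dff
         for j in range(recording.n_rois)]
    )
    sd = dffs.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(dffs, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, np.where(constant, np.nan, 1.0))
    iu = np.triu_indices(recording.n_rois, k=1)
    upper = corr[iu]
    valid = np.isfinite(upper)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning(
            "FOV %s: %d constant-trace pairs excluded from mean correlation",
            recording.fov_id, n_excluded,
        )
    if valid.any():
        vals = upper[valid]
        if fisher_z:
            z = np.arctanh(np.clip(vals, -1 + 1e-12, 1 - 1e-12))
            mean_corr = float(np.tanh(z.mean()))
        else:
            mean_corr = float(vals.mean())
    else:
        mean_corr = float("nan")
    return FOVSynchrony(corr_matrix=corr, mean_corr=mean_corr,
                        n_excluded_pairs=n_excluded)


def summarize_fov(
    recording: FOVRecording,
    threshold_multiple: float = 3.0,
    min_duration_frames: int = 1,
    baseline_method: str = "mad",
) -> tuple[pd.DataFrame, pd.DataFrame, FOVSynchrony]:
    """Per-ROI calcium metrics plus FOV synchrony.

    Returns
    -------
    roi_table : DataFrame
        One row per ROI: identifiers, compartment, integrated calcium,
        transient count, and mean/max transient peak.
    transient_table : DataFrame
        One row per detected transient with frame and second timings.
    synchrony : FOVSynchrony
    """
    fs = recording.sampling_rate_hz
    roi_rows, tr_rows = [], []
    for j in range(recording.n_rois):
        roi_id = f"roi{j}"
        trace = normalize_trace(recording.fluorescence[:, j])
        transients = detect_transients(
            trace, threshold_multiple, min_duration_frames,
            baseline_method=baseline_method, roi_id=roi_id,
        )
        peaks = [t.peak_dff for t in transients]
        roi_rows.append({
            "fov_id": recording.fov_id,
            "animal_id": recording.animal_id,
            "group": recording.group,
            "roi_id": roi_id,
            "compartment": recording.roi_labels[j],
            "integrated_dff": integrated_calcium(trace),
            "n_transients": len(transients),
            "mean_peak_dff": float(np.mean(peaks)) if peaks else 0.0,
            "max_peak_dff": float(np.max(peaks)) if peaks else 0.0,
        })
        for t in transients:
            tr_rows.append({
                "fov_id": recording.fov_id,
                "roi_id": roi_id,
                "compartment": recording.roi_labels[j],
                "start_frame": t.start_frame,
                "end_frame": t.end_frame,
                "start_s": t.start_frame / fs,
                "end_s": t.end_frame / fs,
                "peak_dff": t.peak_dff,
                "integral_dff": t.integral_dff,
            })
    roi_table = pd.DataFrame(roi_rows)
    transient_table = pd.DataFrame(
        tr_rows,
        columns=["fov_id", "roi_id", "compartment", "start_frame", "end_frame",
                 "start_s", "end_s", "peak_dff", "integral_dff"],
    )
    synchrony = fov_synchrony(recording) if recording.n_rois >= 2 else None
    return roi_table, transient_table, synchrony
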