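"""Core data containers shared by the analysis stages.

Conventions used throughout the package: lengths and positions in micrometres,
time in frames (with seconds derived from the sampling rate), fluorescence in
arbitrary units, dF/Fmin dimensionless. Frame indexing is 0-based and frame
intervals are inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, GeometryError

COMPARTMENTS = ("soma", "process")


@dataclass
class FOVRecording:
    """One field of view: raw fluorescence traces for simultaneously imaged ROIs.

    Parameters
    ----------
    fluorescence : (n_frames, n_rois) array
        Raw fluorescence, arbitrary units. Must be finite.
    sampling_rate_hz : float
        Acquisition rate in frames per second.
    roi_labels : sequence of str
        Per-ROI compartment tag, each ``"soma"`` or ``"process"``.
    fov_id, animal_id, group : str
        Identifiers carried through to summary tables.
    """

    fluorescence: np.ndarray
    sampling_rate_hz: float
    roi_labels: tuple[str, ...]
    fov_id: str = "fov0"
    animal_id: str = "animal0"
    group: str = ""

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 2:
            raise DataError("fluorescence must be a frames x ROIs matrix")
        if self.fluorescence.shape[0] < 2:
            raise DataError("a recording needs at least 2 frames")
        if not np.all(np.isfinite(self.fluorescence)):
            raise DataError("fluorescence contains non-finite values")
        self.roi_labels = tuple(self.roi_labels)
        if len(self.roi_labels) != self.fluorescence.shape[1]:
            raise DataError("one compartment label required per ROI")
        bad = set(self.roi_labels) - set(COMPARTMENTS)
        if bad:
            raise DataError(f"unknown compartment labels: {sorted(bad)}")
        if self.sampling_rate_hz <= 0:
            raise DataError("sampling_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_rois(self) -> int:
        return self.fluorescence.shape[1]


@dataclass
class DffTrace:
    """A dF/Fmin trace for one ROI, plus the Fmin it was normalized by."""

    dff: np.ndarray
    fmin: float

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)


@dataclass
class CalciumTransient:
    """One detected calcium event on one ROI.

    ``start_frame``/``end_frame`` are inclusive 0-based indices of the maximal
    supra-threshold run; ``peak_dff`` its maximum dF/Fmin and ``integral_dff``
    the sum of dF/Fmin over the run's frames.
    """

    roi_id: str
    start_frame: int
    end_frame: int
    peak_dff: float
    integral_dff: float

    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_s(self, sampling_rate_hz: float) -> float:
        return self.duration_frames() / sampling_rate_hz


@dataclass
class FOVSynchrony:
    """Pairwise Pearson correlations of dF/Fmin traces within one FOV.

    ``mean_corr`` averages the upper-triangle off-diagonal entries; pairs
    involving a constant trace are undefined (NaN in the matrix) and excluded,
    with ``n_excluded_pairs`` recording how many were dropped.
    """

    corr_matrix: np.ndarray
    mean_corr: float
    n_excluded_pairs: int = 0


@dataclass
class Shaft:
    """One dendritic shaft: arc-length positions of its spines in micrometres."""

    shaft_id: str
    shaft_length_um: float
    positions_um: np.ndarray

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.shaft_length_um <= 0:
            raise DataError(f"shaft {self.shaft_id}: length must be > 0")
        if self.positions_um.size and (
            self.positions_um.min() < 0
            or self.positions_um.max() > self.shaft_length_um
        ):
            raise DataError(
                f"shaft {self.shaft_id}: spine positions must lie in "
                f"[0, {self.shaft_length_um}]"
            )
        if self.positions_um.size > 1:
            diffs = np.diff(np.sort(self.positions_um))
            if np.any(diffs < 1e-6):
                raise DataError(
                    f"shaft {self.shaft_id}: spine positions not unique within 1e-6 um"
                )

    @property
    def n_spines(self) -> int:
        return int(self.positions_um.size)


@dataclass
class SpineSession:
    """Spine annotations for one imaging session of one animal."""

    shafts: list[Shaft]
    session_index: int = 1
    animal_id: str = "animal0"
    group: str = ""

    def shaft_ids(self) -> list[str]:
        return [s.shaft_id for s in self.shafts]

    def total_spines(self) -> int:
        return sum(s.n_spines for s in self.shafts)

    def total_length_um(self) -> float:
        return float(sum(s.shaft_length_um for s in self.shafts))


@dataclass
class SpinePair:
    """A matched (session-1, session-2) spine pair on one shaft."""

    shaft_id: str
    s1_index: int
    s2_index: int
    distance_um: float


@dataclass
class SpineMatch:
    """One-to-one cross-session spine assignment with fate labels.

    Unmatched session-1 spines are eliminated; unmatched session-2 spines are
    new. The partition identities |pairs| + |unmatched_s1| = N1 and
    |pairs| + |unmatched_s2| = N2 hold by construction.
    """

    pairs: list[SpinePair]
    unmatched_s1: list[tuple[str, int]]
    unmatched_s2: list[tuple[str, int]]
    tolerance_um: float = 1.0

    @property
    def n_stable(self) -> int:
        return len(self.pairs)

    @property
    def n_eliminated(self) -> int:
        return len(self.unmatched_s1)

    @property
    def n_new(self) -> int:
        return len(self.unmatched_s2)


@dataclass
class TurnoverSummary:
    """Spine density and turnover percentages for a matched session pair."""

    density_s1: float
    density_s2: float
    formation_pct: float
    elimination_pct: float
    turnover_pct: float
    n_s1: int = 0
    n_s2: int = 0


@dataclass
class MorphTree:
    """An SWC-style rooted tree plus a soma contour polygon.

    ``nodes`` arrays are index-aligned; ``parent_index[i]`` is -1 for the root
    and otherwise the array index of node i's parent. Coordinates in
    micrometres.
    """

    node_ids: np.ndarray
    node_types: np.ndarray
    xyz: np.ndarray
    radii: np.ndarray
    parent_index: np.ndarray
    soma_contour: np.ndarray
    cell_id: str = "cell0"
    group: str = ""

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.node_types = np.asarray(self.node_types, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.parent_index = np.asarray(self.parent_index, dtype=int)
        self.soma_contour = np.asarray(self.soma_contour, dtype=float)
        n = self.node_ids.size
        if self.xyz.shape != (n, 3):
            raise DataError("xyz must be (n_nodes, 3)")
        roots = np.flatnonzero(self.parent_index == -1)
        if roots.size != 1:
            raise DataError(f"tree must have exactly one root, found {roots.size}")
        if self.soma_contour.ndim != 2 or self.soma_contour.shape[0] < 3:
            raise GeometryError("soma contour needs >= 3 vertices")
        # cycle check: walking up from every node must reach the root
        for i in range(n):
            seen, j = set(), i
            while j != -1:
                if j in seen:
                    raise DataError("tree contains a cycle")
                seen.add(j)
                j = int(self.parent_index[j])

    @property
    def n_nodes(self) -> int:
        return int(self.node_ids.size)

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parent_index == -1)[0])

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (starts, ends) arrays of all parent->child segments."""
        child = np.flatnonzero(self.parent_index >= 0)
        return self.xyz[self.parent_index[child]], self.xyz[child]


@dataclass
class ShollProfile:
    """Sholl crossings and per-annulus process length around the soma centroid.

    ``radii`` are the circle radii (strictly increasing); ``intersections[i]``
    counts segments crossing circle i; ``annulus_length_um[i]`` is the process
    length with centroid distance in [r_{i-1}, r_i), where r_0 = 0.
    """

    radii_um: np.ndarray
    intersections: np.ndarray
    annulus_length_um: np.ndarray
    length_beyond_um: float = 0.0


@dataclass
class GroupComparisonResult:
    """Outcome of one omnibus group comparison plus optional post-hoc table."""

    test_name: str
    statistic: float
    df: tuple
    p_value: float
    posthoc: list[dict] = field(default_factory=list)
    normality_decision: dict | None = None
    notes: list[str] = field(default_factory=list)
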