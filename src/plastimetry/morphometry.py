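"""Astrocyte morphometry: SWC I/O, soma area, Sholl profiles, total process
length and branch count.

Sholl analysis is computed in the tree's native 3-D space around the soma
centroid (the arithmetic mean of the soma-contour vertices, at the root
node's z). For each circle radius r the intersection count is the number of
tree segments with one endpoint at centroid distance <= r and the other > r
("inside" includes the circle itself, so a segment ending exactly on a circle
does not cross it). Segments longer than half the radius step are recursively
bisected first so a single long segment cannot silently cross several
circles. Annulus lengths are exact segment-sphere clippings over the
half-open annuli [r_{i-1}, r_i) with r_0 = 0.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

from .datatypes import MorphTree, ShollProfile
from .errors import FormatError, GeometryError, ParameterError


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path, soma_contour=None, cell_id=None, group="") -> MorphTree:
    """Read a standard 7-column SWC file into a :class:`MorphTree`.

    Two-pass parse, so forward parent references are accepted. '#' comment
    lines and blank lines are ignored. ``soma_contour`` may be an (n, 2)
    array or a path to a contour CSV written by :func:`write_contour`; if
    omitted, a small triangle around the root is substituted so purely
    topological uses still validate.
    """
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 7:
            raise FormatError(
                f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}"
            )
        try:
            rows.append((int(parts[0]), int(parts[1]),
                         float(parts[2]), float(parts[3]), float(parts[4]),
                         float(parts[5]), int(parts[6]), lineno))
        except ValueError as exc:
            raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
    if not rows:
        raise FormatError(f"{path.name}: no nodes")
    id_to_index = {r[0]: i for i, r in enumerate(rows)}
    parent_index = np.empty(len(rows), dtype=int)
    for i, r in enumerate(rows):
        pid, lineno = r[6], r[7]
        if pid == -1:
            parent_index[i] = -1
        elif pid in id_to_index:
            parent_index[i] = id_to_index[pid]
        else:
            raise FormatError(
                f"{path.name}:{lineno}: parent id {pid} does not exist"
            )
    n_roots = int((parent_index == -1).sum())
    if n_roots != 1:
        raise FormatError(f"{path.name}: expected exactly 1 root, found {n_roots}")
    xyz = np.array([[r[2], r[3], r[4]] for r in rows])
    if soma_contour is None:
        root = xyz[int(np.flatnonzero(parent_index == -1)[0])] \
            if (parent_index == -1).any() else xyz[0]
        soma_contour = root[:2] + np.array([[1.0, 0], [-0.5, 0.87], [-0.5, -0.87]])
    elif isinstance(soma_contour, (str, Path)):
        soma_contour = read_contour(soma_contour)
    return MorphTree(
        node_ids=np.array([r[0] for r in rows]),
        node_types=np.array([r[1] for r in rows]),
        xyz=xyz,
        radii=np.array([r[5] for r in rows]),
        parent_index=parent_index,
        soma_contour=np.asarray(soma_contour, dtype=float),
        cell_id=cell_id or path.stem,
        group=group,
    )


def write_swc(tree: MorphTree, path) -> None:
    """Write a :class:`MorphTree` as 7-column SWC, preserving node order."""
    lines = ["# id type x y z radius parent"]
    for i in range(tree.n_nodes):
        pid = -1 if tree.parent_index[i] == -1 \
            else int(tree.node_ids[tree.parent_index[i]])
        x, y, z = tree.xyz[i]
        lines.append(
            f"{int(tree.node_ids[i])} {int(tree.node_types[i])} "
            f"{x:.4f} {y:.4f} {z:.4f} {tree.radii[i]:.4f} {pid}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_contour(contour: np.ndarray, path) -> None:
    """Write a soma contour polygon as a two-column CSV (x_um, y_um)."""
    contour = np.asarray(contour, dtype=float)
    lines = ["x_um,y_um"] + [f"{x:.6f},{y:.6f}" for x, y in contour]
    Path(path).write_text("\n".join(lines) + "\n")


def read_contour(path) -> np.ndarray:
    text = Path(path).read_text().splitlines()
    return np.array([[float(v) for v in line.split(",")] for line in text[1:]])


# ---------------------------------------------------------------------------
# scalar morphometrics
# ---------------------------------------------------------------------------

def soma_area(contour: np.ndarray) -> float:
    """Area of the soma contour polygon in square micrometres.

    Shoelace area via shapely, orientation-independent; self-intersecting
    contours are rejected.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[0] < 3:
        raise GeometryError("contour needs >= 3 vertices")
    poly = Polygon(contour)
    if not poly.is_simple or poly.area == 0:
        raise GeometryError("soma contour is self-intersecting or degenerate")
    return float(poly.area)


def total_length(tree: MorphTree) -> float:
    """Total process length: sum of Euclidean parent-child distances (um)."""
    starts, ends = tree.segments()
    if starts.size == 0:
        return 0.0
    return float(np.linalg.norm(ends - starts, axis=1).sum())


def branch_count(tree: MorphTree) -> int:
    """Number of unbranched segments (maximal paths between the root,
    bifurcations, and terminals)."""
    n = tree.n_nodes
    outdeg = np.zeros(n, dtype=int)
    for i in range(n):
        p = tree.parent_index[i]
        if p >= 0:
            outdeg[p] += 1
    count = 0
    for i in range(n):
        if tree.parent_index[i] == -1 or outdeg[i] >= 2:
            count += outdeg[i]
    return count


def soma_centroid(tree: MorphTree) -> np.ndarray:
    """Sholl centre: mean of the contour vertices (x, y) at the root's z."""
    cx, cy = tree.soma_contour.mean(axis=0)
    return np.array([cx, cy, tree.xyz[tree.root_index][2]])


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------

def _subdivide(starts: np.ndarray, ends: np.ndarray, max_len: float):
    """Recursively bisect segments until none exceeds ``max_len``."""
    out_s, out_e = [], []
    stack = list(zip(starts, ends))
    while stack:
        a, b = stack.pop()
        if np.linalg.norm(b - a) > max_len:
            m = (a + b) / 2.0
            stack.append((a, m))
            stack.append((m, b))
        else:
            out_s.append(a)
            out_e.append(b)
    return np.array(out_s), np.array(out_e)


def _sphere_crossings(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                      r: float) -> list[float]:
    """Parameters t in (0, 1) where |a + t(b-a) - c| = r."""
    d = b - a
    f = a - c
    A = float(d @ d)
    if A == 0:
        return []
    B = 2.0 * float(f @ d)
    C = float(f @ f) - r * r
    disc = B * B - 4 * A * C
    if disc <= 0:
        return []
    sq = math.sqrt(disc)
    return [t for t in ((-B - sq) / (2 * A), (-B + sq) / (2 * A))
            if 0.0 < t < 1.0]


def _segment_annulus_lengths(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                             edges: np.ndarray) -> np.ndarray:
    """Exact length of segment [a, b] inside each annulus [edges[i], edges[i+1]).

    The final annulus edge may be inf (length beyond the largest circle).
    Splits [0, 1] at every sphere crossing and bins each sub-interval by the
    distance at its midpoint.
    """
    ts = [0.0, 1.0]
    finite_edges = edges[1:-1] if np.isinf(edges[-1]) else edges[1:]
    for r in finite_edges:
        ts.extend(_sphere_crossings(a, b, c, float(r)))
    ts = sorted(set(ts))
    seg_len = float(np.linalg.norm(b - a))
    out = np.zeros(len(edges) - 1)
    for t0, t1 in zip(ts[:-1], ts[1:]):
        mid = a + ((t0 + t1) / 2.0) * (b - a)
        d = float(np.linalg.norm(mid - c))
        idx = int(np.searchsorted(edges, d, side="right")) - 1
        if 0 <= idx < len(out):
            out[idx] += (t1 - t0) * seg_len
    return out


def sholl(
    tree: MorphTree,
    r_start: float = 5.0,
    r_step: float = 5.0,
    r_max: float | None = None,
) -> ShollProfile:
    """Sholl intersections and per-annulus process length.

    Parameters
    ----------
    r_start, r_step : float
        First circle radius and the spacing between circles (um).
    r_max : float, optional
        Largest circle radius; defaults to the smallest multiple of
        ``r_step`` at or beyond ``r_start`` that encloses the whole tree.

    Returns
    -------
    ShollProfile
        Radii, crossing counts, annulus lengths over [r_{i-1}, r_i) with
        r_0 = 0, and the process length beyond the largest circle.
    """
    if r_step <= 0:
        raise ParameterError("r_step must be > 0")
    if r_start < 0:
        raise ParameterError("r_start must be >= 0")
    c = soma_centroid(tree)
    starts, ends = tree.segments()
    if starts.size == 0:
        radii = np.array([r_start]) if r_max is None else \
            np.arange(r_start, r_max + 0.5 * r_step, r_step)
        z = np.zeros(len(radii))
        return ShollProfile(radii, z.astype(int), z.copy(), 0.0)
    dists = np.maximum(np.linalg.norm(starts - c, axis=1),
                       np.linalg.norm(ends - c, axis=1))
    tree_extent = float(dists.max())
    if r_max is None:
        r_max = max(r_start, r_step * math.ceil(tree_extent / r_step))
    if r_max < r_start:
        raise ParameterError("r_max must be >= r_start")
    radii = np.arange(r_start, r_max + 0.5 * r_step, r_step)

    starts, ends = _subdivide(starts, ends, max_len=r_step / 2.0)
    da = np.linalg.norm(starts - c, axis=1)
    db = np.linalg.norm(ends - c, axis=1)
    intersections = np.array(
        [int(np.sum(((da <= r) & (db > r)) | ((db <= r) & (da > r))))
         for r in radii]
    )
    edges = np.concatenate([[0.0], radii, [np.inf]])
    lengths = np.zeros(len(edges) - 1)
    for a, b in zip(starts, ends):
        lengths += _segment_annulus_lengths(a, b, c, edges)
    return ShollProfile(
        radii_um=radii,
        intersections=intersections,
        annulus_length_um=lengths[:-1],
        length_beyond_um=float(lengths[-1]),
    )
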