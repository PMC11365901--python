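"""Synthetic-data generators with known ground truth.

Every pipeline input — fluorescence recordings, two-session spine
annotations, astrocyte morphologies, and a three-group study design — can be
simulated with configurable group effects, so each analysis stage is testable
against the generator's own ground truth without any external data.

Fluorescence model
------------------
Each ROI receives a Poisson train of calcium events. An event contributes
``amplitude x k(t - t_event)`` to the true dF/F, where k is a
difference-of-exponentials kernel normalized to unit peak, so the event
amplitude *is* the true peak dF/F. Raw fluorescence is
``baseline_f0 * (1 + dff_true) + Gaussian noise``; the noise is redrawn if
any frame falls to or below zero so dF/Fmin stays defined. FOV synchrony is
produced by a single shared population event train: each cell event is drawn
from the shared train with probability ``sync_prob`` and is otherwise
private, which maps ``sync_prob`` monotonically onto mean pairwise
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .datatypes import FOVRecording, MorphTree, Shaft, SpineSession
from .errors import ConfigurationError, ParameterError

GROUPS_DEFAULT = ("Saline", "Alcohol", "Alcohol+Ex")


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceSimParams:
    """Parameters of the fluorescence-trace simulator.

    ``tau_decay_s`` defaults to a slow-indicator stand-in (1.8 s, neurons);
    use 0.4 s as a fast-indicator stand-in for astrocytes. ``sync_prob`` is
    the probability that a cell event comes from the shared population train.
    ``min_event_interval_s`` > 0 thins each ROI's train to a minimum
    inter-event gap (deterministically, keeping earlier events), giving
    well-separated events when an analysis needs them; 0 disables thinning.
    """

    n_rois: int = 30
    n_frames: int = 600
    sampling_rate_hz: float = 2.0
    event_rate_per_min: float = 2.0
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.3
    tau_rise_s: float = 0.1
    tau_decay_s: float = 1.8
    sync_prob: float = 0.3
    baseline_f0: float = 100.0
    noise_sd: float = 1.0
    min_event_interval_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_rois >= 1, "n_rois >= 1 violated")
        _check(self.n_frames >= 1, "n_frames >= 1 violated")
        _check(self.sampling_rate_hz > 0, "sampling_rate_hz > 0 violated")
        _check(0 <= self.sync_prob <= 1, "0 <= sync_prob <= 1 violated")
        _check(self.baseline_f0 > 0, "baseline_f0 > 0 violated")
        _check(self.tau_decay_s > self.tau_rise_s > 0,
               "tau_decay_s > tau_rise_s > 0 violated")
        _check(self.event_rate_per_min >= 0, "event_rate_per_min >= 0 violated")
        _check(self.noise_sd >= 0, "noise_sd >= 0 violated")
        _check(self.min_event_interval_s >= 0,
               "min_event_interval_s >= 0 violated")


@dataclass(frozen=True)
class SpineSimParams:
    """Parameters of the two-session spine simulator."""

    n_shafts: int = 10
    shaft_length_um: float = 20.0
    spines_per_shaft_mean: float = 11.0
    survival_prob: float = 0.85
    birth_rate_per_um: float = 0.08
    position_jitter_um: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_shafts >= 1, "n_shafts >= 1 violated")
        _check(self.shaft_length_um > 0, "shaft_length_um > 0 violated")
        _check(0 <= self.survival_prob <= 1, "0 <= survival_prob <= 1 violated")
        _check(self.birth_rate_per_um >= 0, "birth_rate_per_um >= 0 violated")
        _check(self.position_jitter_um >= 0, "position_jitter_um >= 0 violated")


@dataclass(frozen=True)
class MorphSimParams:
    """Parameters of the astrocyte-tree simulator."""

    n_primary_processes: int = 6
    branch_prob: float = 0.3
    segment_length_mean_um: float = 4.0
    max_depth: int = 4
    soma_radius_um: float = 5.0
    steps_per_chain: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_primary_processes >= 1, "n_primary_processes >= 1 violated")
        _check(0 <= self.branch_prob <= 1, "0 <= branch_prob <= 1 violated")
        _check(self.max_depth >= 1, "max_depth >= 1 violated")
        _check(self.soma_radius_um > 0, "soma_radius_um > 0 violated")
        _check(self.segment_length_mean_um > 0,
               "segment_length_mean_um > 0 violated")
        _check(self.steps_per_chain >= 1, "steps_per_chain >= 1 violated")


@dataclass
class GroundTruth:
    """Ground truth emitted alongside each simulated object."""

    event_table: pd.DataFrame | None = None
    spine_labels: pd.DataFrame | None = None
    tree_total_length_um: float | None = None
    tree_branch_count: int | None = None


# ---------------------------------------------------------------------------
# fluorescence traces
# ---------------------------------------------------------------------------

def event_kernel(t_s: np.ndarray, tau_rise_s: float,
                 tau_decay_s: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak (causal)."""
    t_s = np.asarray(t_s, dtype=float)
    t_peak = (tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)
              * np.log(tau_decay_s / tau_rise_s))
    peak = np.exp(-t_peak / tau_decay_s) - np.exp(-t_peak / tau_rise_s)
    k = np.where(
        t_s >= 0,
        np.exp(-np.maximum(t_s, 0) / tau_decay_s)
        - np.exp(-np.maximum(t_s, 0) / tau_rise_s),
        0.0,
    )
    return k / peak


def _thin_events(times: np.ndarray, amps: np.ndarray, origin: np.ndarray,
                 min_gap_s: float):
    """Enforce a minimum inter-event gap, keeping earlier events."""
    if min_gap_s <= 0 or times.size == 0:
        return times, amps, origin
    order = np.argsort(times)
    keep, last = [], -np.inf
    for idx in order:
        if times[idx] - last >= min_gap_s:
            keep.append(idx)
            last = times[idx]
    keep = np.array(keep, dtype=int)
    return times[keep], amps[keep], origin[keep]


def simulate_fov(params: TraceSimParams,
                 fov_id: str = "fov0", animal_id: str = "animal0",
                 group: str = "", roi_labels=None
                 ) -> tuple[FOVRecording, GroundTruth]:
    """Simulate one FOV of raw fluorescence traces with ground-truth events.

    Returns the recording and a ground-truth table with one row per kept
    event: roi, time (s and frames), true peak amplitude, and whether the
    event came from the shared population train.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate_hz
    duration_s = params.n_frames / fs
    t_frames = np.arange(params.n_frames) / fs
    lam = params.event_rate_per_min * duration_s / 60.0

    # shared population train for the whole FOV
    n_shared = rng.poisson(lam)
    shared_times = np.sort(rng.uniform(0, duration_s, n_shared))

    # lognormal parameterized so amplitude_mean/sd are the arithmetic moments
    mu, sd = params.amplitude_mean, params.amplitude_sd
    if mu > 0:
        sigma2 = np.log1p((sd / mu) ** 2)
        ln_mu, ln_sigma = np.log(mu) - sigma2 / 2, np.sqrt(sigma2)
    else:
        ln_mu, ln_sigma = 0.0, 0.0
    if n_shared:
        shared_amps = rng.lognormal(ln_mu, ln_sigma, n_shared) if mu > 0 \
            else np.zeros(n_shared)
    else:
        shared_amps = np.empty(0)

    dff_true = np.zeros((params.n_frames, params.n_rois))
    gt_rows = []
    for j in range(params.n_rois):
        take_shared = rng.random(n_shared) < params.sync_prob if n_shared \
            else np.empty(0, dtype=bool)
        times = shared_times[take_shared] if n_shared else np.empty(0)
        amps = shared_amps[take_shared] if n_shared else np.empty(0)
        origin = np.ones(times.size, dtype=bool)
        n_priv = rng.poisson(lam * (1.0 - params.sync_prob))
        if n_priv:
            pt = rng.uniform(0, duration_s, n_priv)
            pa = rng.lognormal(ln_mu, ln_sigma, n_priv) if mu > 0 \
                else np.zeros(n_priv)
            times = np.concatenate([times, pt])
            amps = np.concatenate([amps, pa])
            origin = np.concatenate([origin, np.zeros(n_priv, dtype=bool)])
        times, amps, origin = _thin_events(
            times, amps, origin, params.min_event_interval_s)
        for t0, a in zip(times, amps):
            dff_true[:, j] += a * event_kernel(
                t_frames - t0, params.tau_rise_s, params.tau_decay_s)
        order = np.argsort(times)
        for idx in order:
            gt_rows.append({
                "roi_id": f"roi{j}",
                "time_s": float(times[idx]),
                "frame": int(np.ceil(times[idx] * fs)),
                "amplitude": float(amps[idx]),
                "shared": bool(origin[idx]),
            })

    raw = params.baseline_f0 * (1.0 + dff_true)
    if params.noise_sd > 0:
        for _ in range(200):
            noise = rng.normal(0, params.noise_sd, raw.shape)
            if np.all(raw + noise > 0):
                raw = raw + noise
                break
        else:
            raw = np.clip(raw + noise, 1e-6, None)

    labels = tuple(roi_labels) if roi_labels is not None \
        else ("soma",) * params.n_rois
    rec = FOVRecording(
        fluorescence=raw, sampling_rate_hz=fs, roi_labels=labels,
        fov_id=fov_id, animal_id=animal_id, group=group,
    )
    gt = GroundTruth(event_table=pd.DataFrame(
        gt_rows, columns=["roi_id", "time_s", "frame", "amplitude", "shared"]))
    return rec, gt


# ---------------------------------------------------------------------------
# spine sessions
# ---------------------------------------------------------------------------

def _unique_positions(rng: np.random.Generator, n: int, length: float
                      ) -> np.ndarray:
    """Uniform positions on [0, length], resampled until pairwise distinct."""
    for _ in range(100):
        pos = rng.uniform(0, length, n)
        if n < 2 or np.min(np.diff(np.sort(pos))) >= 1e-5:
            return pos
    return np.linspace(0, length, n + 2)[1:-1]  # deterministic fallback


def simulate_spine_sessions(params: SpineSimParams,
                            animal_id: str = "animal0", group: str = ""
                            ) -> tuple[SpineSession, SpineSession, GroundTruth]:
    """Simulate a matched pair of spine-annotation sessions.

    Session-1 spine counts per shaft are Poisson (resampled to >= 1); each
    session-1 spine survives to session 2 with ``survival_prob`` (position
    jittered and clipped to the shaft); births arrive as a Poisson process at
    ``birth_rate_per_um``. Ground truth labels every spine stable,
    eliminated, or new.
    """
    rng = np.random.default_rng(params.seed)
    shafts1, shafts2, rows = [], [], []
    for k in range(params.n_shafts):
        sid = f"shaft{k}"
        n1 = 0
        while n1 < 1:
            n1 = int(rng.poisson(params.spines_per_shaft_mean))
        pos1 = np.sort(_unique_positions(rng, n1, params.shaft_length_um))
        survive = rng.random(n1) < params.survival_prob
        pos2 = []
        for i in range(n1):
            fate = "stable" if survive[i] else "eliminated"
            rows.append({"shaft_id": sid, "session": 1, "spine_index": i,
                         "position_um": float(pos1[i]), "fate": fate})
            if survive[i]:
                p = pos1[i] + rng.normal(0, params.position_jitter_um) \
                    if params.position_jitter_um > 0 else pos1[i]
                pos2.append(float(np.clip(p, 0, params.shaft_length_um)))
        n_births = rng.poisson(params.birth_rate_per_um
                               * params.shaft_length_um)
        births = rng.uniform(0, params.shaft_length_um, n_births)
        pos2_all = np.array(pos2 + list(births))
        # nudge coincident session-2 positions apart (unique within 1e-6 um)
        if pos2_all.size > 1:
            order = np.argsort(pos2_all)
            srt = pos2_all[order]
            for i in range(1, srt.size):
                if srt[i] - srt[i - 1] < 1e-5:
                    srt[i] = srt[i - 1] + 1e-5
            pos2_all = np.empty_like(srt)
            pos2_all[order] = srt
            pos2_all = np.clip(pos2_all, 0, params.shaft_length_um)
            # clipping can re-collide at the upper end; shift downwards
            order = np.argsort(pos2_all)
            srt = pos2_all[order]
            for i in range(srt.size - 2, -1, -1):
                if srt[i + 1] - srt[i] < 1e-5:
                    srt[i] = srt[i + 1] - 1e-5
            pos2_all[order] = srt
        for b, p in enumerate(births):
            rows.append({"shaft_id": sid, "session": 2,
                         "spine_index": len(pos2) + b,
                         "position_um": float(p), "fate": "new"})
        shafts1.append(Shaft(sid, params.shaft_length_um, pos1))
        shafts2.append(Shaft(sid, params.shaft_length_um, pos2_all))
    s1 = SpineSession(shafts1, 1, animal_id, group)
    s2 = SpineSession(shafts2, 2, animal_id, group)
    gt = GroundTruth(spine_labels=pd.DataFrame(
        rows, columns=["shaft_id", "session", "spine_index", "position_um",
                       "fate"]))
    return s1, s2, gt


# ---------------------------------------------------------------------------
# astrocyte trees
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def simulate_astrocyte_tree(params: MorphSimParams, cell_id: str = "cell0",
                            group: str = ""
                            ) -> tuple[MorphTree, GroundTruth]:
    """Simulate a branching astrocyte morphology rooted at the soma.

    ``n_primary_processes`` chains grow outward from the soma centre; each
    chain extends ``steps_per_chain`` segments of exponential length around
    ``segment_length_mean_um`` and then bifurcates with ``branch_prob``
    (depth capped at ``max_depth``). The soma contour is a circle of
    ``soma_radius_um``. Ground truth carries the exact total length and the
    number of unbranched chains.
    """
    rng = np.random.default_rng(params.seed)
    ids = [1]
    types = [1]
    xyz = [np.zeros(3)]
    radii = [params.soma_radius_um]
    parents = [-1]
    total_len = 0.0
    n_chains = 0
    next_id = 2

    # each stack entry: (parent index in arrays, position, direction, depth)
    stack = [(0, np.zeros(3), _random_unit(rng), 1)
             for _ in range(params.n_primary_processes)]
    while stack:
        parent_idx, pos, direction, depth = stack.pop(0)
        n_chains += 1
        for _ in range(params.steps_per_chain):
            step = rng.exponential(params.segment_length_mean_um)
            step = max(step, 0.25 * params.segment_length_mean_um)
            direction = direction + 0.3 * rng.normal(size=3)
            direction = direction / np.linalg.norm(direction)
            new_pos = pos + step * direction
            total_len += float(np.linalg.norm(new_pos - pos))
            ids.append(next_id)
            types.append(7)  # glial process
            xyz.append(new_pos)
            radii.append(0.5)
            parents.append(parent_idx)
            parent_idx = len(ids) - 1
            next_id += 1
            pos = new_pos
        if depth < params.max_depth and rng.random() < params.branch_prob:
            for _ in range(2):
                child_dir = direction + 0.8 * rng.normal(size=3)
                child_dir = child_dir / np.linalg.norm(child_dir)
                stack.append((parent_idx, pos, child_dir, depth + 1))

    # soma contour: a gently wobbled circle so cell-to-cell areas vary
    theta = np.linspace(0, 2 * np.pi, 25)[:-1]
    wobble = 1.0 + 0.06 * rng.normal() + 0.04 * rng.normal(size=theta.size)
    contour = (params.soma_radius_um * np.abs(wobble))[..., None] * \
        np.column_stack([np.cos(theta), np.sin(theta)])
    tree = MorphTree(
        node_ids=np.array(ids), node_types=np.array(types),
        xyz=np.array(xyz), radii=np.array(radii),
        parent_index=np.array(parents), soma_contour=contour,
        cell_id=cell_id, group=group,
    )
    gt = GroundTruth(tree_total_length_um=total_len,
                     tree_branch_count=n_chains)
    return tree, gt


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """A multi-group study layout with per-group parameter overrides.

    ``overrides`` maps a group name to a dict with optional sub-dicts
    ``"trace"``, ``"spine"``, ``"morph"`` whose keys override the
    corresponding simulator parameter (e.g.
    ``{"Alcohol": {"trace": {"amplitude_mean": 0.6}}}``). Unknown group or
    parameter keys are rejected.
    """

    groups: tuple[str, ...] = GROUPS_DEFAULT
    n_animals_per_group: int = 4
    n_fovs_per_animal: int = 2
    base_trace: TraceSimParams = field(default_factory=TraceSimParams)
    base_spine: SpineSimParams = field(default_factory=SpineSimParams)
    base_morph: MorphSimParams = field(default_factory=MorphSimParams)
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ConfigurationError("a study design needs >= 2 groups")
        known_sections = {"trace", "spine", "morph"}
        param_fields = {
            "trace": {f.name for f in fields(TraceSimParams)},
            "spine": {f.name for f in fields(SpineSimParams)},
            "morph": {f.name for f in fields(MorphSimParams)},
        }
        for gname, sections in self.overrides.items():
            if gname not in self.groups:
                raise ConfigurationError(
                    f"override for unknown group {gname!r}")
            for sec, kv in sections.items():
                if sec not in known_sections:
                    raise ConfigurationError(
                        f"unknown override section {sec!r} for group {gname!r}")
                unknown = set(kv) - param_fields[sec]
                if unknown:
                    raise ConfigurationError(
                        f"unknown {sec} parameters for group {gname!r}: "
                        f"{sorted(unknown)}")

    def params_for(self, group: str):
        ov = self.overrides.get(group, {})
        return (
            replace(self.base_trace, **ov.get("trace", {})),
            replace(self.base_spine, **ov.get("spine", {})),
            replace(self.base_morph, **ov.get("morph", {})),
        )


#: paper-style group effects: alcohol lowers neuronal event amplitude and
#: rate, raises synchrony, lowers spine survival and birth; exercise restores
#: toward the saline settings.
DEFAULT_OVERRIDES = {
    "Alcohol": {
        "trace": {"amplitude_mean": 0.6, "event_rate_per_min": 1.2,
                  "sync_prob": 0.6},
        "spine": {"survival_prob": 0.92, "birth_rate_per_um": 0.04},
        "morph": {"branch_prob": 0.45, "segment_length_mean_um": 5.0,
                  "soma_radius_um": 6.0},
    },
    "Alcohol+Ex": {
        "trace": {"amplitude_mean": 0.9, "event_rate_per_min": 1.8,
                  "sync_prob": 0.38},
        "spine": {"survival_prob": 0.87, "birth_rate_per_um": 0.07},
        "morph": {"branch_prob": 0.34, "segment_length_mean_um": 4.2,
                  "soma_radius_um": 5.3},
    },
}


def animal_seed(master_seed: int, group_index: int, animal_index: int,
                stream: int = 0) -> int:
    """Deterministic per-animal sub-seed, stable across runs (< 2**31)."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed),
        spawn_key=(int(group_index), int(animal_index), int(stream)),
    )
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class StudyBundle:
    """All simulated inputs of one study plus the tidy measurement table."""

    recordings: list[FOVRecording]
    spine_pairs: list[tuple[SpineSession, SpineSession]]
    trees: list[MorphTree]
    measurements: pd.DataFrame
    ground_truths: dict


def simulate_study(design: StudyDesign, seed: int) -> StudyBundle:
    """Simulate a full multi-group study and its tidy measurement table.

    Per-animal seeds are derived deterministically from the master seed, so
    identical (design, seed) pairs give identical bundles. The measurement
    table has columns (unit_id, group, measure, value) with one row per
    animal-level endpoint, ready for the group-statistics stage.
    """
    from . import calcium, morphometry, spines as spines_mod

    recordings, spine_pairs, trees, meas = [], [], [], []
    gts: dict = {"fov": {}, "spines": {}, "tree": {}}
    for gi, gname in enumerate(design.groups):
        tpar, spar, mpar = design.params_for(gname)
        for ai in range(design.n_animals_per_group):
            animal = f"{gname}_a{ai}"
            fov_metrics = []
            for fi in range(design.n_fovs_per_animal):
                s = animal_seed(seed, gi, ai, stream=fi)
                rec, gt = simulate_fov(
                    replace(tpar, seed=s),
                    fov_id=f"{animal}_fov{fi}", animal_id=animal, group=gname,
                )
                recordings.append(rec)
                gts["fov"][rec.fov_id] = gt
                roi_tab, _, sync = calcium.summarize_fov(rec)
                fov_metrics.append({
                    "integrated": roi_tab["integrated_dff"].mean(),
                    "peak": roi_tab.loc[roi_tab.n_transients > 0,
                                        "mean_peak_dff"].mean(),
                    "mean_corr": sync.mean_corr,
                })
            fm = pd.DataFrame(fov_metrics)
            meas += [
                {"unit_id": animal, "group": gname,
                 "measure": "integrated_calcium", "value": fm["integrated"].mean()},
                {"unit_id": animal, "group": gname,
                 "measure": "peak_dff",
                 "value": float(np.nanmean(fm["peak"]))},
                {"unit_id": animal, "group": gname,
                 "measure": "mean_corr", "value": fm["mean_corr"].mean()},
            ]
            s1, s2, sgt = simulate_spine_sessions(
                replace(spar, seed=animal_seed(seed, gi, ai, stream=100)),
                animal_id=animal, group=gname,
            )
            spine_pairs.append((s1, s2))
            gts["spines"][animal] = sgt
            match = spines_mod.match_spines(s1, s2)
            summ = spines_mod.turnover_metrics(match, s1, s2)
            meas += [
                {"unit_id": animal, "group": gname,
                 "measure": "spine_density", "value": summ.density_s2},
                {"unit_id": animal, "group": gname,
                 "measure": "formation_pct", "value": summ.formation_pct},
                {"unit_id": animal, "group": gname,
                 "measure": "elimination_pct", "value": summ.elimination_pct},
                {"unit_id": animal, "group": gname,
                 "measure": "turnover_pct", "value": summ.turnover_pct},
            ]
            tree, tgt = simulate_astrocyte_tree(
                replace(mpar, seed=animal_seed(seed, gi, ai, stream=200)),
                cell_id=f"{animal}_astro", group=gname,
            )
            trees.append(tree)
            gts["tree"][tree.cell_id] = tgt
            meas += [
                {"unit_id": animal, "group": gname,
                 "measure": "soma_area_um2",
                 "value": morphometry.soma_area(tree.soma_contour)},
                {"unit_id": animal, "group": gname,
                 "measure": "total_process_length_um",
                 "value": morphometry.total_length(tree)},
                {"unit_id": animal, "group": gname,
                 "measure": "branch_count",
                 "value": float(morphometry.branch_count(tree))},
            ]
    return StudyBundle(
        recordings=recordings, spine_pairs=spine_pairs, trees=trees,
        measurements=pd.DataFrame(meas), ground_truths=gts,
    )
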