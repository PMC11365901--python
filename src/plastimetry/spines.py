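"""Two-session dendritic spine matching and turnover metrics.

Spines are points along a dendritic shaft, identified by their arc-length
position in micrometres. Across two imaging sessions a spine is *stable* if
present in both, *eliminated* if present only in the first, and *new* if
present only in the second. Matching is greedy nearest-neighbour within a
positional tolerance; the rates are percentages of the session-1 spine count
(the dominant convention in transcranial spine-imaging work) and the overall
turnover rate is the arithmetic mean of formation and elimination; a pooled
(gained+lost)/(N1+N2) convention is available via ``denominator="pooled"``.
"""

from __future__ import annotations

import logging

from .datatypes import (
    SpineMatch,
    SpinePair,
    SpineSession,
    TurnoverSummary,
)
from .errors import AlignmentError, DataError

logger = logging.getLogger(__name__)


def select_shafts(
    session: SpineSession,
    min_spines: int = 8,
    max_spines: int = 15,
    companion: SpineSession | None = None,
):
    """Keep only shafts whose spine count lies in [min_spines, max_spines].

    The filter is applied to ``session`` (conventionally session 1) and, when
    a ``companion`` session is given, the companion is restricted to the same
    shaft set so both sessions stay aligned.
    """
    if min_spines > max_spines:
        raise ValueError("min_spines must be <= max_spines")
    keep = {s.shaft_id for s in session.shafts
            if min_spines <= s.n_spines <= max_spines}
    if not keep:
        logger.warning("shaft filter [%d, %d] removed every shaft",
                       min_spines, max_spines)
    filtered = SpineSession(
        shafts=[s for s in session.shafts if s.shaft_id in keep],
        session_index=session.session_index,
        animal_id=session.animal_id,
        group=session.group,
    )
    if companion is None:
        return filtered
    filtered2 = SpineSession(
        shafts=[s for s in companion.shafts if s.shaft_id in keep],
        session_index=companion.session_index,
        animal_id=companion.animal_id,
        group=companion.group,
    )
    return filtered, filtered2


def match_spines(
    s1: SpineSession, s2: SpineSession, tolerance_um: float = 1.0
) -> SpineMatch:
    """Greedy one-to-one nearest-neighbour spine matching per shaft.

    All cross-session position pairs within ``tolerance_um`` are processed in
    ascending distance order (ties broken by lower session-1 index, then lower
    session-2 index); each spine is used at most once. Unmatched session-1
    spines are eliminated, unmatched session-2 spines are new.
    """
    if tolerance_um < 0:
        raise ValueError("tolerance_um must be >= 0")
    ids1, ids2 = s1.shaft_ids(), s2.shaft_ids()
    if set(ids1) != set(ids2):
        raise AlignmentError(
            f"shaft ids differ between sessions: "
            f"{sorted(set(ids1) ^ set(ids2))}"
        )
    by_id2 = {s.shaft_id: s for s in s2.shafts}
    pairs: list[SpinePair] = []
    unmatched_s1: list[tuple[str, int]] = []
    unmatched_s2: list[tuple[str, int]] = []
    for shaft1 in s1.shafts:
        shaft2 = by_id2[shaft1.shaft_id]
        cands = sorted(
            (abs(float(p1) - float(p2)), i, j)
            for i, p1 in enumerate(shaft1.positions_um)
            for j, p2 in enumerate(shaft2.positions_um)
            if abs(float(p1) - float(p2)) <= tolerance_um
        )
        used1: set[int] = set()
        used2: set[int] = set()
        for d, i, j in cands:
            if i in used1 or j in used2:
                continue
            used1.add(i)
            used2.add(j)
            pairs.append(SpinePair(shaft1.shaft_id, i, j, d))
        unmatched_s1 += [(shaft1.shaft_id, i)
                         for i in range(shaft1.n_spines) if i not in used1]
        unmatched_s2 += [(shaft1.shaft_id, j)
                         for j in range(shaft2.n_spines) if j not in used2]
    return SpineMatch(pairs=pairs, unmatched_s1=unmatched_s1,
                      unmatched_s2=unmatched_s2, tolerance_um=tolerance_um)


def spine_density(session: SpineSession) -> float:
    """Spines per micrometre, pooled over all shafts of the session."""
    total_len = session.total_length_um()
    if total_len <= 0:
        raise DataError("spine density undefined: total shaft length is 0")
    return session.total_spines() / total_len


def turnover_metrics(
    match: SpineMatch,
    s1: SpineSession,
    s2: SpineSession,
    denominator: str = "s1",
) -> TurnoverSummary:
    """Density, formation, elimination, and overall turnover percentages.

    With the default ``denominator="s1"``: formation = 100 x |new| / N1,
    elimination = 100 x |eliminated| / N1, turnover = their mean. With
    ``"pooled"``: formation = 100 x |new| / N2, elimination stays over N1, and
    turnover = 100 x (|new| + |eliminated|) / (N1 + N2).
    """
    n1, n2 = s1.total_spines(), s2.total_spines()
    if match.n_stable + match.n_eliminated != n1 or \
            match.n_stable + match.n_new != n2:
        raise DataError("match is inconsistent with the supplied sessions")
    if n1 == 0:
        raise DataError("turnover rates undefined: session 1 has no spines")
    if denominator == "s1":
        formation = 100.0 * match.n_new / n1
        elimination = 100.0 * match.n_eliminated / n1
        turnover = (formation + elimination) / 2.0
    elif denominator == "pooled":
        if n2 == 0:
            raise DataError("pooled rates undefined: session 2 has no spines")
        formation = 100.0 * match.n_new / n2
        elimination = 100.0 * match.n_eliminated / n1
        turnover = 100.0 * (match.n_new + match.n_eliminated) / (n1 + n2)
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    return TurnoverSummary(
        density_s1=spine_density(s1),
        density_s2=spine_density(s2),
        formation_pct=formation,
        elimination_pct=elimination,
        turnover_pct=turnover,
        n_s1=n1,
        n_s2=n2,
    )
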