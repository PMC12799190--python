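"""Agent-locked 30-second pre/post windows and their local entropy.

An encounter is the first retained fixation on an agent collider: a fixation
is kept as an onset iff no retained encounter on the same agent occurred in
the preceding 30 s (per-agent refractory rule) and both the pre window
``[onset - 30, onset)`` and the post window ``[onset, onset + 30)`` fit
inside the session.  The onset fixation itself belongs to the post window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import AGENT_CATEGORIES, CANONICAL_CATEGORIES, gte
from .fixations import FixationEvent

#: map agent category -> agent type label
_AGENT_TYPE = {
    "agent_acontextual": "acontextual",
    "agent_congruent": "congruent",
    "agent_incongruent": "incongruent",
}

MIN_WINDOW_FIXATIONS = 3


@dataclass
class Encounter:
    participant: object
    session: object
    agent_id: str
    agent_type: str
    onset: float
    pre_window: tuple[float, float]
    post_window: tuple[float, float]
    gte_pre: float = np.nan
    gte_post: float = np.nan
    encounter_index: int = 0


def extract_encounters(
    fixations: list[FixationEvent],
    session_span: tuple[float, float],
    window: float = 30.0,
    participant=None,
    session=None,
    refractory_scope: str = "per_agent",
) -> list[Encounter]:
    """Scan agent fixations in time order and retain valid encounter onsets.

    ``refractory_scope`` is ``"per_agent"`` (default: the 30-s refractory
    period applies per agent collider) or ``"global"`` (across all agents).
    Encounters are numbered 1.. per participant in onset order.
    """
    t0, t1 = session_span
    last_onset: dict[str, float] = {}
    out: list[Encounter] = []
    for f in sorted(fixations, key=lambda f: f.start):
        if f.category not in AGENT_CATEGORIES:
            continue
        onset = f.start
        key = "*" if refractory_scope == "global" else str(f.object_id)
        prev = last_onset.get(key, -np.inf)
        if onset - prev < window:
            continue
        if onset - window < t0 or onset + window > t1:
            continue
        last_onset[key] = onset
        out.append(Encounter(
            participant=participant, session=session,
            agent_id=str(f.object_id), agent_type=_AGENT_TYPE[f.category],
            onset=onset,
            pre_window=(onset - window, onset),
            post_window=(onset, onset + window),
        ))
    for i, e in enumerate(out, start=1):
        e.encounter_index = i
    return out


def window_gte(
    fixations: list[FixationEvent],
    interval: tuple[float, float],
    labels: tuple[str, ...] = CANONICAL_CATEGORIES,
    min_fixations: int = MIN_WINDOW_FIXATIONS,
    drop_self_transitions: bool = False,
):
    """Normalized GTE of the fixations whose midpoint falls in ``interval``.

    Returns the :class:`~gazeflow.entropy.EntropyResult` or ``None`` when the
    window holds fewer than ``min_fixations`` fixations (flagged missing).
    """
    lo, hi = interval
    if not hi > lo:
        raise ValueError("interval must have positive length")
    seq = [f.category for f in fixations if lo <= 0.5 * (f.start + f.end) < hi]
    if len(seq) < min_fixations:
        return None
    return gte(seq, labels=labels, drop_self_transitions=drop_self_transitions)


def encounter_table(
    fixations: list[FixationEvent],
    session_span: tuple[float, float],
    window: float = 30.0,
    participant=None,
    session=None,
    refractory_scope: str = "per_agent",
    labels: tuple[str, ...] = CANONICAL_CATEGORIES,
) -> pd.DataFrame:
    """Extract encounters and attach per-window normalized GTE values."""
    encounters = extract_encounters(
        fixations, session_span, window=window,
        participant=participant, session=session,
        refractory_scope=refractory_scope,
    )
    for e in encounters:
        pre = window_gte(fixations, e.pre_window, labels=labels)
        post = window_gte(fixations, e.post_window, labels=labels)
        e.gte_pre = pre.H_norm if pre is not None else np.nan
        e.gte_post = post.H_norm if post is not None else np.nan
    return pd.DataFrame(
        [(e.participant, e.session, e.agent_id, e.agent_type, e.onset,
          e.encounter_index, e.gte_pre, e.gte_post) for e in encounters],
        columns=["participant", "session", "agent_id", "agent_type", "onset",
                 "encounter_index", "gte_pre", "gte_post"],
    )
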