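"""Velocity-threshold fixation classification for head-free VR gaze data.

Raw 90 Hz gaze samples are converted to angular velocities with a correction
for the observer's translational movement, thresholded segment-by-segment
with a robust (median + MAD) adaptive criterion, and grouped into fixation
events carrying the modal hit object.  Dwelling time is then accumulated per
object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: assumed gaze depth (m) for samples without a collider hit
DEFAULT_GAZE_DEPTH = 50.0
MAD_SCALE = 1.4826  # normal-consistency constant


@dataclass(frozen=True)
class FixationEvent:
    start: float
    end: float
    object_id: str | None
    category: str | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start


def angular_velocity(samples: pd.DataFrame, gaze_depth: float = DEFAULT_GAZE_DEPTH) -> np.ndarray:
    """Per-sample angular velocity (deg/s) with translational correction.

    Each gaze ray is projected to its world end point (head position plus
    hit distance along the gaze direction; ``gaze_depth`` where no collider
    was hit).  Consecutive end points are re-anchored at the midpoint head
    position, so angular motion induced purely by walking past a fixated
    point cancels.  The first element is NaN.
    """
    if "valid" in samples:
        n_valid = int(samples["valid"].sum())
    else:
        n_valid = len(samples)
    if n_valid < 2:
        raise ValueError("need at least 2 valid samples")
    t = samples["t"].to_numpy(float)
    if (np.diff(t) <= 0).any():
        raise ValueError("timestamps must be strictly increasing")
    gaze = samples[["gaze_x", "gaze_y", "gaze_z"]].to_numpy(float)
    head = samples[["head_x", "head_y", "head_z"]].to_numpy(float)
    dist = samples["hit_dist"].to_numpy(float) if "hit_dist" in samples else np.full(len(samples), np.nan)
    dist = np.where(np.isfinite(dist), dist, gaze_depth)
    target = head + dist[:, None] * gaze

    mid = 0.5 * (head[:-1] + head[1:])
    v0 = target[:-1] - mid
    v1 = target[1:] - mid
    cosang = np.einsum("ij,ij->i", v0, v1) / (
        np.linalg.norm(v0, axis=1) * np.linalg.norm(v1, axis=1)
    )
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    vel = np.empty(len(samples))
    vel[0] = np.nan
    vel[1:] = ang / np.diff(t)
    if "valid" in samples:
        invalid = ~samples["valid"].to_numpy(bool)
        vel[1:][invalid[1:] | invalid[:-1]] = np.nan
    return vel


def _segment_thresholds(
    t: np.ndarray, vel: np.ndarray, segment_s: float, lam: float
) -> np.ndarray:
    """Adaptive per-sample threshold: median + lam * 1.4826 * MAD per segment."""
    thresh = np.full(len(t), np.nan)
    seg = np.floor((t - t[0]) / segment_s).astype(int)
    for s in np.unique(seg):
        m = seg == s
        v = vel[m]
        v = v[np.isfinite(v)]
        if v.size == 0:
            logger.warning("segment %d has no finite velocities; skipped", s)
            continue
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        thresh[m] = med + lam * MAD_SCALE * mad
    return thresh


def classify_fixations(
    samples: pd.DataFrame,
    segment_s: float = 10.0,
    lam: float = 3.0,
    min_fix_s: float = 0.1,
    blink_bridge_s: float = 0.075,
    max_fix_deg_s: float = 100.0,
    category_of: dict[str, str] | None = None,
) -> list[FixationEvent]:
    """Classify gaze samples into fixation events.

    Velocities are thresholded per 10-s segment (``median + lam * robust SD``);
    runs of sub-threshold samples lasting at least ``min_fix_s`` become
    fixations.  ``max_fix_deg_s`` is an absolute physiological ceiling: the
    adaptive threshold degenerates on constant-velocity input (zero spread),
    and no fixation sample should move at saccadic speed regardless of the
    segment statistics.  Invalid-sample gaps shorter than ``blink_bridge_s``
    are bridged (treated as continuing the surrounding state); longer gaps
    split events.  Each fixation's object is the hit object with the longest
    within-fixation hit time (ties broken lexicographically).
    """
    t = samples["t"].to_numpy(float)
    if t[-1] - t[0] < segment_s:
        raise ValueError("samples must span at least one segment")
    vel = angular_velocity(samples)
    thresh = _segment_thresholds(t, vel, segment_s, lam)
    with np.errstate(invalid="ignore"):
        # <= tolerates the zero-spread segment (threshold == every velocity)
        below = (vel <= thresh + 1e-12) & (vel < max_fix_deg_s)
    below[0] = bool(below[1]) if len(below) > 1 else False

    valid = samples["valid"].to_numpy(bool) if "valid" in samples else np.ones(len(t), bool)
    # bridge short invalid gaps
    state = below & valid
    if not valid.all():
        state = _bridge_gaps(state, valid, t, blink_bridge_s)

    events: list[FixationEvent] = []
    objs = samples["hit_object_id"].to_numpy(object)
    i = 0
    n = len(t)
    while i < n:
        if not state[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and state[j + 1]:
            j += 1
        start, end = t[i], t[j] + (t[j] - t[j - 1] if j > 0 else 0.0)
        if end - start >= min_fix_s:
            obj = _modal_object(objs[i:j + 1], t[i:j + 1])
            cat = category_of.get(obj) if (category_of and obj is not None) else None
            if cat is None and obj is not None and ":" in str(obj):
                cat = str(obj).split(":", 1)[0]
            events.append(FixationEvent(start=start, end=end, object_id=obj, category=cat))
        i = j + 1
    return events


def _bridge_gaps(state: np.ndarray, valid: np.ndarray, t: np.ndarray, bridge_s: float) -> np.ndarray:
    out = state.copy()
    n = len(state)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not valid[j + 1]:
            j += 1
        gap = t[j] - t[i]
        if gap < bridge_s and i > 0 and j + 1 < n and state[i - 1] and state[j + 1]:
            out[i:j + 1] = True
        i = j + 1
    return out


def _modal_object(objs: np.ndarray, times: np.ndarray) -> str | None:
    """Object with the longest hit time within a fixation; lexicographic ties."""
    if len(times) == 1:
        return objs[0]
    dt = np.diff(times)
    dt = np.append(dt, dt[-1])
    acc: dict[str, float] = {}
    for o, w in zip(objs, dt):
        if o is None or (isinstance(o, float) and np.isnan(o)):
            continue
        acc[str(o)] = acc.get(str(o), 0.0) + float(w)
    if not acc:
        return None
    return min(acc.items(), key=lambda kv: (-kv[1], kv[0]))[0]


def accumulate_dwell(fixations: list[FixationEvent], participant) -> pd.DataFrame:
    """Per-object cumulative dwell table for one participant.

    Total dwell over all objects equals the summed fixation durations
    exactly (conservation).
    """
    rows: dict[tuple, list] = {}
    for f in fixations:
        key = (participant, f.object_id, f.category)
        if key not in rows:
            rows[key] = [0.0, 0]
        rows[key][0] += f.duration
        rows[key][1] += 1
    return pd.DataFrame(
        [(p, o, c, d, n) for (p, o, c), (d, n) in sorted(
            rows.items(), key=lambda kv: (str(kv[0][1]), str(kv[0][2])))],
        columns=["participant", "object_id", "category", "total_dwell", "fixation_count"],
    )


def fixations_to_frame(fixations: list[FixationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.start, f.end, f.duration, f.object_id, f.category) for f in fixations],
        columns=["start", "end", "duration", "object_id", "category"],
    )


def frame_to_fixations(df: pd.DataFrame) -> list[FixationEvent]:
    return [
        FixationEvent(start=float(r.start), end=float(r.end),
                      object_id=r.object_id, category=r.category)
        for r in df.itertuples()
    ]
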