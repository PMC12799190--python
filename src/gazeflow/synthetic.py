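"""Synthetic VR gaze data with the statistical structure the analysis assumes.

The generator emulates a free-exploration study in a virtual city: fixation
sequences over 8 visual categories driven by condition-specific Markov
transition matrices, Gamma-distributed dwell durations, 90 Hz gaze-sample
traces with velocity-separable fixations and saccades, agent encounters that
flatten the post-encounter transition structure, and pointing-task trials
whose absolute angular error follows a Gamma--log model with gaze-transition-
entropy (GTE) and dwell covariates plus participant/location random
intercepts.

Every public function is deterministic given its seed; identical seeds yield
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .entropy import AGENT_CATEGORIES, CANONICAL_CATEGORIES

AGENT_TYPES = ("acontextual", "congruent", "incongruent")
#: category label for each agent type
AGENT_CATEGORY = {
    "acontextual": "agent_acontextual",
    "congruent": "agent_congruent",
    "incongruent": "agent_incongruent",
}

SAMPLE_RATE_HZ = 90.0  # HMD refresh rate


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# default generative parameters (the study conditions)
# ---------------------------------------------------------------------------

def default_true_coefficients() -> dict[str, dict[str, float]]:
    """Generative coefficient sets for the five regression models.

    Values follow the magnitudes the analysis is designed to detect: dwell
    effects on the log-mean scale, entropy effects on the logit scale, and a
    negative GTE slope on log pointing error.  Random-intercept SDs mirror the
    modest participant/session heterogeneity the models assume.
    """
    return {
        # Gamma-log dwell model: object kind x agent congruency interaction
        "dwell": {
            "beta0": float(np.log(8.0)),  # buildings, acontextual: ~8 s
            "beta_O": -1.23,              # agents dwell far less than buildings
            "beta_C": 0.08,
            "beta_I": 0.012,
            "beta_OC": 0.06,
            "beta_OI": 0.41,              # incongruent agents grab attention
            "kappa": 1.49,
            "sigma_p": 0.20,
            "sigma_ps": 0.15,
        },
        # Beta-logit pre/post encounter entropy model with encounter-index spline
        "prepost": {
            "beta0": 0.55,
            "beta_P": 0.38,               # post-encounter entropy rises
            "phi": 8.0,
            "sigma_u": 0.19,
            "sigma_v": 0.19,
        },
        # Beta-logit post-encounter entropy model, sum-to-zero agent coding
        "postgte": {
            "beta0": 0.94,
            "gamma1": 0.009,              # acontextual deviation
            "gamma2": -0.015,             # congruent deviation
            "phi": 8.0,
            "sigma_u": 0.19,
            "sigma_v": 0.19,
        },
        # Gamma-log pointing-error model (outcome of the mediation)
        "perf": {
            "beta0": 3.9,
            "beta_C": 0.01,
            "beta_I": -0.12,
            "beta_pub": -0.09,
            "beta_GTE": -0.31,
            "beta_DW_A": -0.03,
            "beta_DW_B": -0.04,
            "kappa": 2.0,
            "sigma_u": 0.33,
            "sigma_v": 0.19,
        },
        # Beta-logit mediator model for post-encounter GTE
        "mediator": {
            "beta0": 0.93,
            "beta_C": 0.06,
            "beta_I": 0.065,
            "beta_pub": 0.10,
            "phi": 8.0,
            "sigma_u": 0.19,
            "sigma_v": 0.19,
        },
    }


def default_transition_matrix(concentration: float = 0.95, self_boost: float = 1.5) -> np.ndarray:
    """Structured row-stochastic matrix over the 8 canonical categories.

    Rows mix a shared anchor profile (most transitions land on buildings and
    background, as in free exploration of a city) with a self-transition
    boost, then with the uniform matrix at weight ``1 - concentration`` so the
    chain is irreducible with moderate conditional entropy.
    """
    k = len(CANONICAL_CATEGORIES)
    # agents are sparse landmarks of the city: encounters are rare events,
    # so 30-s pre windows are mostly free of earlier agent-driven flattening
    anchor = np.array([0.275, 0.375, 0.115, 0.115, 0.065, 0.003, 0.003, 0.003])
    anchor = anchor / anchor.sum()
    P = np.tile(anchor, (k, 1))
    # revisiting sticky environment content is common; agents are isolated
    # single objects, so their categories get no self-transition boost
    boost = np.full(k, self_boost)
    boost[5:] = 0.0
    P = P + np.diag(boost)
    P = P / P.sum(axis=1, keepdims=True)
    U = np.full((k, k), 1.0 / k)
    P = concentration * P + (1.0 - concentration) * U
    return P


def default_transition_matrices() -> dict[str, np.ndarray]:
    """Per-condition matrices; incongruent placements scan slightly flatter."""
    return {
        "acontextual": default_transition_matrix(concentration=0.95),
        "congruent": default_transition_matrix(concentration=0.95),
        "incongruent": default_transition_matrix(concentration=0.90),
    }


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror the study design: exploration sessions are scaled to a
    configurable ``session_length``, individual fixation durations are Gamma
    with mean ~0.44 s (free-viewing scale; cumulative per-object dwell then
    lands in the seconds range), the sampler runs at 90 Hz, and saccades peak
    well above the fixation velocity noise so a velocity-threshold classifier
    can separate them.
    """

    n_participants: int = 8
    n_sessions: int = 2
    session_length: float = 300.0           # seconds
    categories: tuple[str, ...] = CANONICAL_CATEGORIES
    transition_matrix_by_condition: dict[str, np.ndarray] = field(
        default_factory=default_transition_matrices
    )
    dwell_shape: float = 2.0                 # Gamma shape of fixation durations
    dwell_rate: float = 4.5                  # Gamma rate (1/s); mean ~0.44 s per fixation
    min_dwell: float = 0.15                  # floor so fixations are classifiable (s)
    saccade_peak_velocity: float = 200.0     # deg/s
    fixation_velocity_noise: float = 4.0     # deg/s jitter during fixations
    encounter_flattening: float = 0.6        # lambda mixing toward uniform post-encounter
    sample_rate: float = SAMPLE_RATE_HZ
    objects_per_category: int = 4
    object_distance: float = 10.0            # meters to fixation targets
    n_locations: int = 28                    # pointing-task start locations
    w_public: float = 0.5                    # empirical share of public-building trials
    true_coefficients: dict[str, dict[str, float]] = field(
        default_factory=default_true_coefficients
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.categories) != 8:
            raise ValueError("the category taxonomy has exactly 8 labels")
        for name, P in self.transition_matrix_by_condition.items():
            P = np.asarray(P, float)
            if P.shape != (8, 8) or (P < 0).any() or np.abs(P.sum(axis=1) - 1).max() > 1e-9:
                raise ValueError(f"transition matrix for {name!r} is not row-stochastic")
            self.transition_matrix_by_condition[name] = P
        if not 0.0 <= self.encounter_flattening <= 1.0:
            raise ValueError("encounter_flattening must lie in [0, 1]")
        if self.dwell_shape <= 0 or self.dwell_rate <= 0:
            raise ValueError("dwell parameters must be positive")
        if self.session_length <= 60.0:
            raise ValueError("session_length must exceed 60 s (one full pre+post window)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transition_matrix_by_condition"] = {
            k: np.asarray(v).tolist() for k, v in self.transition_matrix_by_condition.items()
        }
        return d


@dataclass
class GroundTruth:
    """Generating state of one session, kept for recovery tests."""

    fixation_log: pd.DataFrame        # start, end, object_id, category
    encounter_onsets: list[float]
    generating_coefficients: dict[str, dict[str, float]]
    random_intercepts: dict[str, float]
    condition: str
    transition_matrix: np.ndarray


# ---------------------------------------------------------------------------
# Markov machinery
# ---------------------------------------------------------------------------

def _validate_stochastic(P) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if (P < 0).any() or np.abs(P.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("transition matrix must be row-stochastic with non-negative entries")
    return P


def simulate_fixation_sequence(P, n: int, start_category, seed=None, labels=None) -> list:
    """Sample a category sequence of length ``n`` from a Markov chain.

    ``start_category`` may be a label (when ``labels`` given or it is one of
    the canonical categories) or an integer state index.
    """
    P = _validate_stochastic(P)
    if n < 2:
        raise ValueError("n must be >= 2")
    k = P.shape[0]
    if labels is None:
        labels = CANONICAL_CATEGORIES if k == len(CANONICAL_CATEGORIES) else tuple(range(k))
    labels = tuple(labels)
    if isinstance(start_category, (int, np.integer)):
        state = int(start_category)
    else:
        state = labels.index(start_category)
    rng = _as_rng(seed)
    cum = np.cumsum(P, axis=1)
    u = rng.random(n - 1)
    states = np.empty(n, dtype=np.int64)
    states[0] = state
    for i in range(1, n):
        state = int(np.searchsorted(cum[state], u[i - 1], side="right"))
        state = min(state, k - 1)
        states[i] = state
    return [labels[s] for s in states]


def simulate_encounter_shift(pre_P, lam: float) -> np.ndarray:
    """Flatten a transition matrix toward uniform by mixing weight ``lam``.

    ``post = (1 - lam) * pre + lam * U``; for ``lam > 0`` and a non-uniform
    ``pre`` this raises the normalized conditional entropy, encoding the
    post-encounter broadening of exploration.
    """
    P = _validate_stochastic(pre_P)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    k = P.shape[0]
    return (1.0 - lam) * P + lam * np.full((k, k), 1.0 / k)


# ---------------------------------------------------------------------------
# gaze-sample sessions
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _slerp(a: np.ndarray, b: np.ndarray, frac: float) -> np.ndarray:
    dot = float(np.clip(a @ b, -1.0, 1.0))
    theta = np.arccos(dot)
    if theta < 1e-9:
        return a
    return (np.sin((1 - frac) * theta) * a + np.sin(frac * theta) * b) / np.sin(theta)


def _object_directions(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One fixed world direction per object, spread over the forward sphere."""
    dirs: dict[str, np.ndarray] = {}
    for ci, cat in enumerate(config.categories):
        for oi in range(config.objects_per_category):
            # deterministic lattice plus jitter keeps pairwise separations > ~8 deg
            az = np.deg2rad(-60 + 120 * (ci * config.objects_per_category + oi)
                            / (8 * config.objects_per_category - 1))
            el = np.deg2rad(-20 + 40 * ((oi * 3 + ci) % 8) / 7.0)
            az += rng.normal(0, np.deg2rad(1.0))
            el += rng.normal(0, np.deg2rad(1.0))
            dirs[f"{cat}:{oi}"] = _unit(np.array(
                [np.cos(el) * np.sin(az), np.sin(el), np.cos(el) * np.cos(az)]
            ))
    return dirs


def _small_rotation(d: np.ndarray, angle_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate ``d`` by ``angle_rad`` about a random axis orthogonal to it."""
    r = rng.normal(size=3)
    axis = r - (r @ d) * d
    axis = _unit(axis)
    return _unit(np.cos(angle_rad) * d + np.sin(angle_rad) * axis)



def flatten_environment(P: np.ndarray, lam: float, agent_cols) -> np.ndarray:
    """Post-encounter flattening over environment (non-agent) categories.

    Each row's probability mass on non-agent categories is mixed with the
    uniform distribution over those categories at weight ``lam``; agent
    probabilities are untouched, so an encounter broadens scanning of the
    surroundings without making further agent fixations more likely (which
    would let flattening cascade indefinitely).
    """
    P = _validate_stochastic(P)
    k = P.shape[0]
    agent_cols = np.asarray(agent_cols, int)
    env = np.setdiff1d(np.arange(k), agent_cols)
    out = P.copy()
    mass = P[:, env].sum(axis=1)
    out[:, env] = (1.0 - lam) * P[:, env] + lam * mass[:, None] / len(env)
    return out


def _draw_fixation_plan(config: SimConfig, P: np.ndarray, obj_dirs, rng):
    """Time-aware fixation plan with post-encounter transition flattening.

    After any fixation on an agent category the chain follows the
    environment-flattened matrix for the next 30 s (extended by new
    encounters), implementing the generative post-encounter broadening of
    exploration.  Returns ``(plan, encounter_onsets)`` where plan rows are
    ``(start, end, object_id, category)``.
    """
    labels = config.categories
    agent_cols = [i for i, c in enumerate(labels) if c in AGENT_CATEGORIES]
    post_P = flatten_environment(P, config.encounter_flattening, agent_cols)
    cum_pre = np.cumsum(P, axis=1)
    cum_post = np.cumsum(post_P, axis=1)
    k = len(labels)
    plan: list[tuple[float, float, str, str]] = []
    onsets: list[float] = []
    t = 0.0
    state = 0
    prev_obj = None
    flatten_until = -np.inf
    while t < config.session_length:
        cat = labels[state]
        dur = max(float(rng.gamma(config.dwell_shape, 1.0 / config.dwell_rate)),
                  config.min_dwell)
        oi = int(rng.integers(config.objects_per_category))
        obj = f"{cat}:{oi}"
        merged = obj == prev_obj and bool(plan)
        if merged:
            s0, e0, o0, c0 = plan[-1]
            plan[-1] = (s0, e0 + dur, o0, c0)    # same object again: no saccade
            t = e0 + dur
        else:
            if plan:
                amp_deg = np.rad2deg(np.arccos(np.clip(
                    obj_dirs[prev_obj] @ obj_dirs[obj], -1, 1)))
                t += float(np.clip(2.0 * amp_deg / config.saccade_peak_velocity,
                                   0.03, 0.08))
            plan.append((t, t + dur, obj, cat))
            t += dur
        if cat in AGENT_CATEGORIES and not merged:
            onset = plan[-1][0]
            onsets.append(float(onset))
            flatten_until = max(flatten_until, onset + 30.0)
        prev_obj = obj
        cum = cum_post if t < flatten_until else cum_pre
        state = int(min(np.searchsorted(cum[state], rng.random(), side="right"), k - 1))
    return plan, onsets


def simulate_fixation_log(
    config: SimConfig,
    participant: int,
    session: int,
    condition: str | None = None,
    seed=None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Fixation-level session (no 90 Hz rasterization): fast path for
    entropy and window analyses that do not need raw gaze samples."""
    if condition is None:
        condition = next(iter(config.transition_matrix_by_condition))
    P = config.transition_matrix_by_condition[condition]
    if seed is None:
        seed = np.random.SeedSequence([config.seed, participant, session, 7]).generate_state(1)[0]
    rng = _as_rng(int(seed) if not isinstance(seed, np.random.Generator) else seed)
    obj_dirs = _object_directions(config, rng)
    plan, onsets = _draw_fixation_plan(config, P, obj_dirs, rng)
    plan = [p for p in plan if p[0] < config.session_length]
    log = pd.DataFrame(
        [(s, min(e, config.session_length), o, c) for s, e, o, c in plan],
        columns=["start", "end", "object_id", "category"],
    )
    truth = GroundTruth(
        fixation_log=log, encounter_onsets=onsets,
        generating_coefficients=config.true_coefficients,
        random_intercepts={}, condition=condition, transition_matrix=P,
    )
    return log, truth


def simulate_gaze_session(
    config: SimConfig,
    participant: int,
    session: int,
    condition: str | None = None,
    seed=None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one session's 90 Hz gaze-sample table plus its ground truth.

    Fixations follow the condition's Markov chain over categories (objects
    drawn within category); dwell durations are Gamma; saccades are symmetric
    triangular velocity profiles of 30-80 ms whose peak is at least
    ``saccade_peak_velocity``.  The head is stationary; translational
    correction is exercised by dedicated unit fixtures instead.
    """
    if condition is None:
        condition = next(iter(config.transition_matrix_by_condition))
    P = config.transition_matrix_by_condition[condition]
    if seed is None:
        seed = np.random.SeedSequence([config.seed, participant, session, 7]).generate_state(1)[0]
    rng = _as_rng(int(seed) if not isinstance(seed, np.random.Generator) else seed)

    # --- draw the fixation plan -------------------------------------------
    obj_dirs = _object_directions(config, rng)
    plan, onsets = _draw_fixation_plan(config, P, obj_dirs, rng)
    if not plan or plan[0][1] > config.session_length:
        raise ValueError("session_length too short for a single fixation")
    plan = [p for p in plan if p[0] < config.session_length]

    # --- rasterize to 90 Hz samples ---------------------------------------
    dt = 1.0 / config.sample_rate
    times = np.arange(0.0, config.session_length, dt)
    n = len(times)
    gaze = np.empty((n, 3))
    hit_obj = np.empty(n, dtype=object)
    hit_dist = np.full(n, np.nan)
    head = np.zeros((n, 3))

    starts = np.array([p[0] for p in plan])
    ends = np.array([p[1] for p in plan])
    idx = np.searchsorted(starts, times, side="right") - 1
    jitter_step = np.deg2rad(config.fixation_velocity_noise) * dt
    cur_dir = obj_dirs[plan[0][2]].copy()
    cur_fix = -1
    for i, (ti, j) in enumerate(zip(times, idx)):
        if j >= 0 and ti < ends[j]:
            s, e, obj, cat = plan[j]
            if j != cur_fix:
                cur_dir = obj_dirs[obj].copy()
                cur_fix = j
            else:
                cur_dir = _small_rotation(cur_dir, rng.uniform(0, jitter_step), rng)
            gaze[i] = cur_dir
            hit_obj[i] = obj
            hit_dist[i] = config.object_distance
        else:  # saccade between fixation j and j+1
            a = obj_dirs[plan[j][2]] if j >= 0 else obj_dirs[plan[0][2]]
            b = obj_dirs[plan[min(j + 1, len(plan) - 1)][2]]
            t0 = ends[j] if j >= 0 else 0.0
            t1 = starts[min(j + 1, len(plan) - 1)]
            span = max(t1 - t0, dt)
            x = float(np.clip((ti - t0) / span, 0.0, 1.0))
            # triangular velocity -> quadratic-ease position profile
            frac = 2 * x * x if x < 0.5 else 1 - 2 * (1 - x) * (1 - x)
            gaze[i] = _unit(_slerp(a, b, frac))
            hit_obj[i] = None
    samples = pd.DataFrame({
        "t": times,
        "gaze_x": gaze[:, 0], "gaze_y": gaze[:, 1], "gaze_z": gaze[:, 2],
        "head_x": head[:, 0], "head_y": head[:, 1], "head_z": head[:, 2],
        "hit_object_id": hit_obj,
        "hit_dist": hit_dist,
        "valid": True,
    })
    samples.attrs["participant"] = participant
    samples.attrs["session"] = session
    samples.attrs["seed"] = int(seed) if not isinstance(seed, np.random.Generator) else None

    fixation_log = pd.DataFrame(
        [(s, min(e, config.session_length), o, c) for s, e, o, c in plan],
        columns=["start", "end", "object_id", "category"],
    )
    truth = GroundTruth(
        fixation_log=fixation_log,
        encounter_onsets=onsets,
        generating_coefficients=config.true_coefficients,
        random_intercepts={},
        condition=condition,
        transition_matrix=P,
    )
    return samples, truth


# ---------------------------------------------------------------------------
# regression-model datasets
# ---------------------------------------------------------------------------

def _need(coefs: Mapping[str, float], model: str, names: Sequence[str]) -> None:
    for nm in names:
        if nm not in coefs:
            raise KeyError(f"true_coefficients[{model!r}] is missing {nm!r}")


def simulate_dwell_records(config: SimConfig, n: int, seed=None) -> pd.DataFrame:
    """Per-object dwell rows from the Gamma-log dwell model.

    Columns: participant, session, object_kind (0 building / 1 agent),
    agent_type, dwell (seconds).
    """
    c = config.true_coefficients["dwell"]
    _need(c, "dwell", ["beta0", "beta_O", "beta_C", "beta_I", "beta_OC", "beta_OI",
                       "kappa", "sigma_p", "sigma_ps"])
    rng = _as_rng(config.seed if seed is None else seed)
    p = rng.integers(config.n_participants, size=n)
    s = rng.integers(config.n_sessions, size=n)
    u_p = rng.normal(0, c["sigma_p"], size=config.n_participants)
    v_ps = rng.normal(0, c["sigma_ps"], size=(config.n_participants, config.n_sessions))
    O = rng.integers(2, size=n)
    at = rng.integers(3, size=n)  # 0 acontextual, 1 congruent, 2 incongruent
    TC, TI = (at == 1).astype(float), (at == 2).astype(float)
    eta = (c["beta0"] + c["beta_O"] * O + c["beta_C"] * TC + c["beta_I"] * TI
           + c["beta_OC"] * O * TC + c["beta_OI"] * O * TI + u_p[p] + v_ps[p, s])
    mu = np.exp(eta)
    y = rng.gamma(c["kappa"], mu / c["kappa"], size=n)
    return pd.DataFrame({
        "participant": p, "session": s, "object_kind": O,
        "agent_type": np.array(AGENT_TYPES)[at], "dwell": y,
    })


def simulate_prepost_records(config: SimConfig, n_encounters: int, seed=None) -> pd.DataFrame:
    """Pre/post window entropy rows from the Beta-logit pre/post model.

    Each encounter contributes a pre (P=0) and a post (P=1) row sharing its
    encounter index ``k`` within participant.
    """
    c = config.true_coefficients["prepost"]
    _need(c, "prepost", ["beta0", "beta_P", "phi", "sigma_u", "sigma_v"])
    rng = _as_rng(config.seed if seed is None else seed)
    u = rng.normal(0, c["sigma_u"], size=config.n_participants)
    v = rng.normal(0, c["sigma_v"], size=(config.n_participants, config.n_sessions))
    p = rng.integers(config.n_participants, size=n_encounters)
    s = rng.integers(config.n_sessions, size=n_encounters)
    # encounter index counts up within participant in row order
    k_within = np.empty(n_encounters, dtype=int)
    counters = np.zeros(config.n_participants, dtype=int)
    for i, pi in enumerate(p):
        counters[pi] += 1
        k_within[i] = counters[pi]
    rows = []
    for prepost in (0, 1):
        eta = c["beta0"] + c["beta_P"] * prepost + u[p] + v[p, s]
        mu = 1.0 / (1.0 + np.exp(-eta))
        h = rng.beta(mu * c["phi"], (1 - mu) * c["phi"])
        rows.append(pd.DataFrame({
            "participant": p, "session": s, "k": k_within,
            "prepost": prepost, "H": h,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_postgte_records(config: SimConfig, n: int, seed=None) -> pd.DataFrame:
    """Post-encounter entropy rows from the sum-coded Beta-logit model."""
    c = config.true_coefficients["postgte"]
    _need(c, "postgte", ["beta0", "gamma1", "gamma2", "phi", "sigma_u", "sigma_v"])
    rng = _as_rng(config.seed if seed is None else seed)
    u = rng.normal(0, c["sigma_u"], size=config.n_participants)
    v = rng.normal(0, c["sigma_v"], size=(config.n_participants, config.n_sessions))
    p = rng.integers(config.n_participants, size=n)
    s = rng.integers(config.n_sessions, size=n)
    at = rng.integers(3, size=n)
    Z1 = np.where(at == 0, 1.0, np.where(at == 1, 0.0, -1.0))
    Z2 = np.where(at == 0, 0.0, np.where(at == 1, 1.0, -1.0))
    eta = c["beta0"] + c["gamma1"] * Z1 + c["gamma2"] * Z2 + u[p] + v[p, s]
    mu = 1.0 / (1.0 + np.exp(-eta))
    h = rng.beta(mu * c["phi"], (1 - mu) * c["phi"])
    return pd.DataFrame({
        "participant": p, "session": s,
        "agent_type": np.array(AGENT_TYPES)[at], "H": h,
    })


def simulate_pointing_trials(config: SimConfig, n_trials: int, seed=None) -> pd.DataFrame:
    """Pointing-task trials from the Gamma-log performance model.

    ``gte_post`` is drawn from the mediator model's Beta distribution so the
    covariate has the dependence structure the mediation analysis assumes;
    dwell covariates are standard-normal on the z-scale.
    """
    cy = config.true_coefficients["perf"]
    _need(cy, "perf", ["beta0", "beta_C", "beta_I", "beta_pub", "beta_GTE",
                       "beta_DW_A", "beta_DW_B", "kappa", "sigma_u", "sigma_v"])
    cm = config.true_coefficients["mediator"]
    _need(cm, "mediator", ["beta0", "beta_C", "beta_I", "beta_pub", "phi"])
    rng = _as_rng(config.seed if seed is None else seed)
    cols = ["participant", "start_location", "agent_type", "building_type",
            "gte_post", "dw_agent_z", "dw_building_z", "error"]
    if n_trials == 0:
        return pd.DataFrame(columns=cols)
    p = rng.integers(config.n_participants, size=n_trials)
    loc = rng.integers(config.n_locations, size=n_trials)
    u = rng.normal(0, cy["sigma_u"], size=config.n_participants)
    v = rng.normal(0, cy["sigma_v"], size=config.n_locations)
    at = rng.integers(3, size=n_trials)
    C, I = (at == 1).astype(float), (at == 2).astype(float)
    pub = (rng.random(n_trials) < config.w_public).astype(float)
    mu_m = 1.0 / (1.0 + np.exp(-(cm["beta0"] + cm["beta_C"] * C + cm["beta_I"] * I
                                 + cm["beta_pub"] * pub)))
    m = rng.beta(mu_m * cm["phi"], (1 - mu_m) * cm["phi"])
    dwa = rng.normal(size=n_trials)
    dwb = rng.normal(size=n_trials)
    eta = (cy["beta0"] + cy["beta_C"] * C + cy["beta_I"] * I + cy["beta_pub"] * pub
           + cy["beta_GTE"] * m + cy["beta_DW_A"] * dwa + cy["beta_DW_B"] * dwb
           + u[p] + v[loc])
    y = rng.gamma(cy["kappa"], np.exp(eta) / cy["kappa"])
    return pd.DataFrame({
        "participant": p, "start_location": loc,
        "agent_type": np.array(AGENT_TYPES)[at],
        "building_type": np.where(pub == 1, "public", "residential"),
        "gte_post": m, "dw_agent_z": dwa, "dw_building_z": dwb, "error": y,
    })


def simulate_mediation_dataset(
    config: SimConfig, n: int, seed=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Joint mediator/outcome tables sharing participant and location keys.

    The mediator (post-encounter GTE) is drawn from the Beta-logit mediator
    model; the pointing error is then generated from the Gamma-log outcome
    model with the *realized* mediator value, so the indirect pathway in the
    data matches the generating coefficients.
    """
    cm = config.true_coefficients["mediator"]
    _need(cm, "mediator", ["beta0", "beta_C", "beta_I", "beta_pub", "phi",
                           "sigma_u", "sigma_v"])
    cy = config.true_coefficients["perf"]
    _need(cy, "perf", ["beta0", "beta_C", "beta_I", "beta_pub", "beta_GTE",
                       "beta_DW_A", "beta_DW_B", "kappa", "sigma_u", "sigma_v"])
    if cm["phi"] <= 0:
        raise ValueError("mediator precision phi must be positive")
    rng = _as_rng(config.seed if seed is None else seed)
    p = rng.integers(config.n_participants, size=n)
    loc = rng.integers(config.n_locations, size=n)
    at = rng.integers(3, size=n)
    C, I = (at == 1).astype(float), (at == 2).astype(float)
    pub = (rng.random(n) < config.w_public).astype(float)
    uM = rng.normal(0, cm["sigma_u"], size=config.n_participants)
    vM = rng.normal(0, cm["sigma_v"], size=config.n_locations)
    etaM = cm["beta0"] + cm["beta_C"] * C + cm["beta_I"] * I + cm["beta_pub"] * pub
    muM = 1.0 / (1.0 + np.exp(-(etaM + uM[p] + vM[loc])))
    m = rng.beta(muM * cm["phi"], (1 - muM) * cm["phi"])
    uY = rng.normal(0, cy["sigma_u"], size=config.n_participants)
    vY = rng.normal(0, cy["sigma_v"], size=config.n_locations)
    dwa = rng.normal(size=n)
    dwb = rng.normal(size=n)
    etaY = (cy["beta0"] + cy["beta_C"] * C + cy["beta_I"] * I + cy["beta_pub"] * pub
            + cy["beta_GTE"] * m + cy["beta_DW_A"] * dwa + cy["beta_DW_B"] * dwb
            + uY[p] + vY[loc])
    y = rng.gamma(cy["kappa"], np.exp(etaY) / cy["kappa"])
    agent = np.array(AGENT_TYPES)[at]
    btype = np.where(pub == 1, "public", "residential")
    mediator = pd.DataFrame({
        "participant": p, "start_location": loc, "agent_type": agent,
        "building_type": btype, "gte_post": m,
    })
    trials = pd.DataFrame({
        "participant": p, "start_location": loc, "agent_type": agent,
        "building_type": btype, "gte_post": m,
        "dw_agent_z": dwa, "dw_building_z": dwb, "error": y,
    })
    return mediator, trials
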