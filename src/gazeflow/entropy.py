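"""Gaze transition entropy (GTE) over visual categories.

A scanpath is reduced to the sequence of visual categories of its fixations.
Forward transitions between consecutive fixations define a count matrix; each
row (conditional next-category distribution) gets a Chao-Shen bias-corrected
Shannon entropy, rows are averaged with stationary-distribution weights, and
the result is normalized by ``log2(k)`` so that 0 means fully predictable
scanning and 1 means maximally dispersed scanning.

The Chao-Shen estimator rescales maximum-likelihood probabilities by the
estimated sample coverage ``C = 1 - S1/N`` (``S1`` = transition types seen
exactly once in the row) and divides each term by the probability of having
observed that type at least once (Horvitz-Thompson correction), which removes
most of the downward bias of plug-in entropy under sparse sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical 8-category taxonomy of fixation targets in the virtual city.
CANONICAL_CATEGORIES: tuple[str, ...] = (
    "background",
    "building",
    "task_residential",
    "task_public",
    "landmark",
    "agent_acontextual",
    "agent_congruent",
    "agent_incongruent",
)

AGENT_CATEGORIES: tuple[str, ...] = (
    "agent_acontextual",
    "agent_congruent",
    "agent_incongruent",
)


@dataclass
class TransitionCounts:
    """Forward-transition counts over ``k`` categories.

    ``counts[a, b]`` is the number of fixation pairs whose current category is
    ``a`` and next category is ``b``.
    """

    counts: np.ndarray  # (k, k) int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n_row(self) -> np.ndarray:
        """Per-row totals (N of the coverage formula)."""
        return self.counts.sum(axis=1)

    @property
    def s1_row(self) -> np.ndarray:
        """Per-row singleton counts (S1 of the coverage formula)."""
        return (self.counts == 1).sum(axis=1)


@dataclass
class EntropyResult:
    """Full per-sequence GTE decomposition."""

    P: np.ndarray                 # row-normalized transition matrix
    H_row: np.ndarray             # per-category Chao-Shen entropy, bits
    C_row: np.ndarray             # per-row estimated sample coverage
    pi: np.ndarray                # stationary weights (0 for unobserved rows)
    H_global: float               # stationary-weighted entropy, bits
    H_norm: float                 # H_global / log2(k), in [0, 1]
    labels: tuple[str, ...]
    zero_rows: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    pi_method: str = "eigen"      # "eigen" or "empirical" (fallback)


def build_transition_matrix(
    seq,
    labels: tuple[str, ...] = CANONICAL_CATEGORIES,
    drop_self_transitions: bool = False,
) -> TransitionCounts:
    """Count forward transitions of a category sequence.

    Each fixation is linked exclusively to the subsequent fixation.  Category
    self-transitions (consecutive fixations in the same category, e.g. on two
    different buildings) are counted by default; ``drop_self_transitions``
    excludes them for sensitivity analysis.
    """
    seq = list(seq)
    if len(seq) < 2:
        raise ValueError(f"need at least 2 fixations to count transitions, got {len(seq)}")
    index = {lab: i for i, lab in enumerate(labels)}
    try:
        codes = np.array([index[s] for s in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown category label: {exc.args[0]!r}") from None
    cur, nxt = codes[:-1], codes[1:]
    if drop_self_transitions:
        keep = cur != nxt
        cur, nxt = cur[keep], nxt[keep]
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (cur, nxt), 1)
    return TransitionCounts(counts=counts, labels=tuple(labels))


def row_normalize(tc: TransitionCounts) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalize counts to conditional probabilities.

    Returns ``(P, zero_rows)`` where rows with no observations stay all-zero
    and are flagged in the boolean ``zero_rows`` mask.
    """
    n = tc.n_row.astype(float)
    zero = n == 0
    P = np.zeros_like(tc.counts, dtype=float)
    nz = ~zero
    P[nz] = tc.counts[nz] / n[nz, None]
    return P, zero


def chao_shen_entropy(row_counts) -> tuple[float, float]:
    """Chao-Shen corrected Shannon entropy (bits) of one count vector.

    Returns ``(H, C)`` with ``C`` the estimated sample coverage.  When every
    observed type is a singleton (``S1 == N``) the standard implementation fix
    substitutes ``S1 = N - 1`` so the coverage stays positive.
    """
    counts = np.asarray(row_counts, dtype=np.int64)
    if counts.ndim != 1:
        raise ValueError("row_counts must be 1-D")
    if (counts < 0).any():
        raise ValueError("row_counts must be non-negative")
    n_total = int(counts.sum())
    if n_total < 1:
        raise ValueError("all-zero row: caller must skip unobserved rows")
    s1 = int((counts == 1).sum())
    if s1 == n_total:
        s1 = n_total - 1
    coverage = 1.0 - s1 / n_total
    if coverage == 0.0:  # unreachable after the fix, but keep the guard
        return 0.0, 0.0
    observed = counts[counts > 0].astype(float)
    p_ml = observed / n_total
    p_adj = coverage * p_ml
    la = 1.0 - (1.0 - p_adj) ** n_total
    h = float(np.sum(-p_adj * np.log2(p_adj) / la))
    return max(h, 0.0), coverage


def stationary_distribution(
    P: np.ndarray, row_totals: np.ndarray, tol: float = 1e-10
) -> tuple[np.ndarray, str]:
    """Stationary category weights of the normalized transition matrix.

    The principal left eigenvector of ``P`` restricted to observed categories
    (rows with data), renormalized to sum 1.  When the restricted chain leaks
    mass to unobserved categories, is reducible, or the eigen-solve misses
    tolerance, falls back to the empirical marginal ``row_totals / sum`` and
    reports ``method = "empirical"``.
    """
    P = np.asarray(P, dtype=float)
    row_totals = np.asarray(row_totals, dtype=float)
    k = P.shape[0]
    obs = row_totals > 0
    if not obs.any():
        raise ValueError("no observed rows")
    pi = np.zeros(k)
    sub = P[np.ix_(obs, obs)]
    empirical = row_totals[obs] / row_totals[obs].sum()
    # mass must stay inside the observed set for the sub-chain to be stochastic
    if np.abs(sub.sum(axis=1) - 1.0).max() > 1e-9:
        pi[obs] = empirical
        return pi, "empirical"
    try:
        w, v = np.linalg.eig(sub.T)
    except np.linalg.LinAlgError:
        pi[obs] = empirical
        return pi, "empirical"
    near_one = np.isclose(w, 1.0, atol=1e-8)
    if near_one.sum() != 1:  # reducible chain: stationary law not unique
        pi[obs] = empirical
        return pi, "empirical"
    vec = np.real(v[:, near_one.argmax()])
    vec = vec / vec.sum()
    if (vec < -tol).any() or np.abs(vec @ sub - vec).max() > tol:
        pi[obs] = empirical
        return pi, "empirical"
    pi[obs] = np.clip(vec, 0.0, None)
    pi[obs] /= pi[obs].sum()
    return pi, "eigen"


def global_entropy(H_row: np.ndarray, pi: np.ndarray) -> float:
    """Stationary-weighted average of per-category entropies (bits)."""
    H_row = np.asarray(H_row, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if H_row.shape != pi.shape:
        raise ValueError("H_row and pi must have equal length")
    return float(np.sum(pi * H_row))


def normalize_entropy(H: float, k: int) -> float:
    """Normalize entropy by the theoretical maximum ``log2(k)``."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if H < 0:
        raise ValueError("H must be >= 0")
    h = H / np.log2(k)
    if h > 1.0:
        # Chao-Shen can overshoot log2(k) on very sparse rows; clip and log
        logger.debug("normalized entropy %.6f > 1 clipped to 1", h)
        h = 1.0
    return float(h)


def gte(
    seq,
    labels: tuple[str, ...] = CANONICAL_CATEGORIES,
    drop_self_transitions: bool = False,
    stationary: str = "eigen",
) -> EntropyResult:
    """Full gaze-transition-entropy pipeline for one category sequence.

    counts -> row-normalize -> per-row Chao-Shen entropy -> stationary
    weights -> global entropy -> normalization by ``log2(k)``.

    Parameters
    ----------
    stationary
        ``"eigen"`` (principal left eigenvector, with empirical-marginal
        fallback) or ``"empirical"`` (marginal fixation frequencies).
    """
    tc = build_transition_matrix(seq, labels=labels, drop_self_transitions=drop_self_transitions)
    P, zero = row_normalize(tc)
    k = tc.k
    H_row = np.zeros(k)
    C_row = np.zeros(k)
    n_row = tc.n_row
    for i in range(k):
        if n_row[i] > 0:
            H_row[i], C_row[i] = chao_shen_entropy(tc.counts[i])
    if stationary == "empirical":
        pi = np.where(n_row > 0, n_row / n_row.sum(), 0.0)
        method = "empirical"
    else:
        pi, method = stationary_distribution(P, n_row)
    h_global = global_entropy(H_row, pi)
    h_norm = normalize_entropy(h_global, k)
    return EntropyResult(
        P=P, H_row=H_row, C_row=C_row, pi=pi, H_global=h_global,
        H_norm=h_norm, labels=tc.labels, zero_rows=zero, pi_method=method,
    )
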