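"""The five hierarchical regressions of the gaze-entropy analysis.

Declarative specs (likelihood, link, contrast coding, priors, random-effect
structure, coefficient registry) for:

``DWELL``
    Gamma-log dwell time ~ object kind x agent congruency, random intercepts
    for participant and session-within-participant.
``PREPOST``
    Beta-logit window entropy ~ pre/post indicator + smoothing spline over
    the encounter index, same nesting.
``POSTGTE``
    Beta-logit post-encounter entropy ~ agent type under sum-to-zero coding,
    same nesting.
``PERF``
    Gamma-log absolute pointing error ~ agent type + building type +
    post-encounter GTE + z-scored dwell covariates, crossed random
    intercepts for participant and pointing start location.
``MEDIATOR``
    Beta-logit post-encounter GTE ~ agent type + building type, crossed
    random intercepts for participant and start location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

import arviz as az

from .glmm import GLMMProblem, REBlock, diagnostics, sample_posterior

logger = logging.getLogger(__name__)

AGENT_LEVELS = ("acontextual", "congruent", "incongruent")


# ---------------------------------------------------------------------------
# small reusable pieces
# ---------------------------------------------------------------------------

def sv_transform(H, n: int):
    """Smithson-Verkuilen squeeze of [0, 1] responses into (0, 1).

    ``H* = (H * (n - 1) + 0.5) / n`` with ``n`` the analysis-sample size.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    H = np.asarray(H, dtype=float)
    if ((H < 0) | (H > 1)).any():
        raise ValueError("H must lie in [0, 1]")
    out = (H * (n - 1) + 0.5) / n
    return float(out) if out.ndim == 0 else out


def code_contrasts(levels, scheme: str) -> pd.DataFrame:
    """Contrast columns for a 2- or 3-level factor.

    ``treatment``: reference (first) level all-zero dummies.  ``sum``:
    sum-to-zero coding; for three levels the rows are (1,0), (0,1), (-1,-1)
    so the intercept is the grand mean and coefficients are level deviations.
    """
    levels = list(levels)
    if not 2 <= len(levels) <= 3:
        raise ValueError("2 or 3 levels supported")
    k = len(levels)
    if scheme == "treatment":
        M = np.zeros((k, k - 1))
        for i in range(1, k):
            M[i, i - 1] = 1.0
    elif scheme == "sum":
        M = np.vstack([np.eye(k - 1), -np.ones((1, k - 1))])
    else:
        raise ValueError(f"unknown contrast scheme {scheme!r}")
    cols = [f"c{i + 1}" for i in range(k - 1)]
    return pd.DataFrame(M, index=levels, columns=cols)


def spline_basis(k_values, dim: int = 5) -> np.ndarray:
    """Centered cubic B-spline basis of dimension ``dim`` over observed indices.

    Boundary knots sit at the data range with one interior knot per extra
    degree of freedom; columns are mean-centered so the smooth is orthogonal
    to the intercept in expectation.
    """
    x = np.asarray(k_values, dtype=float)
    if x.size == 0:
        raise ValueError("k_values must be non-empty")
    lo, hi = x.min(), x.max()
    if np.unique(x).size < 2:
        raise ValueError("degenerate spline basis: need >= 2 distinct index values")
    degree = 3
    n_interior = dim - (degree + 1)  # dim basis functions for cubic B-splines
    interior = np.quantile(np.unique(x), np.linspace(0, 1, n_interior + 2)[1:-1]) \
        if n_interior > 0 else np.array([])
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    B = BSpline.design_matrix(x, t, degree, extrapolate=True).toarray()
    assert B.shape[1] == dim, B.shape
    return B - B.mean(axis=0)


def effect_transform(beta: float, link: str, mode: str) -> float:
    """Back-transform a link-scale coefficient to a reportable effect."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if mode == "percent_change":
        if link != "log":
            raise ValueError("percent_change applies to log-link coefficients")
        return 100.0 * (np.exp(beta) - 1.0)
    if mode == "odds_ratio":
        return float(np.exp(beta))
    if mode == "inv_logit":
        return float(1.0 / (1.0 + np.exp(-beta)))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# model specs
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    name: str
    likelihood: str                 # "gamma_log" | "beta_logit"
    contrast: str                   # "treatment" | "sum"
    random_effects: str             # "nested" | "crossed"
    coefficients: tuple[str, ...]   # registry of fixed-effect names
    response: str
    has_spline: bool = False

    def default_hdi_prob(self) -> float:
        # dwell & pre/post effects reported with 89% HDIs, the rest with 95%
        return 0.89 if self.name in ("DWELL", "PREPOST") else 0.95


MODEL_SPECS: dict[str, ModelSpec] = {
    "DWELL": ModelSpec(
        name="DWELL", likelihood="gamma_log", contrast="treatment",
        random_effects="nested", response="dwell",
        coefficients=("beta0", "beta_O", "beta_C", "beta_I", "beta_OC", "beta_OI"),
    ),
    "PREPOST": ModelSpec(
        name="PREPOST", likelihood="beta_logit", contrast="treatment",
        random_effects="nested", response="H", has_spline=True,
        coefficients=("beta0", "beta_P"),
    ),
    "POSTGTE": ModelSpec(
        name="POSTGTE", likelihood="beta_logit", contrast="sum",
        random_effects="nested", response="H",
        coefficients=("beta0", "gamma1", "gamma2"),
    ),
    "PERF": ModelSpec(
        name="PERF", likelihood="gamma_log", contrast="treatment",
        random_effects="crossed", response="error",
        coefficients=("beta0", "beta_C", "beta_I", "beta_pub", "beta_GTE",
                      "beta_DW_A", "beta_DW_B"),
    ),
    "MEDIATOR": ModelSpec(
        name="MEDIATOR", likelihood="beta_logit", contrast="treatment",
        random_effects="crossed", response="gte_post",
        coefficients=("beta0", "beta_C", "beta_I", "beta_pub"),
    ),
}


def _codes(values) -> tuple[np.ndarray, int]:
    cats = pd.Categorical(values)
    return cats.codes.astype(int), len(cats.categories)


def build_problem(spec: ModelSpec, data: pd.DataFrame) -> GLMMProblem:
    """Assemble design matrices, priors and random-effect blocks for a spec."""
    n = len(data)
    y = data[spec.response].to_numpy(float)
    cols = [np.ones(n)]
    names = ["beta0"]

    if spec.name == "DWELL":
        O = data["object_kind"].to_numpy(float)
        cm = code_contrasts(AGENT_LEVELS, "treatment")
        T = cm.loc[data["agent_type"]].to_numpy()
        cols += [O, T[:, 0], T[:, 1], O * T[:, 0], O * T[:, 1]]
        names += ["beta_O", "beta_C", "beta_I", "beta_OC", "beta_OI"]
    elif spec.name == "PREPOST":
        cols += [data["prepost"].to_numpy(float)]
        names += ["beta_P"]
    elif spec.name == "POSTGTE":
        cm = code_contrasts(AGENT_LEVELS, "sum")
        Z = cm.loc[data["agent_type"]].to_numpy()
        cols += [Z[:, 0], Z[:, 1]]
        names += ["gamma1", "gamma2"]
    elif spec.name in ("PERF", "MEDIATOR"):
        cm = code_contrasts(AGENT_LEVELS, "treatment")
        T = cm.loc[data["agent_type"]].to_numpy()
        pub = (data["building_type"].astype(str) == "public").to_numpy(float)
        cols += [T[:, 0], T[:, 1], pub]
        names += ["beta_C", "beta_I", "beta_pub"]
        if spec.name == "PERF":
            cols += [data["gte_post"].to_numpy(float),
                     data["dw_agent_z"].to_numpy(float),
                     data["dw_building_z"].to_numpy(float)]
            names += ["beta_GTE", "beta_DW_A", "beta_DW_B"]
    else:
        raise ValueError(f"unknown spec {spec.name!r}")
    X = np.column_stack(cols)
    assert tuple(names) == spec.coefficients

    gamma = spec.likelihood == "gamma_log"
    intercept_prior = ("cauchy", 2.5) if gamma else ("student_t", 3, 2.5)
    sd_prior = ("cauchy", 2.5) if gamma else ("student_t", 3, 2.5)
    coef_priors = [intercept_prior] + [("normal", 1.0)] * (len(names) - 1)

    blocks: list[REBlock] = []
    pcode, pm = _codes(data["participant"])
    blocks.append(REBlock("participant", codes=pcode, n_levels=pm, sd_prior=sd_prior))
    if spec.random_effects == "nested":
        key = data["participant"].astype(str) + ":" + data["session"].astype(str)
        scode, sm = _codes(key)
        blocks.append(REBlock("participant:session", codes=scode, n_levels=sm,
                              sd_prior=sd_prior))
    else:
        lcode, lm = _codes(data["start_location"])
        blocks.append(REBlock("start_location", codes=lcode, n_levels=lm,
                              sd_prior=sd_prior))
    if spec.has_spline:
        B = spline_basis(data["k"].to_numpy(float), dim=5)
        blocks.append(REBlock("spline_k", Z=B, sd_prior=("student_t", 3, 0.8)))

    return GLMMProblem(
        family=spec.likelihood, X=X, y=y, coef_names=names,
        coef_priors=coef_priors, re_blocks=blocks,
        aux_name="kappa" if gamma else "phi",
    )


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

RHAT_LIMIT = 1.01


@dataclass
class Posterior:
    """Link-scale posterior draws and diagnostics for one fitted spec."""

    spec: ModelSpec
    draws: pd.DataFrame            # flattened (chain*draw) x named parameters
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name].to_numpy()


def fit_model(
    spec: ModelSpec | str,
    data: pd.DataFrame,
    profile: str = "test",
    seed: int = 0,
) -> Posterior:
    """Fit one hierarchical model and return its named posterior draws.

    Beta-likelihood responses must already be strictly interior (apply
    :func:`sv_transform` first when the raw entropies can touch 0 or 1).
    Non-convergence (any reported R-hat >= 1.01) flags the posterior rather
    than raising.
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec.upper()]
    problem = build_problem(spec, data)
    chain, meta = sample_posterior(problem, profile=profile, seed=seed)
    names = list(problem.coef_names) + [problem.aux_name] + [
        f"sd_{b.name}" for b in problem.re_blocks
    ]
    k = len(problem.coef_names)
    arr = np.empty(chain.shape[:2] + (len(names),))
    arr[..., :k] = chain[..., :k]
    arr[..., k] = np.exp(chain[..., k])                     # aux on natural scale
    for g in range(len(problem.re_blocks)):
        arr[..., k + 1 + g] = np.exp(chain[..., k + 1 + g])  # SDs
    rhat, ess = diagnostics(arr, names)
    reported = problem.coef_names + [problem.aux_name]
    converged = all(np.isfinite(rhat[nm]) and rhat[nm] < RHAT_LIMIT for nm in reported)
    if not converged:
        logger.warning("%s: flagged non-converged (max R-hat %.3f)",
                       spec.name, max(rhat[nm] for nm in reported))
    flat = arr.reshape(-1, len(names))
    # keep raw random-effect draws available for prediction if ever needed
    meta = dict(meta, n_obs=len(data), coef_names=problem.coef_names)
    return Posterior(
        spec=spec,
        draws=pd.DataFrame(flat, columns=names),
        rhat=rhat, ess=ess, converged=converged, metadata=meta,
    )


def summarize_posterior(post: Posterior, prob: float = 0.95) -> pd.DataFrame:
    """Mean, HDI bounds at ``prob``, and R-hat per named parameter."""
    rows = []
    for nm in post.draws.columns:
        x = post.draws[nm].to_numpy()
        if np.ptp(x) == 0:
            lo = hi = x[0]
        else:
            lo, hi = az.hdi(x, hdi_prob=prob)
        rows.append((nm, float(x.mean()), float(lo), float(hi), post.rhat.get(nm, np.nan)))
    out = pd.DataFrame(rows, columns=["coefficient", "mean", "hdi_lo", "hdi_hi", "rhat"])
    out.attrs["hdi_prob"] = prob
    return out


def floor_pointing_errors(y, floor: float = 0.1) -> np.ndarray:
    """Gamma support is positive: floor exact-zero pointing errors at 0.1 deg."""
    y = np.asarray(y, float)
    n_floored = int((y < floor).sum())
    if n_floored:
        logger.info("floored %d pointing errors below %.2f deg", n_floored, floor)
    return np.maximum(y, floor)
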