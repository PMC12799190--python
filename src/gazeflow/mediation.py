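"""Counterfactual mediation of agent effects on pointing error through GTE.

Bayesian parametric g-computation: per replication, one mediator-model draw
and one outcome-model draw are paired at random; the mediator mean under each
agent level and context is plugged into the outcome model's linear predictor;
context-marginal potential outcomes are formed with empirical residential /
public weights, and the three counterfactuals

``Y00`` (mediator and outcome at baseline), ``Y10`` (outcome treated,
mediator at baseline) and ``Y11`` (fully treated)

yield the natural direct, indirect and total effects

``NDE = Y10 - Y00``, ``NIE = Y11 - Y10``, ``TE = Y11 - Y00``

with risk-ratio counterparts ``RR = Y./Y.``; per draw ``TE = NDE + NIE`` and
``RR_TE = RR_NDE * RR_NIE`` hold exactly.  Dwell covariates sit at 0 on the
z-scale and random intercepts at 0 (average participant / location).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .models import Posterior

BASELINE = "acontextual"
TREATMENTS = ("congruent", "incongruent")


@dataclass
class MediationInput:
    mediator_posterior: Posterior | pd.DataFrame
    outcome_posterior: Posterior | pd.DataFrame
    w_res: float = 0.5
    w_pub: float = 0.5
    replications: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w_res < 0 or self.w_pub < 0 or abs(self.w_res + self.w_pub - 1) > 1e-9:
            raise ValueError("context weights must be non-negative and sum to 1")

    def mediator_draws(self) -> pd.DataFrame:
        p = self.mediator_posterior
        return p.draws if isinstance(p, Posterior) else p

    def outcome_draws(self) -> pd.DataFrame:
        p = self.outcome_posterior
        return p.draws if isinstance(p, Posterior) else p


def _level_dummies(level: str) -> tuple[float, float]:
    if level == BASELINE:
        return 0.0, 0.0
    if level == "congruent":
        return 1.0, 0.0
    if level == "incongruent":
        return 0.0, 1.0
    raise ValueError(f"unknown agent level {level!r}")


def mediator_mean(draw: pd.DataFrame | dict, level: str, context: str) -> np.ndarray:
    """Plug-in mediator mean ``inv-logit(b0 + bC*C + bI*I + bpub*P)``.

    ``draw`` holds mediator-model coefficients (columns beta0, beta_C,
    beta_I, beta_pub); random intercepts are zero (average participant and
    starting location).
    """
    C, I = _level_dummies(level)
    P = 1.0 if context == "public" else 0.0
    try:
        eta = (np.asarray(draw["beta0"]) + np.asarray(draw["beta_C"]) * C
               + np.asarray(draw["beta_I"]) * I + np.asarray(draw["beta_pub"]) * P)
    except KeyError as exc:
        raise KeyError(f"mediator draw is missing coefficient {exc.args[0]!r}") from None
    return expit(eta)


def outcome_mean(draw: pd.DataFrame | dict, level: str, m, context: str) -> np.ndarray:
    """Expected pointing error ``exp(eta)`` at mediator value ``m``.

    Dwell covariates pinned at 0 on the z-scale; random intercepts zero.
    """
    m = np.asarray(m, float)
    if ((m <= 0) | (m >= 1)).any():
        raise ValueError("mediator value must lie strictly inside (0, 1)")
    C, I = _level_dummies(level)
    P = 1.0 if context == "public" else 0.0
    try:
        eta = (np.asarray(draw["beta0"]) + np.asarray(draw["beta_C"]) * C
               + np.asarray(draw["beta_I"]) * I + np.asarray(draw["beta_pub"]) * P
               + np.asarray(draw["beta_GTE"]) * m)
    except KeyError as exc:
        raise KeyError(f"outcome draw is missing coefficient {exc.args[0]!r}") from None
    return np.exp(eta)


def potential_outcomes(inp: MediationInput, treatment: str) -> pd.DataFrame:
    """Per-replication context-marginal Y00, Y10, Y11 for one contrast."""
    rng = np.random.default_rng(inp.seed)
    dm = inp.mediator_draws().reset_index(drop=True)
    dy = inp.outcome_draws().reset_index(drop=True)
    iM = rng.integers(len(dm), size=inp.replications)
    iY = rng.integers(len(dy), size=inp.replications)
    dM = dm.iloc[iM]
    dY = dy.iloc[iY]
    levels = {0: BASELINE, 1: treatment}
    cols = {}
    for j, k in ((0, 0), (1, 0), (1, 1)):
        y_ctx = []
        for context, w in (("residential", inp.w_res), ("public", inp.w_pub)):
            mu_m = mediator_mean(dM, levels[k], context)
            y_ctx.append(w * outcome_mean(dY, levels[j], mu_m, context))
        cols[f"Y{j}{k}"] = y_ctx[0] + y_ctx[1]
    out = pd.DataFrame(cols)
    if (out.to_numpy() <= 0).any():
        raise RuntimeError("potential outcomes must be strictly positive")
    return out


@dataclass
class MediationEffects:
    """Summaries (posterior mean, 95% equal-tailed CrI) plus per-draw effects."""

    treatment: str
    per_draw: pd.DataFrame
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for nm in ("NDE", "NIE", "TE", "RR_NDE", "RR_NIE", "RR_TE"):
            x = self.per_draw[nm].to_numpy()
            lo, hi = np.quantile(x, [0.025, 0.975])
            rows.append((nm, float(x.mean()), float(lo), float(hi)))
        self.summary = pd.DataFrame(rows, columns=["effect", "mean", "ci_lo", "ci_hi"])


def mediation_effects(po: pd.DataFrame, treatment: str = "") -> MediationEffects:
    """Natural effects and risk ratios per draw from potential outcomes."""
    if len(po) < 1:
        raise ValueError("need at least one replication")
    y00, y10, y11 = (po[c].to_numpy() for c in ("Y00", "Y10", "Y11"))
    per_draw = pd.DataFrame({
        "Y00": y00, "Y10": y10, "Y11": y11,
        "NDE": y10 - y00, "NIE": y11 - y10, "TE": y11 - y00,
        "RR_NDE": y10 / y00, "RR_NIE": y11 / y10, "RR_TE": y11 / y00,
    })
    return MediationEffects(treatment=treatment, per_draw=per_draw)


def run_mediation(inp: MediationInput) -> dict[str, MediationEffects]:
    """Full g-computation for both treatment contrasts vs. acontextual."""
    out = {}
    for treatment in TREATMENTS:
        po = potential_outcomes(inp, treatment)
        out[treatment] = mediation_effects(po, treatment)
    return out


def true_effects(
    mediator_coefs: dict, outcome_coefs: dict, treatment: str,
    w_res: float = 0.5, w_pub: float = 0.5,
) -> dict[str, float]:
    """Closed-form effects from generating coefficients (no posterior).

    Plugs the true coefficient values through the same g-formula, giving the
    ground truth that an end-to-end mediation analysis should recover.
    """
    po = {}
    levels = {0: BASELINE, 1: treatment}
    for j, k in ((0, 0), (1, 0), (1, 1)):
        tot = 0.0
        for context, w in (("residential", w_res), ("public", w_pub)):
            mu_m = mediator_mean(
                {n: np.array([v]) for n, v in mediator_coefs.items()},
                levels[k], context)
            tot += w * float(outcome_mean(
                {n: np.array([v]) for n, v in outcome_coefs.items()},
                levels[j], mu_m, context)[0])
        po[f"Y{j}{k}"] = tot
    return {
        "NDE": po["Y10"] - po["Y00"], "NIE": po["Y11"] - po["Y10"],
        "TE": po["Y11"] - po["Y00"],
        "RR_NDE": po["Y10"] / po["Y00"], "RR_NIE": po["Y11"] / po["Y10"],
        "RR_TE": po["Y11"] / po["Y00"],
    }
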