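"""End-to-end orchestration: simulate -> classify -> entropy -> windows ->
describe -> fit -> mediate -> report.

Each stage reads the previous stage's tables, writes CSV outputs under the
run directory, and records row counts, seeds and file digests in a manifest.
A single global seed fans out deterministically to per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import descriptives, mediation, models, windows
from .entropy import AGENT_CATEGORIES, gte
from .fixations import accumulate_dwell, classify_fixations, fixations_to_frame, frame_to_fixations
from .synthetic import AGENT_CATEGORY, SimConfig, simulate_gaze_session, simulate_mediation_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "entropy", "windows", "describe", "fit", "mediate")

_CAT_TO_TYPE = {v: k for k, v in AGENT_CATEGORY.items()}


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    profile: str = "test"
    n_participants: int = 4
    n_sessions: int = 2
    session_length: float = 300.0
    window: float = 30.0
    n_trials: int = 600
    mediation_reps: int = 1000
    stages: tuple[str, ...] = STAGES
    sim: SimConfig | None = None

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.sim is None:
            self.sim = SimConfig(
                n_participants=self.n_participants,
                n_sessions=self.n_sessions,
                session_length=self.session_length,
                seed=self.seed,
            )
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> dict:
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
    return {"path": str(path), "rows": len(df), "sha256": _digest(path)}


def _session_condition(session: int) -> str:
    # conditions alternate across sessions (agent placement varies by session)
    return ("congruent", "incongruent", "acontextual")[session % 3]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "profile": config.profile, "stages": {}}
    t_start = time.time()

    fixlogs: dict[tuple, pd.DataFrame] = {}
    truths: dict[tuple, object] = {}
    entropy_rows = []
    encounter_frames = []
    posteriors: dict[str, models.Posterior] = {}
    trials = mediator_tab = None

    def record(stage: str, outputs: list[dict], **extra) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "outputs": outputs,
            "elapsed_s": round(time.time() - t_start, 2),
            **extra,
        }
        logger.info(json.dumps({"stage": stage, **manifest["stages"][stage]}))

    # ---- simulate --------------------------------------------------------
    samples_by_key: dict[tuple, pd.DataFrame] = {}
    if "simulate" in config.stages:
        sseed = stage_seed(config.seed, "simulate")
        outputs = []
        truth_frames = []
        for p in range(config.n_participants):
            for s in range(config.n_sessions):
                seed = int(np.random.SeedSequence([sseed, p, s]).generate_state(1)[0] % 2**31)
                samples, truth = simulate_gaze_session(
                    config.sim, p, s, condition=_session_condition(s), seed=seed)
                samples_by_key[(p, s)] = samples
                truths[(p, s)] = truth
                tf = truth.fixation_log.copy()
                tf.insert(0, "participant", p)
                tf.insert(1, "session", s)
                tf["condition"] = truth.condition
                truth_frames.append(tf)
        truth_df = pd.concat(truth_frames, ignore_index=True)
        outputs.append(_write(truth_df, out / "ground_truth_fixations.csv"))
        record("simulate", outputs, n_sessions=len(samples_by_key))

    # ---- classify --------------------------------------------------------
    if "classify" in config.stages:
        frames = []
        for (p, s), samples in samples_by_key.items():
            fixes = classify_fixations(samples)
            df = fixations_to_frame(fixes)
            df.insert(0, "participant", p)
            df.insert(1, "session", s)
            frames.append(df)
            fixlogs[(p, s)] = df
        fix_df = pd.concat(frames, ignore_index=True)
        record("classify", [_write(fix_df, out / "fixations.csv")])

    # ---- entropy ---------------------------------------------------------
    if "entropy" in config.stages:
        for (p, s), df in fixlogs.items():
            res = gte(df["category"].tolist())
            row = {"participant": p, "session": s,
                   "condition": _session_condition(s),
                   "H_global": res.H_global, "H_norm": res.H_norm,
                   "pi_method": res.pi_method}
            for i, lab in enumerate(res.labels):
                row[f"H_{lab}"] = res.H_row[i] / np.log2(len(res.labels))
            entropy_rows.append(row)
        ent_df = pd.DataFrame(entropy_rows)
        record("entropy", [_write(ent_df, out / "entropy_by_session.csv")])

    # ---- windows ---------------------------------------------------------
    if "windows" in config.stages:
        for (p, s), df in fixlogs.items():
            enc = windows.encounter_table(
                frame_to_fixations(df), (0.0, config.session_length),
                window=config.window, participant=p, session=s)
            encounter_frames.append(enc)
        enc_df = pd.concat(encounter_frames, ignore_index=True)
        record("windows", [_write(enc_df, out / "encounters.csv")],
               n_encounters=len(enc_df))

    # ---- describe --------------------------------------------------------
    if "describe" in config.stages:
        per_agent = build_per_agent_table(fixlogs)
        summ = descriptives.condition_summaries(per_agent)
        outputs = [_write(per_agent, out / "per_agent.csv"),
                   _write(summ, out / "kde_summaries.csv")]
        corr_rows = []
        for cond, grp in per_agent.groupby("agent_type"):
            if len(grp.dropna()) >= 3:
                cm = descriptives.correlation_matrix(grp)
                cm2 = cm.reset_index(names="var")
                cm2.insert(0, "agent_type", cond)
                corr_rows.append(cm2)
        if corr_rows:
            outputs.append(_write(pd.concat(corr_rows, ignore_index=True),
                                  out / "correlations.csv"))
        record("describe", outputs)

    # ---- fit -------------------------------------------------------------
    if "fit" in config.stages:
        fseed = stage_seed(config.seed, "fit")
        datasets = build_model_datasets(config, fixlogs, encounter_frames, seed=fseed)
        trials = datasets["trials"]
        mediator_tab = datasets["mediator"]
        outputs = []
        for i, name in enumerate(("DWELL", "PREPOST", "POSTGTE", "PERF", "MEDIATOR")):
            data = datasets[name]
            post = models.fit_model(name, data, profile=config.profile,
                                    seed=(fseed + i) % 2**31)
            posteriors[name] = post
            summ = models.summarize_posterior(
                post, prob=models.MODEL_SPECS[name].default_hdi_prob())
            outputs.append(_write(summ, out / f"fit_{name.lower()}_summary.csv"))
            outputs.append(_write(post.draws, out / f"fit_{name.lower()}_draws.parquet"))
        record("fit", outputs,
               converged={k: v.converged for k, v in posteriors.items()})

    # ---- mediate ---------------------------------------------------------
    if "mediate" in config.stages:
        w_pub = float((trials["building_type"] == "public").mean()) if trials is not None else 0.5
        inp = mediation.MediationInput(
            mediator_posterior=posteriors["MEDIATOR"],
            outcome_posterior=posteriors["PERF"],
            w_res=1.0 - w_pub, w_pub=w_pub,
            replications=config.mediation_reps,
            seed=stage_seed(config.seed, "mediate"),
        )
        effects = mediation.run_mediation(inp)
        frames = []
        for treatment, eff in effects.items():
            s = eff.summary.copy()
            s.insert(0, "contrast", treatment)
            frames.append(s)
        med_df = pd.concat(frames, ignore_index=True)
        record("mediate", [_write(med_df, out / "mediation_effects.csv")],
               w_pub=w_pub)

    manifest["n_stages"] = len(manifest["stages"])
    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def build_per_agent_table(fixlogs: dict[tuple, pd.DataFrame]) -> pd.DataFrame:
    """Per (participant, agent object) dwell, count and category GTE rows."""
    rows = []
    for (p, s), df in fixlogs.items():
        res = gte(df["category"].tolist())
        h_norm_row = {lab: res.H_row[i] / np.log2(len(res.labels))
                      for i, lab in enumerate(res.labels)}
        dwell = accumulate_dwell(frame_to_fixations(df), p)
        ag = dwell[dwell["category"].isin(AGENT_CATEGORIES)]
        for r in ag.itertuples():
            rows.append((p, s, r.object_id, _CAT_TO_TYPE[r.category],
                         r.total_dwell, r.fixation_count, h_norm_row[r.category]))
    return pd.DataFrame(rows, columns=[
        "participant", "session", "agent_id", "agent_type",
        "total_dwell", "fixation_count", "gte"])


def build_model_datasets(
    config: PipelineConfig,
    fixlogs: dict[tuple, pd.DataFrame],
    encounter_frames: list[pd.DataFrame],
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Assemble the five analysis datasets from pipeline outputs.

    DWELL, PREPOST and POSTGTE come from the classified fixations and the
    encounter windows; the pointing task is not part of the gaze sessions, so
    PERF and MEDIATOR use the trial generator with shared keys.
    """
    # DWELL: per-object dwell rows; buildings inherit the session's condition
    dwell_rows = []
    for (p, s), df in fixlogs.items():
        cond = _session_condition(s)
        dw = accumulate_dwell(frame_to_fixations(df), p)
        for r in dw.itertuples():
            if r.category is None:
                continue
            is_agent = r.category in AGENT_CATEGORIES
            atype = _CAT_TO_TYPE[r.category] if is_agent else cond
            dwell_rows.append((p, s, int(is_agent), atype, r.total_dwell))
    dwell_df = pd.DataFrame(dwell_rows, columns=[
        "participant", "session", "object_kind", "agent_type", "dwell"])
    dwell_df = dwell_df[dwell_df["dwell"] > 0]

    enc = pd.concat(encounter_frames, ignore_index=True) if encounter_frames else pd.DataFrame()
    pre = enc.dropna(subset=["gte_pre"]).copy()
    post = enc.dropna(subset=["gte_post"]).copy()
    n_pp = len(pre) + len(post)
    prepost_df = pd.concat([
        pd.DataFrame({"participant": pre["participant"], "session": pre["session"],
                      "k": pre["encounter_index"], "prepost": 0,
                      "H": models.sv_transform(pre["gte_pre"].to_numpy(), max(n_pp, 2))}),
        pd.DataFrame({"participant": post["participant"], "session": post["session"],
                      "k": post["encounter_index"], "prepost": 1,
                      "H": models.sv_transform(post["gte_post"].to_numpy(), max(n_pp, 2))}),
    ], ignore_index=True)

    postgte_df = pd.DataFrame({
        "participant": post["participant"], "session": post["session"],
        "agent_type": post["agent_type"],
        "H": models.sv_transform(post["gte_post"].to_numpy(), max(len(post), 2)),
    })

    mediator_tab, trials = simulate_mediation_dataset(config.sim, config.n_trials, seed=seed)
    trials = trials.copy()
    trials["error"] = models.floor_pointing_errors(trials["error"])
    return {
        "DWELL": dwell_df, "PREPOST": prepost_df, "POSTGTE": postgte_df,
        "PERF": trials, "MEDIATOR": mediator_tab,
        "mediator": mediator_tab, "trials": trials,
    }


def report(manifest: dict, outdir: Path | None = None) -> dict[str, pd.DataFrame]:
    """Assemble stage outputs into result tables; gaps are reported, not fatal."""
    outdir = Path(outdir) if outdir is not None else Path(
        manifest["stages"]["simulate"]["outputs"][0]["path"]).parent
    tables: dict[str, pd.DataFrame] = {}
    gaps = []

    def load(name: str) -> pd.DataFrame | None:
        p = outdir / name
        if not p.exists():
            gaps.append(name)
            return None
        return pd.read_csv(p)

    ent = load("entropy_by_session.csv")
    if ent is not None:
        tables["gte_by_condition"] = ent.groupby("condition")["H_norm"].agg(
            ["mean", "std", "count"]).reset_index()
    enc = load("encounters.csv")
    if enc is not None:
        pp = enc[["gte_pre", "gte_post"]].dropna()
        tables["prepost_entropy"] = pd.DataFrame({
            "window": ["pre", "post"],
            "mean": [pp["gte_pre"].mean(), pp["gte_post"].mean()],
            "sd": [pp["gte_pre"].std(), pp["gte_post"].std()],
            "n": [len(pp), len(pp)],
        })
    kde = load("kde_summaries.csv")
    if kde is not None:
        tables["kde_summaries"] = kde
    corr = load("correlations.csv")
    if corr is not None:
        tables["correlations"] = corr
    for name in ("dwell", "prepost", "postgte", "perf", "mediator"):
        df = load(f"fit_{name}_summary.csv")
        if df is None:
            continue
        link = "log" if name in ("dwell", "perf") else "logit"
        is_coef = df["coefficient"].str.startswith(("beta", "gamma"))
        df["effect"] = np.where(
            is_coef,
            [models.effect_transform(b, link,
                                     "percent_change" if link == "log" else "odds_ratio")
             if c.startswith(("beta", "gamma")) else np.nan
             for b, c in zip(df["mean"], df["coefficient"])],
            np.nan,
        )
        df["effect_unit"] = np.where(is_coef,
                                     "percent_change" if link == "log" else "odds_ratio", "")
        tables[f"model_{name}"] = df
    med = load("mediation_effects.csv")
    if med is not None:
        tables["mediation"] = med
        for contrast, grp in med.groupby("contrast"):
            g = grp.set_index("effect")["mean"]
            resid = g["TE"] - (g["NDE"] + g["NIE"])
            if abs(resid) > 1e-8:
                logger.warning("mediation identity residual %g for %s", resid, contrast)
    if gaps:
        tables["gaps"] = pd.DataFrame({"missing": gaps})
        logger.warning("report has gaps: %s", gaps)
    if outdir is not None:
        for name, df in tables.items():
            _write(df, outdir / "report" / f"{name}.csv")
    return tables
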