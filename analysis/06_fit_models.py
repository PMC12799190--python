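"""Fit the five Bayesian hierarchical models.

Dwell, pre/post-entropy and post-entropy datasets come from the classified
fixations and encounter windows of this run; the pointing task is a separate
session, so the performance and mediator datasets are generated at the study
coefficients with shared participant/location keys.  Posterior draws land in
results/run/fit_<model>_draws.parquet, summaries in CSV.
"""

import sys
from pathlib import Path

import pandas as pd

from gazeflow import models
from gazeflow.pipeline import PipelineConfig, build_model_datasets, stage_seed

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
PROFILE = sys.argv[2] if len(sys.argv) > 2 else "test"
OUT = Path("results/run")

fix_df = pd.read_csv(OUT / "fixations.csv")
fixlogs = {k: g for k, g in fix_df.groupby(["participant", "session"])}
enc = pd.read_csv(OUT / "encounters.csv")

config = PipelineConfig(outdir=OUT, seed=SEED, profile=PROFILE,
                        n_participants=4, n_sessions=2, session_length=600.0,
                        n_trials=1500)
fseed = stage_seed(SEED, "fit")
datasets = build_model_datasets(config, fixlogs, [enc], seed=fseed)
datasets["trials"].to_csv(OUT / "pointing_trials.csv", index=False)

for i, name in enumerate(("DWELL", "PREPOST", "POSTGTE", "PERF", "MEDIATOR")):
    data = datasets[name]
    post = models.fit_model(name, data, profile=PROFILE, seed=(fseed + i) % 2**31)
    prob = models.MODEL_SPECS[name].default_hdi_prob()
    summ = models.summarize_posterior(post, prob=prob)
    summ.to_csv(OUT / f"fit_{name.lower()}_summary.csv", index=False)
    post.draws.to_parquet(OUT / f"fit_{name.lower()}_draws.parquet", index=False)
    print(f"\n{name} (n={len(data)}, {int(prob * 100)}% HDI, "
          f"converged={post.converged}):")
    print(summ.round(3).to_string(index=False))
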