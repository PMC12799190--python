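"""Generate the synthetic study: 90 Hz gaze sessions for every participant.

Four participants explore the virtual city for two 600-s sessions each
(conditions alternate with session, as agent placement did across the two
experiments).  Raw samples go to results/run/samples.parquet, the generating
fixation log to results/run/ground_truth_fixations.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from gazeflow.pipeline import _session_condition, stage_seed
from gazeflow.synthetic import SimConfig, simulate_gaze_session

import numpy as np

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/run")
OUT.mkdir(parents=True, exist_ok=True)

N_PARTICIPANTS, N_SESSIONS, SESSION_LENGTH = 4, 2, 600.0

config = SimConfig(n_participants=N_PARTICIPANTS, n_sessions=N_SESSIONS,
                   session_length=SESSION_LENGTH, seed=SEED)
sseed = stage_seed(SEED, "simulate")

samples_frames, truth_frames = [], []
for p in range(N_PARTICIPANTS):
    for s in range(N_SESSIONS):
        seed = int(np.random.SeedSequence([sseed, p, s]).generate_state(1)[0] % 2**31)
        samples, truth = simulate_gaze_session(
            config, p, s, condition=_session_condition(s), seed=seed)
        samples.insert(0, "participant", p)
        samples.insert(1, "session", s)
        samples_frames.append(samples)
        tf = truth.fixation_log.copy()
        tf.insert(0, "participant", p)
        tf.insert(1, "session", s)
        tf["condition"] = truth.condition
        truth_frames.append(tf)

samples_df = pd.concat(samples_frames, ignore_index=True)
truth_df = pd.concat(truth_frames, ignore_index=True)
samples_df.to_parquet(OUT / "samples.parquet", index=False)
truth_df.to_csv(OUT / "ground_truth_fixations.csv", index=False)

print(f"simulated {N_PARTICIPANTS * N_SESSIONS} sessions "
      f"({len(samples_df):,} gaze samples, {len(truth_df):,} fixations)")
print("fixations per condition:")
print(truth_df.groupby("condition").size().to_string())
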