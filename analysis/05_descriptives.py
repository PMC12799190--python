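"""Exploration-exploitation descriptives per agent condition.

Per-agent dwell, fixation count and category GTE rows; KDE mode / centroid /
FWHM summaries; dwell-count-GTE Pearson correlation matrices.  Writes three
tables under results/run/ and prints the KDE summary.
"""

from pathlib import Path

import pandas as pd

from gazeflow import descriptives
from gazeflow.pipeline import build_per_agent_table

OUT = Path("results/run")
fix_df = pd.read_csv(OUT / "fixations.csv")
fixlogs = {k: g for k, g in fix_df.groupby(["participant", "session"])}

per_agent = build_per_agent_table(fixlogs)
per_agent.to_csv(OUT / "per_agent.csv", index=False)

summ = descriptives.condition_summaries(per_agent)
summ.to_csv(OUT / "kde_summaries.csv", index=False)

corr_frames = []
for cond, grp in per_agent.groupby("agent_type"):
    if len(grp.dropna()) >= 3:
        cm = descriptives.correlation_matrix(grp).reset_index(names="var")
        cm.insert(0, "agent_type", cond)
        corr_frames.append(cm)
if corr_frames:
    pd.concat(corr_frames, ignore_index=True).to_csv(
        OUT / "correlations.csv", index=False)

print(f"{len(per_agent)} per-agent rows")
print(summ.round(3).to_string(index=False))
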