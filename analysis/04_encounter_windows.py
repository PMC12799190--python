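"""Agent-locked 30-s pre/post windows and their local entropy.

Reads results/run/fixations.csv, writes results/run/encounters.csv, and
prints the paired post-minus-pre window GTE contrast that the pre/post
regression will model.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gazeflow.fixations import frame_to_fixations
from gazeflow.windows import encounter_table

OUT = Path("results/run")
SESSION_LENGTH = 600.0

fix_df = pd.read_csv(OUT / "fixations.csv")
frames = []
for (p, s), grp in fix_df.groupby(["participant", "session"]):
    frames.append(encounter_table(frame_to_fixations(grp),
                                  (0.0, SESSION_LENGTH),
                                  participant=p, session=s))
enc = pd.concat(frames, ignore_index=True)
enc.to_csv(OUT / "encounters.csv", index=False)

paired = enc.dropna(subset=["gte_pre", "gte_post"])
diff = paired["gte_post"] - paired["gte_pre"]
se = diff.std() / np.sqrt(len(diff))
print(f"{len(enc)} encounters retained ({len(paired)} with both windows)")
print(f"window GTE pre {paired['gte_pre'].mean():.3f}, "
      f"post {paired['gte_post'].mean():.3f}; "
      f"paired diff {diff.mean():+.3f} +- {se:.3f} (SE)")
print(enc.groupby("agent_type")["gte_post"].mean().round(3).to_string())
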