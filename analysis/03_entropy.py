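"""Per-session gaze transition entropy over the 8 visual categories.

Reads results/run/fixations.csv, writes results/run/entropy_by_session.csv
(global and per-category normalized GTE), and prints condition means.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gazeflow.entropy import gte
from gazeflow.pipeline import _session_condition

OUT = Path("results/run")
fix_df = pd.read_csv(OUT / "fixations.csv")

rows = []
for (p, s), grp in fix_df.groupby(["participant", "session"]):
    res = gte(grp["category"].tolist())
    row = {"participant": p, "session": s, "condition": _session_condition(s),
           "H_global": res.H_global, "H_norm": res.H_norm,
           "pi_method": res.pi_method}
    for i, lab in enumerate(res.labels):
        row[f"H_{lab}"] = res.H_row[i] / np.log2(len(res.labels))
    rows.append(row)
ent = pd.DataFrame(rows)
ent.to_csv(OUT / "entropy_by_session.csv", index=False)

print("normalized GTE by condition (mean +- sd):")
for cond, grp in ent.groupby("condition"):
    print(f"  {cond:<12} {grp['H_norm'].mean():.3f} +- {grp['H_norm'].std():.3f} "
          f"(n={len(grp)})")
agent_cols = [c for c in ent.columns if c.startswith("H_agent")]
print("per-category agent GTE means:",
      {c.removeprefix('H_'): round(ent[c][ent[c] > 0].mean(), 3) for c in agent_cols})
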