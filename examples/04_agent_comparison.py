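"""Compare the four agent types on the default task (small groups).

Five replicas per type keep this quick; the expected pattern is
EFE ~ ADP > IV > RC in the EV+ variants and IV > ADP > EFE in EV-,
the signature of the exploration-exploitation trade-off built into the task.
"""

import numpy as np

from metabandit import AgentSpec, TaskConfig, run_group

cfg = TaskConfig()
for typ in ("efe", "iv", "adp", "rc"):
    logs = run_group(AgentSpec(type=typ, duration_prior="precise"), 5, cfg,
                     master_seed=3)
    seg = [l.segments.iloc[100:] for l in logs]
    evp = np.mean([s.loc[s["ev_plus"], "success"].mean() for s in seg])
    evm = np.mean([s.loc[~s["ev_plus"], "success"].mean() for s in seg])
    print(f"{typ.upper():>3}: success EV+ {evp:.2f}   EV- {evm:.2f}")
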