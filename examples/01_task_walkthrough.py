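"""Walk through the task's generative process for one segment.

Builds the six-context option-outcome table, prints the structure of context
pair 3, then plays one five-trial segment with a fixed option and shows how
points accumulate into a segment outcome.
"""

import numpy as np

from metabandit import TaskConfig, TaskEnvironment, default_context_tables
from metabandit.task import context_label

table = default_context_tables()
print("Option-outcome probabilities, contexts 3:EV- and 3:EV+")
print("(rows: options 1-4; columns: no-point, blue, red)\n")
for c in (5, 6):
    print(f"context {context_label(c)}:")
    print(np.array_str(table.probs[c - 1], precision=2), "\n")

env = TaskEnvironment(TaskConfig(), rng=1)
print(f"segment 1, true context {context_label(env.context)};"
      " playing option 1 five times:")
for t in range(5):
    obs = env.step(1)
    kind = {1: "nothing", 2: "blue point", 3: "red point"}[obs.h]
    print(f"  trial {t + 1}: {kind:>10}, totals (blue, red) = "
          f"({int(obs.w[0])}, {int(obs.w[1])})")
result = env.end_segment()
print(f"segment outcome: {'success' if result.success else 'failure'} "
      "(needs >= 4 points of one colour)")
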