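"""Behavioral preprocessing: key-hold streams to the analysis trial table.

Shows the time-weighted pleasantness index, the halting rule (no response
within the first half of the excerpt), familiarity-based rejection
(exposure rating above 2) and the per-subject median split.
"""

import pandas as pd

from thetasync.behavior import (
    RatingStream,
    assemble_trial_table,
    median_split,
    time_weighted_pleasantness,
)

# one listener holds key 3 for 10 s, then key 5 for 30 s
s = RatingStream("demo", ((3, 0.0, 10.0), (5, 10.0, 40.0)), 45.0)
print("time-weighted pleasantness (3 for 10 s, 5 for 30 s):",
      time_weighted_pleasantness(s))          # (3*10 + 5*30)/40 = 4.5

late = RatingStream("late", ((4, 23.0, 40.0),), 45.0)
print("first key press at 23 s of 45 s ->", time_weighted_pleasantness(late),
      "(trial halted and rejected)")

print("median split of [2, 3, 4]:", list(median_split([2, 3, 4])))

# a 10-excerpt mini-session with one already-familiar excerpt
streams = {
    ("S0", f"E{i}"): RatingStream(f"E{i}", ((1 + i % 5, 1.0, 40.0),), 45.0)
    for i in range(10)
}
cond = pd.DataFrame(
    [("S0", f"E{i}", "old" if i < 5 else "new") for i in range(10)],
    columns=["subject", "excerpt_id", "familiarity_condition"],
)
expo = pd.DataFrame(
    [("S0", f"E{i}", 3 if i == 1 else 1) for i in range(5)],
    columns=["subject", "excerpt_id", "rating"],
)
expe = pd.DataFrame(
    [("S0", f"E{i}", 1) for i in range(10)],
    columns=["subject", "excerpt_id", "rating"],
)
table = assemble_trial_table(streams, cond, expo, expe)
print("\ntrial table (E1 was rated familiar at exposure):")
print(table[["excerpt_id", "familiarity_condition", "pleasantness_index",
             "pleasantness_class", "retained", "rejection_reason"]].to_string(index=False))
print(f"rejected proportion: {1 - table['retained'].mean():.2f}")
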