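"""Metastasis-free survival by instability grade on a synthetic cohort.

Kaplan-Meier curves per grade and the two-group log-rank comparison,
with the hazard ratio computed from observed/expected event counts.
"""

import numpy as np
import pandas as pd

from g2i import SimulationConfig, km_logrank, simulate_clone_map, simulate_cohort

clone_map = simulate_clone_map(5878, seed=1)
config = SimulationConfig(
    n_samples=120, seed=13,
    weights={"complex_e": 0.75, "firestorm_f": 0.25},
)
_, clinical, truths = simulate_cohort(config, clone_map=clone_map)

records = pd.DataFrame({
    "time": clinical["follow_up"],
    "event": clinical["relapse"],
    "group": [f"G2I-{t.grade}" for t in truths],
})
two = records[records["group"].isin(["G2I-3", "G2I-2"])]
result = km_logrank(two)
print(f"groups: { {g: int((two['group'] == g).sum()) for g in result.curves} }")
print(f"log-rank statistic {result.statistic:.2f}, p = {result.p_value:.2g}")
print(f"hazard ratio (O/E), G2I-3 vs G2I-2: {result.hazard_ratio:.2f}")
for group, curve in result.curves.items():
    ten_year = curve[curve["time"] <= 120]["survival"].iloc[-1]
    print(f"10-year metastasis-free survival, {group}: {ten_year:.2f}")
# grade-3 tumors relapse early and often (planted rate 21/28 vs 23/88),
# so their curve drops steeply and the hazard ratio is well above 1
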