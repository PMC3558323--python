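"""Printed cross-tabulations from the 135-tumor development cohort.

The G2I index was developed on 135 invasive ductal breast carcinomas
(45 with metastatic relapse, 90 without, minimum follow-up 131 months);
its published association statistics derive from the contingency tables
below.  They are inputs to the statistics layer — everything downstream
(odds ratios, chi-square p-values) is recomputed from these counts, not
hard-coded.

All tables are integer count arrays; row/column meanings are documented
per table.  Grades are G2I-1 (stable), G2I-2, G2I-3 (unstable).
"""

from __future__ import annotations

import numpy as np

#: Relapse (col 0) vs no relapse (col 1) by grade; rows G2I-1, G2I-2, G2I-3.
#: Grade sizes 19 / 88 / 28, total 135 (45 relapses).
RELAPSE_BY_GRADE = np.array([
    [1, 18],
    [23, 65],
    [21, 7],
])

#: Node-negative subgroup: relapse vs no relapse, rows G2I-3 (20 tumors)
#: and G2I-2 (43 tumors).  Reconstructed from the published subgroup
#: rates: 16/20 G2I-3 pN0 tumors relapsed; 9/55 G2I-1+2 pN0 relapsed, of
#: which 1 of 12 were G2I-1, leaving 8/43 in G2I-2.
NODE_NEGATIVE_RELAPSE = np.array([
    [16, 4],
    [8, 35],
])

#: TP53 alteration (mutation or protein accumulation): rows altered /
#: not altered, columns G2I-1, G2I-2, G2I-3 (0/19, 24/88, 15/28 altered).
TP53_BY_GRADE = np.array([
    [0, 24, 15],
    [19, 64, 13],
])

#: SBR histological grade (rows 1, 2, 3) by G2I grade (columns 1, 2, 3).
SBR_BY_GRADE = np.array([
    [6, 15, 4],
    [12, 48, 11],
    [1, 25, 13],
])

#: At least one amplicon (rows no / yes) by G2I grade.
AMPLICON_BY_GRADE = np.array([
    [16, 47, 8],
    [3, 41, 20],
])

#: Mib1 proliferation index (rows <20% / >=20%) by G2I grade.
MIB1_BY_GRADE = np.array([
    [18, 60, 15],
    [1, 28, 13],
])

#: IHC intrinsic class (rows luminal A / LB+HER2+basal) by G2I grade;
#: two unclassifiable tumors excluded.
INTRINSIC_BY_GRADE = np.array([
    [16, 55, 12],
    [3, 31, 16],
])

#: Cohort amplicon catalogue totals: 296 amplicons across 135 tumors,
#: 64 of which carry at least one amplicon.
AMPLICON_TOTALS = {"amplicons": 296, "tumors": 135, "tumors_with_amplicons": 64}
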