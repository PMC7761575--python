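"""Published summary tables used as inputs for verification reports.

These are the printed joint isoform counts of the original survey (48
plants = 24 accessions x 2); they serve as fixed inputs for recomputing
the exact-test p-values and marginal frequencies, independently of any
simulation.
"""
from __future__ import annotations

import pandas as pd

# rows: GID1 isoforms, columns: RHT-1 isoforms
GID1_BY_RHT = pd.DataFrame(
    [[10, 22, 2, 2], [12, 0, 0, 0]],
    index=pd.Index(["A", "B"], name="GID1"),
    columns=pd.Index(["A", "B", "C", "D"], name="RHT-1"),
)

# rows: GID2 isoforms, columns: RHT-1 isoforms
GID2_BY_RHT = pd.DataFrame(
    [[14, 22, 2, 2], [8, 0, 0, 0]],
    index=pd.Index(["A", "B"], name="GID2"),
    columns=pd.Index(["A", "B", "C", "D"], name="RHT-1"),
)

# rows: GID2 isoforms, columns: GID1 isoforms
GID2_BY_GID1 = pd.DataFrame(
    [[33, 7], [3, 5]],
    index=pd.Index(["A", "B"], name="GID2"),
    columns=pd.Index(["A", "B"], name="GID1"),
)

# The exact tests were computed on the RHT {A, B} restriction (the rare C
# and D isoforms excluded); published two-sided p-values at 4 decimals.
PUBLISHED_P = {
    "gid1_by_rht": 0.0001,
    "gid2_by_rht": 0.0036,
    "gid2_by_gid1": 0.0166,
}

RESTRICTED_GID1_BY_RHT = GID1_BY_RHT[["A", "B"]]
RESTRICTED_GID2_BY_RHT = GID2_BY_RHT[["A", "B"]]
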