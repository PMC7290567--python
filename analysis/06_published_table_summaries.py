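#!/usr/bin/env python
"""Summary statistics of the packaged published-table transcriptions.

Recomputes, from the raw table rows, the pairwise percentage columns and the
multi-cell summaries (variant counts, homoplasmic/heteroplasmic split, bulk
confirmation, majority sharing) that the concordance analysis reports.
"""

import json
from pathlib import Path

from scmito import compare as cmp

OUT = Path("results")
OUT.mkdir(exist_ok=True)

out = {}
t1 = cmp.load_table1()
for _, row in t1.iterrows():
    out[f"pairwise_{row['Protocol']}"] = cmp.concordance_from_counts(
        int(row["All"]), int(row["Common"]), int(row["Confirmed"])
    )

out["nine_cell_wgs"] = cmp.table_stats(
    cmp.assay_view(cmp.load_table2(), "in_WGS", "maf_WGS"), n_cells=9
)
out["nine_cell_wes_n_variants"] = len(
    cmp.assay_view(cmp.load_table2(), "in_WES", "maf_WES")
)
out["atac_48_cell"] = cmp.table_stats(
    cmp.assay_view(cmp.load_table3(), "n_cells", "maf"), n_cells=48
)

print(json.dumps(out, indent=2))
(OUT / "published_table_summaries.json").write_text(json.dumps(out, indent=2))
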