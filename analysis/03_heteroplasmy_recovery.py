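#!/usr/bin/env python
"""Heteroplasmy quantification accuracy at deep coverage.

A cell carrying heteroplasmic SNPs at 10/30/50% plus homoplasmic variants is
sequenced at ~1000x; the pipeline's AF estimates are compared with truth.
Expected finding: every estimate sits within binomial sampling error of its
true fraction, and homoplasmic variants come back at AF ~ 1.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from scmito import studies

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")
OUT.mkdir(exist_ok=True)

res = studies.heteroplasmy_recovery(SEED)
sites = pd.DataFrame(res["sites"])
sites["binomial_se"] = np.sqrt(sites["h"] * (1 - sites["h"]) / sites["n"])
sites["z"] = sites["abs_error"] / sites["binomial_se"]
sites.to_csv(OUT / "heteroplasmy_recovery.tsv", sep="\t", index=False)
print(sites.to_string(index=False))
print(
    f"\nhomoplasmic truth variants recovered: {res['n_hom_recovered']}/{res['n_hom_true']}"
    f" (min AF {res['min_hom_af']:.4f})"
)
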