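"""Bin-based screening-array selection with pool-frequency quotas.

Partitions the genome into 100 kb bins, derives the per-bin budget from
the array capacity, and fills bins from p-convert-categorized candidates,
balancing Flint-specific, Dent-specific, common and rare variants.
"""

import numpy as np
import pandas as pd

from maizearray import binning

# the published design arithmetic: 2.066 Gb at 100 kb -> 20,660 bins;
# 1.23 M capacity minus fixed coding and legacy content -> 48 per bin
bins = binning.partition_bins(2_066_000_000, 100_000)
budget = binning.compute_bin_budget(1_230_000, 150_394, 2 * 48_324, len(bins))
print(f"{len(bins):,} bins of 100 kb; average budget {budget} variants/bin")

# a synthetic candidate table for one 1 Mb chromosome
rng = np.random.default_rng(3)
n = 2000
cand = pd.DataFrame({
    "variant_id": [f"v{i}" for i in range(n)],
    "chrom": "chr1",
    "pos": np.sort(rng.choice(np.arange(1, 1_000_001), n, replace=False)),
    "pconvert_category": rng.choice(
        ["recommended", "neutral", "not recommended"], n, p=[0.45, 0.35, 0.2]),
    "dent_class": rng.choice(["A", "B"], n),
    "flint_class": rng.choice(["A", "B"], n),
})

selected, log = binning.assemble_bins(cand, bin_width=100_000,
                                      budget=budget, seed=3)
print(f"selected {len(selected)} of {n} candidates across "
      f"{cand['pos'].max() // 100_000 + 1} bins")
cells = selected.groupby(["dent_class", "flint_class"]).size()
print("quota cells (Dent class, Flint class):")
print(cells.to_string())
# (A,B) is Flint-specific, (B,A) Dent-specific, (A,A) common, (B,B) rare;
# the 1/3, 1/3, 1/6, 1/6 quotas show through wherever a draw was needed.
if log:
    print(f"{len(log)} quota-shortfall redistributions logged, e.g. {log[0]}")
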