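"""The voting system: from screened variants to the final array content.

Forwards doubly-stable PolyHighResolution variants, selects stable OTVs
passing the custom metric cuts, ranks the remainder by
35 x class weight + 90 x sequence concordance + 10 x bin representation,
and assembles the final design with its density and annotation summary.
"""

import numpy as np
import pandas as pd

from maizearray import clustering, design, simulate

genome = simulate.simulate_genome(seed=5)
panel = simulate.default_panel()
truth = simulate.simulate_panel(genome, panel, n_variants=400, seed=5)
intensities = simulate.simulate_intensities(truth, seed=5)
seq = simulate.simulate_sequencing_calls(truth, paralog_fraction=0.0,
                                         genotype_error_rate=0.01, seed=5)
sheet = simulate.sample_sheet(panel)
res_off = clustering.genotype_panel(intensities, sheet, inbred_correction=False)
res_on = clustering.genotype_panel(intensities, sheet, inbred_correction=True)

tdf = truth.variants.set_index("variant_id")
cats = pd.DataFrame({
    "variant_id": res_off.metrics["variant_id"],
    "category_nocorr": res_off.metrics["category"],
    "category_corr": res_on.metrics.set_index("variant_id")
                     .loc[res_off.metrics["variant_id"], "category"].to_numpy(),
})
phr = design.forward_phr_stable(cats)
otv = design.select_otv_stable(cats, res_on.metrics)
print(f"forwarded PHR-stable: {len(phr)}  forwarded OTV-stable: {len(otv)}")

order = [res_on.variant_ids.index(v) for v in tdf.index]
conc, _ = design.sequence_concordance(
    res_on.calls[:, order], seq.genotypes.T, res_on.samples, seq.samples
)
weights = [clustering.class_weight(clustering.compare_correction(b, a))
           for b, a in zip(cats["category_nocorr"], cats["category_corr"])]
ranked = pd.DataFrame({
    "variant_id": cats["variant_id"],
    "rank": [design.rank_variant(w, float(np.clip(c, 0, 1)), 0.0)
             for w, c in zip(weights, conc)],
})

target = len(set(phr) | set(otv)) + 30  # leave room for ranked fill-up
final = design.assemble_final(phr, otv, ranked, target_size=target, seed=5)
print(f"final design: {final.composition}")

sel = tdf.loc[final.variants['variant_id'], ["chrom", "pos"]].reset_index()
dens = design.density_stats(sel, genome.chrom_lengths)
print(f"mean density: one variant per {dens['mean_density_kb']:.1f} kb; "
      f"largest gap {dens['max_gap_kb']:.1f} kb")
table, summary = design.annotate_variants(sel, genome.genes)
print(f"genes tagged: {summary['pct_tagged_genic']:.1f} % "
      f"(with 5 kb flanks: {summary['pct_tagged_with_flanks']:.1f} %)")
# Forwarded variants enter unconditionally; the ranked remainder fills the
# design in score order, so raising the target only appends lower ranks.
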