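"""Detect and mask an introgression planted in a reference accession.

A reference mandarin-side accession is given a heterozygous MAX block;
the windowed heterozygosity scan flags it, the mask converts it to
missing data, and the diagnostic-marker count recovers.
"""

import numpy as np

from phylokaryo import AncestrySpec, simulate_reference_panel, simulate_ancestral_model
from phylokaryo.dp import compute_gst_ret_max
from phylokaryo.introgression import scan_reference_panel
from phylokaryo.stats import taxon_centroid

model = simulate_ancestral_model(n_chrom=2, loci_per_chrom=1000, seed=21)
L = model.chrom_lengths["1"]
block = (8_000_000, 20_000_000)
spec = AncestrySpec.pure("ret01", "RET", model.chrom_lengths).with_block(
    "1", *block, "MAX", homologs=(0,)
)
gm, panel, _ = simulate_reference_panel(model, introgressions={"ret01": spec},
                                        seed=22)

gst1 = compute_gst_ret_max(gm, panel)  # first pass, references taken at face value
cen_ret = taxon_centroid(gm, panel.ret_refs)
cen_max = taxon_centroid(gm, panel.max_refs)
masks = scan_reference_panel(gm, panel, cen_ret, cen_max, gst1)

print(f"planted introgression in ret01: chr1:{block[0]}-{block[1]}")
for chrom, ivs in masks.for_sample("ret01").items():
    for s, e in ivs:
        print(f"detected mask interval:      chr{chrom}:{s}-{e}")

gst2 = compute_gst_ret_max(gm, panel, masks)
n1 = int(np.nansum(gst1 >= 0.9))
n2 = int(np.nansum(gst2 >= 0.9))
print(f"\nloci at G_ST >= 0.9 before masking: {n1}, after masking: {n2}")
# The contaminated reference drags G_ST below the diagnostic threshold
# inside the block; masking its calls there restores those loci.
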