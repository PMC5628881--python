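"""Build a small synthetic two-taxon dataset with known ancestry.

Draws an ancestral frequency model (two chromosomes here for speed),
reference accessions of both taxa, an F1 and a first-backcross query,
injects GBS-like missing data, and prints what the truth looks like.
"""

import numpy as np

from phylokaryo import (
    AncestrySpec,
    inject_missingness,
    simulate_ancestral_model,
    simulate_queries,
    simulate_reference_panel,
)
from phylokaryo.simulate import RET, combine_panels

model = simulate_ancestral_model(n_chrom=2, loci_per_chrom=1000, seed=42)
print(f"model: {model.n_loci} loci on {len(model.chroms)} chromosomes, "
      f"{int(model.fixed_difference().sum())} fixed inter-taxon differences")
print(f"mean true G_ST between taxa: {np.nanmean(model.true_gst()):.3f}")

gm_refs, panel, _ = simulate_reference_panel(model, seed=43)
rng = np.random.default_rng(44)
specs = [
    AncestrySpec.f1("f1_hybrid", model.chrom_lengths),
    AncestrySpec.backcross("bc1_to_ret", 1, RET, model.chrom_lengths, rng),
]
gm_q, truth = simulate_queries(model, specs, seed=45)
gm = combine_panels(gm_refs, gm_q)
gm, _ = inject_missingness(gm, rate=0.126, seed=46)

print(f"\ngenotype matrix: {gm.n_samples} samples x {gm.n_loci} loci, "
      f"{gm.is_missing.mean():.1%} missing calls")
for name, spec in truth.specs.items():
    frac = spec.expected_prop_max(model.chrom_lengths)
    print(f"  {name}: pedigree {spec.pedigree}, true MAX genome fraction {frac:.3f}")
# The F1 carries one full homolog from each taxon (fraction 0.5); a first
# backcross to RET is expected to retain 0.5^2 = 25% MAX on average.
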