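"""Call- and locus-level filters applied before discovery.

The pipeline default composition is depth -> locus (missingness + MAF)
-> reference-missingness, mirroring a GBS post-calling cleanup: calls
supported by fewer than 5 reads are unreliable and become missing;
loci are then dropped when more than half the calls are missing or the
minor-allele frequency falls below 0.05; finally only loci with less
than 30% missing data among the reference accessions are retained.

All filters are idempotent and never alter surviving call values.
"""

from __future__ import annotations

import numpy as np

from .matrix import MISSING, DepthMatrix, GenotypeMatrix, SamplePanel


def apply_depth_threshold(
    gm: GenotypeMatrix, dm: DepthMatrix, min_reads: int = 5
) -> GenotypeMatrix:
    """Set calls supported by fewer than ``min_reads`` reads to missing."""
    if dm.reads.shape != gm.dosage.shape:
        raise ValueError(
            f"depth shape {dm.reads.shape} != genotype shape {gm.dosage.shape}"
        )
    out = gm.copy()
    out.dosage[dm.reads < min_reads] = MISSING
    return out


def locus_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per locus from non-missing dosages; NaN if no calls."""
    d = gm.dosage
    present = d != MISSING
    n_alleles = 2 * present.sum(axis=0)
    alt = np.where(present, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return np.minimum(p, 1.0 - p)


def filter_loci(
    gm: GenotypeMatrix, max_missing: float = 0.5, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Drop loci with missing fraction > ``max_missing`` or MAF < ``min_maf``.

    Both statistics are computed over all samples.  The MAF boundary is
    inclusive (a locus at exactly ``min_maf`` is retained); a locus with
    every call missing is removed by the missingness rule.
    """
    if gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    miss = gm.locus_missing_rate()
    maf = locus_maf(gm)
    keep = (miss <= max_missing) & ~np.isnan(maf) & (maf >= min_maf)
    return gm.take_loci(keep)


def filter_by_reference_missing(
    gm: GenotypeMatrix, panel: SamplePanel, max_ref_missing: float = 0.3
) -> GenotypeMatrix:
    """Keep loci whose missing fraction among reference samples is < threshold.

    Only RET_REF and MAX_REF samples are consulted; query missingness is
    irrelevant here.
    """
    refs = panel.ret_refs + panel.max_refs
    if not panel.ret_refs or not panel.max_refs:
        raise ValueError("panel must contain at least one RET_REF and one MAX_REF")
    panel.validate_against(gm)
    miss = gm.locus_missing_rate(refs)
    return gm.take_loci(miss < max_ref_missing)
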