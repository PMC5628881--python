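"""Diagnostic-polymorphism (DP) selection.

After introgressed regions of the reference accessions are masked, the
allele frequencies of the two ancestral taxa are re-estimated and Nei
G_ST between them (G_ST_ret-max) is computed per locus.  Loci with
G_ST_ret-max >= 0.9 are diagnostic of the two-taxon differentiation:
their major allele in each taxon indicates ancestral-species origin.
Only the first (anchor) position of each Indel enters the panel, so a
multi-position Indel contributes a single DP.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, MaskSet, SamplePanel
from .stats import allele_frequencies, nei_gst

logger = logging.getLogger(__name__)

DP_GST_THRESHOLD = 0.9

PANEL_COLUMNS = [
    "chrom",
    "pos",
    "ret_allele",
    "max_allele",
    "gst",
    "variant_class",
    "ret_is_alt",
    "locus_index",
]


def compute_gst_ret_max(
    gm: GenotypeMatrix, panel: SamplePanel, mask: MaskSet | None = None
) -> np.ndarray:
    """Per-locus Nei G_ST between the two reference taxa.

    With ``mask`` given, mask-covered reference calls are excluded from
    the frequency estimates (the masked, second-pass G_ST); without it
    this is the first-pass G_ST on raw reference data.  Loci undefined
    in either taxon are NaN.
    """
    panel.validate_against(gm, discovery=True)
    f_ret = allele_frequencies(gm, panel.ret_refs, mask)
    f_max = allele_frequencies(gm, panel.max_refs, mask)
    gst = nei_gst(f_ret.p_alt, f_max.p_alt)
    gst[~f_ret.defined | ~f_max.defined] = np.nan
    return gst


def _major_allele(p_alt: np.ndarray) -> np.ndarray:
    """+1 where alt is major, 0 where ref is major, -1 on an exact tie."""
    out = np.full(p_alt.shape, -1, dtype=np.int8)
    out[p_alt > 0.5] = 1
    out[p_alt < 0.5] = 0
    return out


def select_diagnostic_panel(
    gst: np.ndarray,
    gm: GenotypeMatrix,
    panel: SamplePanel,
    threshold: float = DP_GST_THRESHOLD,
    mask: MaskSet | None = None,
) -> pd.DataFrame:
    """Select the DP panel: G_ST >= threshold, Indel anchors only.

    Each entry is oriented by the per-taxon major allele (``ret_allele``
    / ``max_allele``, computed from the same masked frequencies as the
    G_ST).  Loci where the two majors coincide or either is tied are
    dropped with a warning.  Returns a DataFrame with columns
    ``chrom pos ret_allele max_allele gst variant_class ret_is_alt
    locus_index``, sorted by (chrom, pos).
    """
    gst = np.asarray(gst, dtype=float)
    if gst.shape != (gm.n_loci,):
        raise ValueError("gst length does not match loci")
    keep = ~np.isnan(gst) & (gst >= threshold)
    # among Indel records keep anchors only
    is_indel = (gm.loci["variant_class"] == "INDEL").to_numpy()
    keep &= ~is_indel | gm.loci["indel_anchor"].to_numpy().astype(bool)

    f_ret = allele_frequencies(gm, panel.ret_refs, mask)
    f_max = allele_frequencies(gm, panel.max_refs, mask)
    maj_ret = _major_allele(f_ret.p_alt)
    maj_max = _major_allele(f_max.p_alt)
    degenerate = keep & ((maj_ret == maj_max) | (maj_ret == -1) | (maj_max == -1))
    if degenerate.any():
        logger.warning(
            "dropping %d candidate DP(s) with coinciding or tied major alleles",
            int(degenerate.sum()),
        )
    keep &= ~degenerate

    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError(
            "no diagnostic polymorphism passed selection; "
            f"review the G_ST threshold ({threshold}) and reference panels"
        )
    loci = gm.loci.iloc[idx]
    ret_is_alt = maj_ret[idx] == 1
    out = pd.DataFrame(
        {
            "chrom": loci["chrom"].to_numpy(),
            "pos": loci["pos"].to_numpy(),
            "ret_allele": np.where(ret_is_alt, loci["alt"], loci["ref"]),
            "max_allele": np.where(ret_is_alt, loci["ref"], loci["alt"]),
            "gst": gst[idx],
            "variant_class": loci["variant_class"].to_numpy(),
            "ret_is_alt": ret_is_alt,
            "locus_index": idx,
        }
    )
    return out.reset_index(drop=True)


def write_panel_tsv(dps: pd.DataFrame, path) -> None:
    """Export `chrom pos ret_allele max_allele gst class`."""
    out = dps[["chrom", "pos", "ret_allele", "max_allele", "gst", "variant_class"]]
    out = out.rename(columns={"variant_class": "class"})
    out.to_csv(path, sep="\t", index=False)


def panel_locus_indices(dps: pd.DataFrame, gm: GenotypeMatrix) -> np.ndarray:
    """Map panel entries to locus indices of ``gm``; errors list missing loci."""
    lookup = {
        (c, p): i
        for i, (c, p) in enumerate(zip(gm.loci["chrom"], gm.loci["pos"]))
    }
    missing = [
        (c, p) for c, p in zip(dps["chrom"], dps["pos"]) if (c, p) not in lookup
    ]
    if missing:
        raise KeyError(f"DP loci absent from genotype matrix: {missing[:10]}")
    return np.array([lookup[(c, p)] for c, p in zip(dps["chrom"], dps["pos"])])
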