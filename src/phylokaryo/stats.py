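"""Population-genetic estimators.

Implements the per-locus statistics the discovery stage is built on:

* allele frequencies per sample subset (optionally mask-aware),
* observed/expected heterozygosity and Wright's fixation index
  ``Fw = 1 - Ho/He``,
* Nei's inter-population differentiation
  ``G_ST = (He_tot - (He_a + He_b)/2) / He_tot`` with the total
  population built from *equal-weight* pooling of the two taxa
  (``p_tot = (p_a + p_b)/2``), so panel-size asymmetry (e.g. 11 vs 6
  references) does not bias the estimate,
* pairwise simple-matching and Euclidean dissimilarities over
  pairwise-complete loci,
* reference-set centroids and per-locus similarity of an individual to
  a centroid.

Undefined statistics propagate as NaN, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, MaskSet


@dataclass
class AlleleFrequencyTable:
    """Per-locus alt-allele frequency and the genotype count behind it."""

    p_alt: np.ndarray  # NaN where undefined (n_obs == 0)
    n_obs: np.ndarray  # non-missing genotypes contributing

    @property
    def defined(self) -> np.ndarray:
        return self.n_obs > 0


@dataclass
class CentroidProfile:
    """Allele-frequency profile of a reference set (its 'centroid')."""

    p_alt: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.p_alt)


@dataclass
class DissimilarityMatrix:
    samples: list[str]
    d: np.ndarray
    n_loci: np.ndarray  # per-pair count of pairwise-complete loci
    metric: str  # EUCLIDEAN | SIMPLE_MATCHING

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.samples, columns=self.samples)

    def write_tsv(self, path) -> None:
        """Square TSV with sample header row/column (NJ / factorial-analysis input)."""
        self.to_frame().to_csv(path, sep="\t", index_label="sample")


def _masked_dosage(
    gm: GenotypeMatrix, samples, mask: MaskSet | None
) -> np.ndarray:
    idx = gm.sample_indices(samples)
    d = gm.dosage[idx].astype(np.int64)
    if mask is not None and not mask.is_empty():
        cm = mask.cell_mask(gm)[idx]
        d = np.where(cm, MISSING, d)
    return d


def allele_frequencies(
    gm: GenotypeMatrix, samples, mask: MaskSet | None = None
) -> AlleleFrequencyTable:
    """Alt-allele frequency per locus over a sample subset.

    Mask-covered calls are treated as missing.  Loci with no usable
    call get ``p_alt = NaN`` and ``n_obs = 0`` (flagged, not raised).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample subset")
    d = _masked_dosage(gm, samples, mask)
    present = d != MISSING
    n_obs = present.sum(axis=0)
    alt = np.where(present, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, alt / np.maximum(2 * n_obs, 1), np.nan)
    return AlleleFrequencyTable(p_alt=p, n_obs=n_obs)


def expected_het(p_alt: np.ndarray) -> np.ndarray:
    """He = 1 - sum_i p_i^2 = 2p(1-p) for a biallelic locus."""
    return 2.0 * p_alt * (1.0 - p_alt)


def locus_diversity(gm: GenotypeMatrix, samples) -> pd.DataFrame:
    """Per-locus Ho, He and Fw = 1 - Ho/He over a sample subset.

    Fw is NaN at monomorphic loci (He = 0) and wherever Ho is undefined.
    """
    samples = list(samples)
    d = _masked_dosage(gm, samples, None)
    present = d != MISSING
    n = present.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, (d == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
    he = expected_het(allele_frequencies(gm, samples).p_alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        fw = np.where(he > 0, 1.0 - ho / he, np.nan)
    return pd.DataFrame({"Ho": ho, "He": he, "Fw": fw})


def sample_heterozygosity(
    gm: GenotypeMatrix, sample: str, loci: np.ndarray | None = None
) -> float:
    """Fraction of a sample's non-missing calls that are heterozygous.

    ``loci`` restricts to a boolean mask or index array; NaN when no
    non-missing call remains.
    """
    row = gm.row(sample)
    if loci is not None:
        row = row[loci]
    present = row != MISSING
    if present.sum() == 0:
        return float("nan")
    return float((row[present] == 1).mean())


def nei_gst(p_a: np.ndarray, p_b: np.ndarray) -> np.ndarray:
    """Nei G_ST per locus from the two taxon alt-allele frequencies.

    Equal-weight pooling: p_tot = (p_a + p_b) / 2.  NaN where either
    input frequency is undefined or the pooled locus is monomorphic
    (He_tot = 0).  Values are clamped to [0, 1] against floating-point
    drift (tolerance 1e-12).
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    p_tot = 0.5 * (p_a + p_b)
    he_tot = expected_het(p_tot)
    he_within = 0.5 * (expected_het(p_a) + expected_het(p_b))
    with np.errstate(invalid="ignore", divide="ignore"):
        gst = np.where(he_tot > 0, (he_tot - he_within) / np.where(he_tot > 0, he_tot, 1), np.nan)
    return np.clip(gst, 0.0, 1.0)


def _pairwise_complete(gm: GenotypeMatrix, i: str, j: str):
    a = gm.row(i).astype(np.int64)
    b = gm.row(j).astype(np.int64)
    ok = (a != MISSING) & (b != MISSING)
    return a[ok], b[ok]


def simple_matching_dissimilarity(gm: GenotypeMatrix, i: str, j: str) -> float:
    """d = 1 - (1/L) sum_l m_l/2 over pairwise-complete loci.

    m_l counts matching alleles at locus l (2 identical genotypes, 1 one
    shared allele, 0 none); for dosages this is ``2 - |x_i - x_j|``.
    NaN when no pairwise-complete locus exists.
    """
    a, b = _pairwise_complete(gm, i, j)
    if a.size == 0:
        return float("nan")
    return float(np.abs(a - b).mean() / 2.0)


def euclidean_dissimilarity(gm: GenotypeMatrix, i: str, j: str) -> float:
    """sqrt(sum_k (x_ik - x_jk)^2) over pairwise-complete dosages."""
    a, b = _pairwise_complete(gm, i, j)
    if a.size == 0:
        return float("nan")
    return float(np.sqrt(((a - b) ** 2).sum()))


def dissimilarity_matrix(
    gm: GenotypeMatrix, metric: str = "SIMPLE_MATCHING", samples=None
) -> DissimilarityMatrix:
    """All-pairs dissimilarities (symmetric, zero diagonal)."""
    samples = list(samples) if samples is not None else list(gm.samples)
    fn = {
        "SIMPLE_MATCHING": simple_matching_dissimilarity,
        "EUCLIDEAN": euclidean_dissimilarity,
    }[metric.upper()]
    n = len(samples)
    d = np.zeros((n, n))
    L = np.zeros((n, n), dtype=np.int64)
    for ii in range(n):
        for jj in range(ii + 1, n):
            d[ii, jj] = d[jj, ii] = fn(gm, samples[ii], samples[jj])
            a, _ = _pairwise_complete(gm, samples[ii], samples[jj])
            L[ii, jj] = L[jj, ii] = a.size
    return DissimilarityMatrix(samples, d, L, metric.upper())


def taxon_centroid(
    gm: GenotypeMatrix, refs, mask: MaskSet | None = None
) -> CentroidProfile:
    """Allele-frequency centroid of a reference set (mask-aware)."""
    return CentroidProfile(p_alt=allele_frequencies(gm, refs, mask).p_alt)


def similarity_to_centroid(
    gm: GenotypeMatrix,
    sample: str,
    centroid: CentroidProfile,
    loci: np.ndarray | None = None,
) -> np.ndarray:
    """Per-locus expected allele-matching rate of a sample to a centroid.

    For a genotype with alleles (a, b) and centroid frequencies p_c,
    S = (p_c(a) + p_c(b)) / 2 — the frequency-weighted generalisation of
    the simple-matching similarity, reducing to it exactly when the
    centroid is a single genotype.  NaN where the call is missing or the
    centroid undefined.
    """
    g = gm.row(sample).astype(float)
    p = centroid.p_alt
    if loci is not None:
        g = g[loci]
        p = p[loci]
    g = np.where(g == MISSING, np.nan, g)
    # alt allele matches with prob p, ref with prob 1-p
    return (g * p + (2.0 - g) * (1.0 - p)) / 2.0


def per_locus_stats_table(
    gm: GenotypeMatrix, samples, gst: np.ndarray | None = None
) -> pd.DataFrame:
    """Export table `chrom pos Ho He Fw [GST]`."""
    div = locus_diversity(gm, samples)
    out = pd.DataFrame({"chrom": gm.loci["chrom"], "pos": gm.loci["pos"]})
    out[["Ho", "He", "Fw"]] = div[["Ho", "He", "Fw"]]
    if gst is not None:
        out["GST"] = gst
    return out
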