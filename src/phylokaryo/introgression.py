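"""Introgression detection and masking in reference accessions.

Reference varieties of the two ancestral taxa are themselves sometimes
admixed; such regions must be masked before taxon allele frequencies
can be trusted.  Detection combines two genome scans per reference
sample:

* a moving-average heterozygosity track (windows of 120 markers stepped
  by 40): interspecific heterozygous tracts show Ho well above the
  intraspecific baseline (~0.30), so windows above 0.40 are flagged;
* moving-average similarity tracks to the two reference-set centroids
  (windows of 60 markers stepped by 20, restricted to loci informative
  for the inter-taxon differentiation: first-pass G_ST > 0.5): windows
  where similarity to the *other* taxon's centroid reaches or exceeds
  similarity to the own centroid are flagged — this captures homozygous
  introgressions that heterozygosity alone misses.

Flagged windows are unioned into bp intervals; masked calls become
missing before taxon frequencies are re-estimated.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, MaskSet, _merge_intervals
from .stats import CentroidProfile, similarity_to_centroid
from .windows import WindowTrack, windowed_statistic

logger = logging.getLogger(__name__)

HO_WIN, HO_STEP = 120, 40
SIM_WIN, SIM_STEP = 60, 20
HO_THRESHOLD = 0.40  # windows above are potential introgressions
HO_INTRASPECIFIC = 0.30  # typical within-taxon level; (0.30, 0.40] not flagged


def heterozygosity_track(
    gm: GenotypeMatrix, sample: str, win: int = HO_WIN, step: int = HO_STEP
) -> dict[str, WindowTrack]:
    """Per-chromosome moving-average heterozygosity of one sample.

    Per-marker indicator: 1 heterozygous, 0 homozygous, missing skipped.
    """
    row = gm.row(sample).astype(float)
    het = np.where(row == MISSING, np.nan, (row == 1).astype(float))
    out = {}
    for chrom in gm.chroms:
        m = gm.chrom_mask(chrom)
        out[chrom] = windowed_statistic(
            het[m], gm.loci["pos"].to_numpy()[m], chrom, win, step
        )
    return out


def similarity_tracks(
    gm: GenotypeMatrix,
    sample: str,
    cen_ret: CentroidProfile,
    cen_max: CentroidProfile,
    gst1: np.ndarray,
    informative_gst: float = 0.5,
    win: int = SIM_WIN,
    step: int = SIM_STEP,
) -> tuple[dict[str, WindowTrack], dict[str, WindowTrack]]:
    """Moving-average similarity of one sample to the two taxon centroids.

    Restricted to loci informative for the inter-taxon differentiation
    (first-pass, unmasked G_ST > ``informative_gst``) with both
    centroids defined.
    """
    informative = (
        ~np.isnan(gst1) & (gst1 > informative_gst) & cen_ret.defined & cen_max.defined
    )
    s_ret = similarity_to_centroid(gm, sample, cen_ret)
    s_max = similarity_to_centroid(gm, sample, cen_max)
    pos = gm.loci["pos"].to_numpy()
    out_ret, out_max = {}, {}
    for chrom in gm.chroms:
        m = gm.chrom_mask(chrom) & informative
        if m.sum() < win:
            warnings.warn(
                f"chromosome {chrom}: only {int(m.sum())} informative loci "
                f"(< window {win}); single-window fallback",
                stacklevel=2,
            )
        out_ret[chrom] = windowed_statistic(s_ret[m], pos[m], chrom, win, step)
        out_max[chrom] = windowed_statistic(s_max[m], pos[m], chrom, win, step)
    return out_ret, out_max


def _flagged_intervals(track: WindowTrack, flags: np.ndarray) -> list[tuple[int, int]]:
    """Merge runs of consecutive flagged windows into bp intervals."""
    out = []
    run_start = None
    for i, w in enumerate(track.windows):
        if flags[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            out.append((track.windows[run_start].bp_start, track.windows[i - 1].bp_end))
            run_start = None
    if run_start is not None:
        out.append((track.windows[run_start].bp_start, track.windows[-1].bp_end))
    return out


def detect_introgressions(
    ho: dict[str, WindowTrack],
    s_own: dict[str, WindowTrack],
    s_other: dict[str, WindowTrack],
    ho_threshold: float = HO_THRESHOLD,
) -> dict[str, list[tuple[int, int]]]:
    """Flag potential introgressions in one reference sample.

    A window is flagged when (a) its heterozygosity exceeds
    ``ho_threshold``, or (b) similarity to the other taxon's centroid is
    >= similarity to the own-taxon centroid.  Overlapping or adjacent
    flagged windows merge into bp intervals (1-based inclusive, spanning
    the first to last marker of the flagged run).  An empty result is a
    valid outcome.
    """
    result: dict[str, list[tuple[int, int]]] = {}
    for chrom, ho_track in ho.items():
        ivs: list[tuple[int, int]] = []
        with np.errstate(invalid="ignore"):
            ho_flags = np.nan_to_num(ho_track.values, nan=-1.0) > ho_threshold
        ivs += _flagged_intervals(ho_track, ho_flags)
        own_t = s_own[chrom]
        own_v, oth_v = own_t.values, s_other[chrom].values
        cond_b = ~np.isnan(own_v) & ~np.isnan(oth_v) & (oth_v >= own_v)
        ivs += _flagged_intervals(own_t, cond_b)
        if ivs:
            result[chrom] = _merge_intervals(ivs)
    return result


def scan_reference_panel(
    gm: GenotypeMatrix,
    panel,
    cen_ret: CentroidProfile,
    cen_max: CentroidProfile,
    gst1: np.ndarray,
    ho_threshold: float = HO_THRESHOLD,
    informative_gst: float = 0.5,
    ho_win: tuple[int, int] = (HO_WIN, HO_STEP),
    sim_win: tuple[int, int] = (SIM_WIN, SIM_STEP),
) -> MaskSet:
    """Run the Ho + similarity scan on every reference accession.

    Masks are computed per reference independently; query samples are
    never masked.
    """
    masks = MaskSet()
    for sample in panel.refs:
        own_is_ret = sample in panel.ret_refs
        ho = heterozygosity_track(gm, sample, *ho_win)
        s_ret, s_max = similarity_tracks(
            gm, sample, cen_ret, cen_max, gst1, informative_gst, *sim_win
        )
        s_own, s_other = (s_ret, s_max) if own_is_ret else (s_max, s_ret)
        found = detect_introgressions(ho, s_own, s_other, ho_threshold)
        for chrom, ivs in found.items():
            for s, e in ivs:
                masks.add(sample, chrom, s, e)
        if found:
            logger.info(
                "sample %s: %d introgression interval(s) flagged",
                sample,
                sum(len(v) for v in found.values()),
            )
    return masks


def apply_mask(gm: GenotypeMatrix, masks: MaskSet) -> GenotypeMatrix:
    """Turn mask-covered calls into missing data; everything else untouched."""
    out = gm.copy()
    cm = masks.cell_mask(gm)
    out.dosage[cm] = MISSING
    return out


def tracks_to_frame(sample: str, tracks: dict[str, WindowTrack]) -> pd.DataFrame:
    """Export `sample chrom win_start_idx win_end_idx bp_start bp_end value`."""
    frames = [t.to_frame() for t in tracks.values()]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    df.insert(0, "sample", sample)
    return df
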