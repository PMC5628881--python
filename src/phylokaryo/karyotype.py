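"""Phylogenomic karyotype painting from diagnostic polymorphisms.

Each sample's genotype at the DP panel is reduced to one of four states
per locus (homozygous for the RET-diagnostic allele, homozygous for the
MAX-diagnostic allele, heterozygous, missing).  Successive
non-overlapping windows of 20 DPs are then called RET/RET, MAX/MAX or
RET/MAX when the most frequent configuration outnumbers the runner-up
by at least a factor of 2 (and at least ``min_scored`` DPs are scored);
otherwise the window is undetermined.  Runs of identical window states
merge into karyotype segments, and genome-wide admixture proportions
are counted directly over scored DP alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dp import panel_locus_indices
from .matrix import MISSING, GenotypeMatrix, chrom_sort_key
from .windows import window_bounds

# per-DP states
RET_HOM, HET, MAX_HOM = 0, 1, 2  # MISSING = -1

# window / segment states
S_RET = "RET/RET"
S_HET = "RET/MAX"
S_MAX = "MAX/MAX"
S_UNDET = "UNDET"
_STATE_OF_BEST = {RET_HOM: S_RET, HET: S_HET, MAX_HOM: S_MAX}

KARYO_WIN = 20
MIN_SCORED = 10
RATIO = 2.0

SEGMENT_COLUMNS = [
    "sample",
    "chrom",
    "bp_start",
    "bp_end",
    "state",
    "n_windows",
    "n_ret_hom",
    "n_max_hom",
    "n_het",
    "n_missing",
]


def classify_dp_genotypes(gm: GenotypeMatrix, dps: pd.DataFrame) -> np.ndarray:
    """Orient each sample's DP calls against the panel.

    Returns an int8 samples x DPs array with values RET_HOM / HET /
    MAX_HOM or -1 (missing).  Every DP locus must be present in ``gm``.
    The internal matrix is strictly biallelic, so a call can only carry
    the two panel alleles; an off-panel (third) allele — impossible
    here — would be treated as missing.
    """
    idx = panel_locus_indices(dps, gm)
    d = gm.dosage[:, idx].astype(np.int8)
    ret_is_alt = dps["ret_is_alt"].to_numpy()
    # count of RET-diagnostic alleles per call
    r = np.where(ret_is_alt[None, :], d, 2 - d)
    states = (2 - r).astype(np.int8)
    states[d == MISSING] = MISSING
    return states


@dataclass
class WindowCall:
    chrom: str
    start_idx: int  # DP-index space within the chromosome, half-open
    end_idx: int
    bp_start: int
    bp_end: int
    state: str
    n_ret_hom: int
    n_max_hom: int
    n_het: int
    n_missing: int


def _call_one_window(
    counts: tuple[int, int, int], n_missing: int, min_scored: int, ratio: float
) -> str:
    """Best-configuration / runner-up rule on (ret_hom, max_hom, het) counts."""
    n_ret, n_max, n_het = counts
    scored = n_ret + n_max + n_het
    if scored < min_scored:
        return S_UNDET
    per_state = {RET_HOM: n_ret, MAX_HOM: n_max, HET: n_het}
    order = sorted(per_state, key=per_state.get, reverse=True)
    best, second = per_state[order[0]], per_state[order[1]]
    if second == 0 or best / second >= ratio:
        if best == second:  # exact tie, even at zero second
            return S_UNDET
        return _STATE_OF_BEST[order[0]]
    return S_UNDET


def call_windows(
    states_row: np.ndarray,
    dps: pd.DataFrame,
    win: int = KARYO_WIN,
    min_scored: int = MIN_SCORED,
    ratio: float = RATIO,
) -> list[WindowCall]:
    """Call successive non-overlapping windows of ``win`` DPs per chromosome.

    A terminal remainder of at least ``win/2`` DPs forms its own window;
    a smaller one merges into the previous window.
    """
    calls: list[WindowCall] = []
    chrom_arr = dps["chrom"].to_numpy()
    pos_arr = dps["pos"].to_numpy()
    seen: dict[str, None] = {}
    for c in chrom_arr:
        seen.setdefault(c, None)
    for chrom in seen:
        on = chrom_arr == chrom
        st = states_row[on]
        pos = pos_arr[on]
        for s, e in window_bounds(len(st), win, win):
            w = st[s:e]
            counts = (
                int((w == RET_HOM).sum()),
                int((w == MAX_HOM).sum()),
                int((w == HET).sum()),
            )
            n_missing = int((w == MISSING).sum())
            calls.append(
                WindowCall(
                    chrom=str(chrom),
                    start_idx=s,
                    end_idx=e,
                    bp_start=int(pos[s]),
                    bp_end=int(pos[e - 1]),
                    state=_call_one_window(counts, n_missing, min_scored, ratio),
                    n_ret_hom=counts[0],
                    n_max_hom=counts[1],
                    n_het=counts[2],
                    n_missing=n_missing,
                )
            )
    return calls


def merge_to_segments(window_calls: list[WindowCall], sample: str) -> pd.DataFrame:
    """Merge maximal runs of identical window state into karyotype segments.

    The merge is lossless: per-segment support counts are the sums over
    its windows, and ``n_windows`` recovers the window-state run length.
    Segment bp spans run from the first DP of the first window to the
    last DP of the last window; inter-segment gaps are left unpainted.
    """
    rows = []
    for call in window_calls:
        if (
            rows
            and rows[-1]["chrom"] == call.chrom
            and rows[-1]["state"] == call.state
        ):
            seg = rows[-1]
            seg["bp_end"] = call.bp_end
            seg["n_windows"] += 1
            seg["n_ret_hom"] += call.n_ret_hom
            seg["n_max_hom"] += call.n_max_hom
            seg["n_het"] += call.n_het
            seg["n_missing"] += call.n_missing
        else:
            rows.append(
                {
                    "sample": sample,
                    "chrom": call.chrom,
                    "bp_start": call.bp_start,
                    "bp_end": call.bp_end,
                    "state": call.state,
                    "n_windows": 1,
                    "n_ret_hom": call.n_ret_hom,
                    "n_max_hom": call.n_max_hom,
                    "n_het": call.n_het,
                    "n_missing": call.n_missing,
                }
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def admixture_proportion(states_row: np.ndarray) -> dict:
    """Genome-wide MAX-allele fraction over scored DPs of one sample.

    prop_max = (2 n_max_hom + n_het) / (2 n_scored); missing DPs are
    excluded.  NaN when nothing is scored.
    """
    n_max = int((states_row == MAX_HOM).sum())
    n_het = int((states_row == HET).sum())
    n_scored = int((states_row != MISSING).sum())
    if n_scored == 0:
        return {"prop_ret": float("nan"), "prop_max": float("nan"), "n_dp_used": 0}
    prop_max = (2 * n_max + n_het) / (2 * n_scored)
    return {"prop_ret": 1.0 - prop_max, "prop_max": prop_max, "n_dp_used": n_scored}


def paint_sample(
    gm: GenotypeMatrix,
    dps: pd.DataFrame,
    sample: str,
    win: int = KARYO_WIN,
    min_scored: int = MIN_SCORED,
    ratio: float = RATIO,
) -> tuple[pd.DataFrame, list[WindowCall], dict]:
    """Full painting of one sample: segments, window calls, admixture."""
    states = classify_dp_genotypes(gm, dps)
    row = states[gm.sample_indices([sample])[0]]
    calls = call_windows(row, dps, win, min_scored, ratio)
    segments = merge_to_segments(calls, sample)
    return segments, calls, admixture_proportion(row)


STATE_COLORS = {S_RET: "#d62728", S_MAX: "#1f77b4", S_HET: "#9467bd", S_UNDET: "#bbbbbb"}


def plot_karyotype(segments: pd.DataFrame, ax=None, bar_height: float = 0.6):
    """Horizontal chromosome bars coloured by ancestry state.

    Red: RET/RET homozygosity; blue: MAX/MAX; purple: RET/MAX
    heterozygosity; grey: undetermined.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    chroms = sorted(segments["chrom"].unique(), key=chrom_sort_key)
    for y, chrom in enumerate(chroms):
        for seg in segments[segments["chrom"] == chrom].itertuples(index=False):
            ax.barh(
                y,
                seg.bp_end - seg.bp_start + 1,
                left=seg.bp_start,
                height=bar_height,
                color=STATE_COLORS[seg.state],
                edgecolor="none",
            )
    ax.set_yticks(range(len(chroms)), [f"chr{c}" for c in chroms])
    ax.invert_yaxis()
    ax.set_xlabel("position (bp)")
    title = segments["sample"].iloc[0] if len(segments) else ""
    ax.set_title(title)
    return ax
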