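"""End-to-end orchestration: discovery and painting runs.

Discovery: filters -> first-pass taxon G_ST -> heterozygosity and
centroid-similarity scans of the references -> introgression masks ->
masked G_ST -> diagnostic-polymorphism panel.

Painting: classify each sample's DP genotypes, call 20-DP windows,
merge to karyotype segments, count admixture proportions, and tabulate
the 100-marker windowed-heterozygosity distribution.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dp as dp_mod
from . import filters, introgression, karyotype, stats
from .matrix import DepthMatrix, GenotypeMatrix, MaskSet, SamplePanel
from .windows import windowed_statistic

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the workflow, at its standard default."""

    min_reads: int = 5
    max_missing: float = 0.5
    min_maf: float = 0.05
    max_ref_missing: float = 0.3
    informative_gst: float = 0.5
    ho_threshold: float = 0.40
    dp_gst: float = 0.9
    ho_win: int = 120
    ho_step: int = 40
    sim_win: int = 60
    sim_step: int = 20
    dist_win: int = 100
    karyo_win: int = 20
    min_scored: int = 10
    ratio: float = 2.0
    seed: int = 0
    mask_enabled: bool = True

    def __post_init__(self) -> None:
        checks = [
            (self.min_reads >= 0, "min_reads >= 0"),
            (0 <= self.max_missing <= 1, "max_missing in [0,1]"),
            (0 <= self.min_maf <= 0.5, "min_maf in [0,0.5]"),
            (0 <= self.max_ref_missing <= 1, "max_ref_missing in [0,1]"),
            (0 <= self.informative_gst < 1, "informative_gst in [0,1)"),
            (0 <= self.ho_threshold <= 1, "ho_threshold in [0,1]"),
            (0 < self.dp_gst <= 1, "dp_gst in (0,1]"),
            (1 <= self.ho_step <= self.ho_win, "ho windows"),
            (1 <= self.sim_step <= self.sim_win, "sim windows"),
            (self.karyo_win >= 1, "karyo_win >= 1"),
            (0 <= self.min_scored <= self.karyo_win, "min_scored in [0, karyo_win]"),
            (self.ratio >= 1, "ratio >= 1"),
        ]
        for ok, what in checks:
            if not ok:
                raise ValueError(f"config violates {what}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class DiscoveryResult:
    gm_filtered: GenotypeMatrix
    gst_first_pass: np.ndarray
    masks: MaskSet
    gst_masked: np.ndarray
    panel: pd.DataFrame  # the DiagnosticPanel table
    locus_stats: pd.DataFrame


@dataclass
class PaintingResult:
    segments: pd.DataFrame
    window_calls: dict[str, list]
    admixture: pd.DataFrame
    ho_distribution: pd.DataFrame  # sample chrom bp_start bp_end value
    skipped: list[str] = field(default_factory=list)


def run_discovery(
    gm: GenotypeMatrix,
    panel: SamplePanel,
    config: PipelineConfig | None = None,
    depth: DepthMatrix | None = None,
) -> DiscoveryResult:
    """Execute the discovery branch of the workflow."""
    cfg = config or PipelineConfig()
    panel.validate_against(gm, discovery=True)

    if depth is not None:
        gm = filters.apply_depth_threshold(gm, depth, cfg.min_reads)
    gm = filters.filter_loci(gm, cfg.max_missing, cfg.min_maf)
    gm = filters.filter_by_reference_missing(gm, panel, cfg.max_ref_missing)
    logger.info("filtering kept %d loci", gm.n_loci)

    gst1 = dp_mod.compute_gst_ret_max(gm, panel)  # first pass, unmasked
    cen_ret = stats.taxon_centroid(gm, panel.ret_refs)
    cen_max = stats.taxon_centroid(gm, panel.max_refs)

    if cfg.mask_enabled:
        masks = introgression.scan_reference_panel(
            gm,
            panel,
            cen_ret,
            cen_max,
            gst1,
            ho_threshold=cfg.ho_threshold,
            informative_gst=cfg.informative_gst,
            ho_win=(cfg.ho_win, cfg.ho_step),
            sim_win=(cfg.sim_win, cfg.sim_step),
        )
    else:
        masks = MaskSet()
    gst2 = dp_mod.compute_gst_ret_max(gm, panel, masks)
    panel_df = dp_mod.select_diagnostic_panel(gst2, gm, panel, cfg.dp_gst, masks)
    logger.info("selected %d diagnostic polymorphisms", len(panel_df))

    locus_stats = stats.per_locus_stats_table(gm, gm.samples, gst2)
    return DiscoveryResult(gm, gst1, masks, gst2, panel_df, locus_stats)


def heterozygosity_distribution(
    gm: GenotypeMatrix, samples, win: int = 100
) -> pd.DataFrame:
    """Windowed-Ho table over successive non-overlapping ``win``-marker windows."""
    from .matrix import MISSING

    rows = []
    pos_all = gm.loci["pos"].to_numpy()
    for sample in samples:
        row = gm.row(sample).astype(float)
        het = np.where(row == MISSING, np.nan, (row == 1).astype(float))
        for chrom in gm.chroms:
            m = gm.chrom_mask(chrom)
            track = windowed_statistic(het[m], pos_all[m], chrom, win, win)
            for w in track.windows:
                rows.append((sample, chrom, w.bp_start, w.bp_end, w.value))
    return pd.DataFrame(rows, columns=["sample", "chrom", "bp_start", "bp_end", "value"])


def run_painting(
    gm: GenotypeMatrix,
    panel_df: pd.DataFrame,
    samples,
    config: PipelineConfig | None = None,
) -> PaintingResult:
    """Paint each sample's genome at the DP panel and summarise admixture."""
    cfg = config or PipelineConfig()
    if len(panel_df) == 0:
        raise ValueError("empty diagnostic panel")
    seg_frames, admix_rows, calls = [], [], {}
    skipped = []
    present = set(gm.samples)
    dp_in_gm = panel_df[
        [
            (c, p) in set(zip(gm.loci["chrom"], gm.loci["pos"]))
            for c, p in zip(panel_df["chrom"], panel_df["pos"])
        ]
    ].reset_index(drop=True)
    if len(dp_in_gm) < len(panel_df):
        logger.warning(
            "%d panel loci absent from genotype matrix; painting on %d",
            len(panel_df) - len(dp_in_gm),
            len(dp_in_gm),
        )
    for sample in samples:
        if sample not in present:
            skipped.append(sample)
            logger.warning("sample %s absent from genotype matrix; skipped", sample)
            continue
        segs, wc, admix = karyotype.paint_sample(
            gm, dp_in_gm, sample, cfg.karyo_win, cfg.min_scored, cfg.ratio
        )
        seg_frames.append(segs)
        calls[sample] = wc
        admix_rows.append({"sample": sample, **admix})
    segments = (
        pd.concat(seg_frames, ignore_index=True)
        if seg_frames
        else pd.DataFrame(columns=karyotype.SEGMENT_COLUMNS)
    )
    admixture = pd.DataFrame(admix_rows)
    ho_dist = heterozygosity_distribution(
        gm, [s for s in samples if s in present], cfg.dist_win
    )
    return PaintingResult(segments, calls, admixture, ho_dist, skipped)


def write_discovery_outputs(result: DiscoveryResult, outdir, cfg: PipelineConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dp_mod.write_panel_tsv(result.panel, outdir / "diagnostic_panel.tsv")
    result.masks.write_tsv(outdir / "introgression_masks.tsv")
    result.locus_stats.to_csv(outdir / "locus_stats.tsv", sep="\t", index=False)
    (outdir / "run_log.json").write_text(
        json.dumps(
            {
                "stage": "discovery",
                "config": dataclasses.asdict(cfg),
                "config_hash": cfg.digest(),
                "n_loci_filtered": result.gm_filtered.n_loci,
                "n_dps": len(result.panel),
            },
            indent=2,
        )
    )


def write_painting_outputs(result: PaintingResult, outdir, cfg: PipelineConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.segments.to_csv(outdir / "karyotype_segments.tsv", sep="\t", index=False)
    result.admixture.to_csv(outdir / "admixture.tsv", sep="\t", index=False)
    result.ho_distribution.to_csv(
        outdir / "heterozygosity_distribution.tsv", sep="\t", index=False
    )
    (outdir / "run_log.json").write_text(
        json.dumps(
            {
                "stage": "painting",
                "config": dataclasses.asdict(cfg),
                "config_hash": cfg.digest(),
                "n_samples": int(result.admixture.shape[0]),
                "skipped": result.skipped,
            },
            indent=2,
        )
    )
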