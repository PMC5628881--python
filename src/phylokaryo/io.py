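"""Readers and writers for genotype, depth and panel tables.

Two genotype input formats are supported:

* VCF 4.x (``GT`` and optional ``DP`` FORMAT fields), parsed with cyvcf2.
  Only strictly biallelic records are accepted; multi-allelic records are
  rejected and reported.  A record whose REF or ALT spans more than one
  base pair is an Indel and is represented once, at its first (anchor)
  position, with ``indel_anchor=True``.
* A TSV dialect: header ``chrom pos ref alt class`` followed by one
  column per sample holding alt-allele dosages in {0, 1, 2, NA}.  An
  optional ``anchor`` column (0/1) carries the Indel-anchor flag for
  dialects that expand Indels to per-position rows; when absent, every
  INDEL row is treated as an anchor.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import LOCUS_COLUMNS, MISSING, DepthMatrix, GenotypeMatrix, chrom_sort_key

logger = logging.getLogger(__name__)

_META = ["chrom", "pos", "ref", "alt", "class"]


class GenotypeParseError(ValueError):
    pass


def _finalise(samples, loci: pd.DataFrame, dosage: np.ndarray) -> GenotypeMatrix:
    """Sort by (chrom, pos), check duplicates, build the matrix."""
    key = loci["chrom"].map(chrom_sort_key)
    order = sorted(range(len(loci)), key=lambda i: (key.iloc[i], loci["pos"].iloc[i]))
    loci = loci.iloc[order].reset_index(drop=True)
    dosage = dosage[:, order]
    dup = loci.duplicated(subset=["chrom", "pos"])
    if dup.any():
        first = loci[dup].iloc[0]
        raise GenotypeParseError(
            f"duplicate locus at {first['chrom']}:{first['pos']}"
        )
    return GenotypeMatrix(samples, loci, dosage)


def read_genotype_table(path, format: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the TSV dialect.

    ``format="auto"`` picks by file extension (.vcf -> VCF, else TSV).
    """
    path = Path(path)
    if format == "auto":
        format = "VCF" if path.suffix.lower() == ".vcf" else "TSV"
    fmt = format.upper()
    if fmt == "VCF":
        return read_vcf(path)[0]
    if fmt == "TSV":
        return read_genotype_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if list(df.columns[: len(_META)]) != _META:
        raise GenotypeParseError(
            f"TSV header must start with {' '.join(_META)}; got {list(df.columns)[:5]}"
        )
    extra = list(df.columns[len(_META):])
    anchor_col = None
    if extra and extra[0] == "anchor":
        anchor_col = df["anchor"].astype(int).astype(bool)
        extra = extra[1:]
    samples = extra
    if not samples:
        raise GenotypeParseError("TSV contains no sample columns")
    vclass = df["class"].str.upper()
    bad = ~vclass.isin(["SNP", "INDEL"])
    if bad.any():
        raise GenotypeParseError(
            f"line {bad.idxmax() + 2}: class must be SNP or INDEL"
        )
    loci = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": df["pos"].astype(int),
            "ref": df["ref"].astype(str),
            "alt": df["alt"].astype(str),
            "variant_class": vclass,
            "indel_anchor": (vclass == "INDEL")
            if anchor_col is None
            else anchor_col.to_numpy(),
        }
    )
    calls = df[samples].to_numpy(dtype=object)
    dosage = np.full(calls.shape, MISSING, dtype=np.int8)
    assigned = pd.isna(calls.astype(object)) | (calls == "NA")
    for v in (0, 1, 2):
        hit = (calls == v) | (calls == float(v)) | (calls == str(v))
        dosage[hit] = v
        assigned |= hit
    if not assigned.all():
        i, j = np.argwhere(~assigned)[0]
        raise GenotypeParseError(
            f"line {i + 2}, sample {samples[j]}: bad dosage {calls[i, j]!r}"
        )
    return _finalise(samples, loci, dosage.T)


def write_genotype_tsv(gm: GenotypeMatrix, path, anchor_column: bool = True) -> None:
    """Write the TSV dialect; round-trips calls and metadata exactly."""
    out = pd.DataFrame(
        {
            "chrom": gm.loci["chrom"],
            "pos": gm.loci["pos"],
            "ref": gm.loci["ref"],
            "alt": gm.loci["alt"],
            "class": gm.loci["variant_class"],
        }
    )
    if anchor_column:
        out["anchor"] = gm.loci["indel_anchor"].astype(int)
    d = gm.dosage.astype(object)
    d[gm.dosage == MISSING] = "NA"
    for i, s in enumerate(gm.samples):
        out[s] = d[i]
    out.to_csv(path, sep="\t", index=False)


def read_vcf(path) -> tuple[GenotypeMatrix, DepthMatrix | None]:
    """Parse a VCF; returns the matrix and, if DP is present, a depth matrix.

    Multi-allelic records are rejected (counted and logged, with the
    locus id of each).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, dos, depths = [], [], []
    n_rejected = 0
    has_dp = True
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_rejected += 1
            logger.warning("rejected multi-allelic record %s:%d", rec.CHROM, rec.POS)
            continue
        ref, alt = rec.REF, rec.ALT[0]
        is_indel = len(ref) != 1 or len(alt) != 1
        rows.append(
            (
                str(rec.CHROM),
                int(rec.POS),
                ref,
                alt,
                "INDEL" if is_indel else "SNP",
                bool(is_indel),
            )
        )
        # gts012: 0/1/2 alt counts, 3 = unknown
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        dos.append(gt)
        if has_dp:
            try:
                dp = rec.format("DP")
            except KeyError:
                dp = None
            if dp is None:
                has_dp = False
            else:
                dp = np.asarray(dp, dtype=np.int64).reshape(-1)
                dp[dp < 0] = 0
                depths.append(dp)
    if n_rejected:
        logger.info("rejected %d multi-allelic record(s)", n_rejected)
    if not rows:
        raise GenotypeParseError(f"no usable biallelic records in {path}")
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    dosage = np.stack(dos, axis=1)
    gm = _finalise(samples, loci, dosage)
    dm = None
    if has_dp and len(depths) == gm.n_loci:
        # re-sort depth columns the same way as the genotype columns
        key = loci["chrom"].map(chrom_sort_key)
        order = sorted(
            range(len(loci)), key=lambda i: (key.iloc[i], loci["pos"].iloc[i])
        )
        dm = DepthMatrix(np.stack(depths, axis=1)[:, order])
    return gm, dm


def write_vcf(gm: GenotypeMatrix, path, depth: DepthMatrix | None = None) -> None:
    """Emit a minimal VCF 4.2 (GT, optional DP) for interface testing."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        fmt = "GT:DP" if depth is not None else "GT"
        for j in range(gm.n_loci):
            loc = gm.loci.iloc[j]
            cells = []
            for i in range(gm.n_samples):
                c = code[int(gm.dosage[i, j])]
                if depth is not None:
                    c += f":{int(depth.reads[i, j])}"
                cells.append(c)
            fh.write(
                f"{loc['chrom']}\t{loc['pos']}\t.\t{loc['ref']}\t{loc['alt']}"
                f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def read_depth_tsv(path, gm: GenotypeMatrix) -> DepthMatrix:
    """Depth table in the same layout as the genotype TSV (chrom pos + samples)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    reads = df[gm.samples].to_numpy(dtype=np.int64).T
    if reads.shape != gm.dosage.shape:
        raise ValueError("depth table dimensions do not match genotype matrix")
    return DepthMatrix(reads)


def write_depth_tsv(dm: DepthMatrix, gm: GenotypeMatrix, path) -> None:
    out = pd.DataFrame({"chrom": gm.loci["chrom"], "pos": gm.loci["pos"]})
    for i, s in enumerate(gm.samples):
        out[s] = dm.reads[i]
    out.to_csv(path, sep="\t", index=False)
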