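"""Core in-memory containers for the pipeline.

The whole pipeline operates on a diploid, strictly biallelic genotype
matrix.  Because every locus carries exactly two alleles and genotypes
are unordered (no phasing is assumed anywhere), a call is fully described
by its alt-allele dosage in {0, 1, 2}; missing calls are encoded as -1.
That single ``int8`` samples x loci array is the internal representation
of every genotype in the package.

Coordinates are 1-based inclusive (VCF convention) throughout, including
every exported interval.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

#: roles a sample can play in a discovery run
RET_REF = "RET_REF"
MAX_REF = "MAX_REF"
QUERY = "QUERY"
ROLES = (RET_REF, MAX_REF, QUERY)

LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt", "variant_class", "indel_anchor"]


def chrom_sort_key(chrom: str):
    """Natural ordering for chromosome labels ("2" < "10", "chr2" < "chr10")."""
    parts = re.split(r"(\d+)", str(chrom))
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass
class GenotypeMatrix:
    """Samples x biallelic loci with unordered allele-pair calls.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    loci
        One row per locus with columns ``chrom, pos, ref, alt,
        variant_class, indel_anchor``, sorted by (chrom, pos), no
        duplicate (chrom, pos).
    dosage
        ``int8`` array of shape (n_samples, n_loci); alt-allele count in
        {0, 1, 2} or :data:`MISSING`.
    """

    samples: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        missing_cols = [c for c in LOCUS_COLUMNS if c not in self.loci.columns]
        if missing_cols:
            raise ValueError(f"loci table lacks columns {missing_cols}")
        self.loci = self.loci.reset_index(drop=True)
        keys = list(zip(self.loci["chrom"].map(chrom_sort_key), self.loci["pos"]))
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("loci must be sorted by (chrom, pos) without duplicates")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2} or MISSING (-1)")

    # -- basic geometry ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.loci["chrom"]:
            seen.setdefault(c, None)
        return list(seen)

    def sample_indices(self, samples: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in samples], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown sample {e.args[0]!r}") from None

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return (self.loci["chrom"] == chrom).to_numpy()

    # -- views ---------------------------------------------------------

    @property
    def is_missing(self) -> np.ndarray:
        return self.dosage == MISSING

    @property
    def is_het(self) -> np.ndarray:
        return self.dosage == 1

    def locus_missing_rate(self, samples: Sequence[str] | None = None) -> np.ndarray:
        d = self.dosage if samples is None else self.dosage[self.sample_indices(samples)]
        return (d == MISSING).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return self.is_missing.mean(axis=1)

    # -- subsetting ----------------------------------------------------

    def take_loci(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given loci (boolean mask or index array)."""
        m = np.asarray(mask_or_index)
        if m.dtype == bool:
            m = np.flatnonzero(m)
        return GenotypeMatrix(self.samples, self.loci.iloc[m], self.dosage[:, m])

    def take_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(samples)
        return GenotypeMatrix(list(samples), self.loci, self.dosage[idx])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.loci.copy(), self.dosage.copy())

    def row(self, sample: str) -> np.ndarray:
        return self.dosage[self.sample_indices([sample])[0]]


@dataclass
class DepthMatrix:
    """Per-sample x locus read counts accompanying a :class:`GenotypeMatrix`."""

    reads: np.ndarray

    def __post_init__(self) -> None:
        self.reads = np.asarray(self.reads)
        if (self.reads < 0).any():
            raise ValueError("read counts must be non-negative")


@dataclass
class SamplePanel:
    """Role assignment: sample id -> RET_REF | MAX_REF | QUERY."""

    roles: dict[str, str]

    def __post_init__(self) -> None:
        for s, r in self.roles.items():
            if r not in ROLES:
                raise ValueError(f"sample {s!r} has unknown role {r!r}")

    @property
    def ret_refs(self) -> list[str]:
        return [s for s, r in self.roles.items() if r == RET_REF]

    @property
    def max_refs(self) -> list[str]:
        return [s for s, r in self.roles.items() if r == MAX_REF]

    @property
    def refs(self) -> list[str]:
        return [s for s, r in self.roles.items() if r != QUERY]

    @property
    def queries(self) -> list[str]:
        return [s for s, r in self.roles.items() if r == QUERY]

    def validate_against(self, gm: GenotypeMatrix, discovery: bool = False) -> None:
        unknown = [s for s in self.roles if s not in gm.samples]
        if unknown:
            raise ValueError(f"panel samples absent from genotype matrix: {unknown}")
        if discovery and (len(self.ret_refs) < 2 or len(self.max_refs) < 2):
            raise ValueError("discovery requires >= 2 RET_REF and >= 2 MAX_REF samples")

    @classmethod
    def read_tsv(cls, path) -> "SamplePanel":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns[:2]) != ["sample", "role"]:
            raise ValueError("panel file must have columns: sample, role")
        return cls(dict(zip(df["sample"], df["role"])))

    def write_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample": list(self.roles), "role": list(self.roles.values())}
        ).to_csv(path, sep="\t", index=False)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals; touching/overlapping merge."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class MaskSet:
    """Per-sample genomic intervals flagged as introgressed.

    Intervals are 1-based inclusive bp coordinates, kept sorted and
    non-overlapping per sample per chromosome.
    """

    intervals: dict[str, dict[str, list[tuple[int, int]]]] = field(default_factory=dict)

    def add(self, sample: str, chrom: str, start: int, end: int) -> None:
        if start > end:
            raise ValueError(f"interval start {start} > end {end}")
        per = self.intervals.setdefault(sample, {}).setdefault(str(chrom), [])
        per.append((int(start), int(end)))
        self.intervals[sample][str(chrom)] = _merge_intervals(per)

    def for_sample(self, sample: str) -> dict[str, list[tuple[int, int]]]:
        return self.intervals.get(sample, {})

    @property
    def samples(self) -> list[str]:
        return list(self.intervals)

    def is_empty(self) -> bool:
        return not any(ivs for per in self.intervals.values() for ivs in per.values())

    def cell_mask(self, gm: GenotypeMatrix) -> np.ndarray:
        """Boolean samples x loci array: True where a call is mask-covered."""
        out = np.zeros((gm.n_samples, gm.n_loci), dtype=bool)
        chroms = set(gm.loci["chrom"])
        chrom_arr = gm.loci["chrom"].to_numpy()
        pos = gm.loci["pos"].to_numpy()
        for sample, per_chrom in self.intervals.items():
            if sample not in gm.samples:
                continue
            si = gm.sample_indices([sample])[0]
            for chrom, ivs in per_chrom.items():
                if ivs and chrom not in chroms:
                    raise ValueError(
                        f"mask interval on unknown chromosome {chrom!r} for {sample!r}"
                    )
                on = chrom_arr == chrom
                for s, e in ivs:
                    out[si] |= on & (pos >= s) & (pos <= e)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sample, chrom, s, e)
            for sample, per in self.intervals.items()
            for chrom, ivs in per.items()
            for s, e in ivs
        ]
        return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end"])

    def write_tsv(self, path) -> None:
        # BED-like but 1-based inclusive, documented as a non-standard offset
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "MaskSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        ms = cls()
        for r in df.itertuples(index=False):
            ms.add(r.sample, r.chrom, int(r.start), int(r.end))
        return ms
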