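"""Synthetic two-taxon gene pools, reference panels and admixed mosaics.

The generator emulates the data regime the pipeline is designed for:
two ancestral taxa (RET and MAX) differentiated at a mixture of fixed
and shared-polymorphism biallelic loci spread over nine chromosomes,
small reference panels (11 RET + 6 MAX accessions by default, optionally
carrying planted introgression blocks), and admixed query varieties
built as per-homolog ancestry-block mosaics (F1, BC(n), or arbitrary
layouts) — all with full ground truth.

Within a taxon, genotypes are drawn in Hardy–Weinberg equilibrium and
loci are in linkage equilibrium: ancestry blocks, not LD, carry the
spatial signal, which suffices because every pipeline statistic is
single-locus or a window mean.  Backcross mosaics are produced by
explicit meioses with one uniform-random crossover per chromosome, so
the expected donor fraction after n backcrosses is exactly 0.5^(n+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import LOCUS_COLUMNS, MISSING, DepthMatrix, GenotypeMatrix, SamplePanel
from .stats import nei_gst
from .windows import window_bounds

RET, MAX = "RET", "MAX"
BOUNDARY = "BOUNDARY"  # truth label for windows straddling a breakpoint

DEFAULT_N_CHROM = 9
DEFAULT_LOCI_PER_CHROM = 4340  # ~39k genome-wide
DEFAULT_CHROM_LENGTH = 30_000_000
DEFAULT_PROP_FIXED = 0.285  # fraction of loci fixed for alternative alleles
DEFAULT_BETA_SHAPE = 0.5  # symmetric Beta for shared-polymorphism frequencies
DEFAULT_PROP_INDEL = 0.225
DEFAULT_MISSING_RATE = 0.126
DEFAULT_MEAN_DEPTH = 34.2

_NUCS = np.array(list("ACGT"))


@dataclass
class AncestralModel:
    """True allele-frequency model of the two ancestral gene pools."""

    loci: pd.DataFrame  # chrom pos ref alt variant_class indel_anchor
    p_ret: np.ndarray  # true alt-allele frequency in RET
    p_max: np.ndarray  # true alt-allele frequency in MAX
    chrom_lengths: dict[str, int]
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.p_ret, self.p_max):
            if ((p < 0) | (p > 1)).any():
                raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def true_gst(self) -> np.ndarray:
        return nei_gst(self.p_ret, self.p_max)

    def fixed_difference(self) -> np.ndarray:
        """Loci fixed for alternative alleles between the taxa (true G_ST = 1)."""
        return np.abs(self.p_ret - self.p_max) == 1.0

    def freq_for(self, taxon: str) -> np.ndarray:
        return self.p_ret if taxon == RET else self.p_max


def simulate_ancestral_model(
    n_chrom: int = DEFAULT_N_CHROM,
    loci_per_chrom: int = DEFAULT_LOCI_PER_CHROM,
    chrom_length: int = DEFAULT_CHROM_LENGTH,
    prop_fixed: float = DEFAULT_PROP_FIXED,
    beta_shape: float = DEFAULT_BETA_SHAPE,
    prop_indel: float = DEFAULT_PROP_INDEL,
    identical_shared: bool = False,
    seed: int | None = None,
) -> AncestralModel:
    """Draw a two-taxon ancestral frequency model.

    A fraction ``prop_fixed`` of loci is fixed for alternative alleles
    (|p_ret - p_max| = 1, orientation random), interleaved uniformly at
    random with shared-polymorphism loci whose per-taxon frequencies are
    independent symmetric Beta(``beta_shape``) draws.  With
    ``identical_shared`` both taxa share one draw per locus (an
    undifferentiated control).  Reproducible given ``seed``.
    """
    if not 0 <= prop_fixed <= 1:
        raise ValueError("prop_fixed must lie in [0, 1]")
    if not 0 <= prop_indel <= 1:
        raise ValueError("prop_indel must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chrom + 1):
        pos = np.sort(
            rng.choice(np.arange(1, chrom_length + 1), size=loci_per_chrom, replace=False)
        )
        for p in pos:
            rows.append((str(c), int(p)))
    loci = pd.DataFrame(rows, columns=["chrom", "pos"])
    n = len(loci)

    is_indel = rng.random(n) < prop_indel
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    ref = _NUCS[ref_idx].astype(object)
    alt = _NUCS[alt_idx].astype(object)
    ins = rng.random(n) < 0.5
    alt = np.where(is_indel & ins, ref + alt, alt)  # insertion
    ref = np.where(is_indel & ~ins, alt + ref, ref)  # deletion
    loci["ref"] = ref
    loci["alt"] = alt
    loci["variant_class"] = np.where(is_indel, "INDEL", "SNP")
    loci["indel_anchor"] = is_indel
    loci = loci[LOCUS_COLUMNS]

    n_fixed = int(round(prop_fixed * n))
    fixed_idx = rng.choice(n, size=n_fixed, replace=False)
    if identical_shared:
        p_shared = rng.beta(beta_shape, beta_shape, size=n)
        p_ret = p_shared.copy()
        p_max = p_shared.copy()
    else:
        p_ret = rng.beta(beta_shape, beta_shape, size=n)
        p_max = rng.beta(beta_shape, beta_shape, size=n)
    orient = rng.random(n_fixed) < 0.5
    p_ret[fixed_idx] = np.where(orient, 1.0, 0.0)
    p_max[fixed_idx] = np.where(orient, 0.0, 1.0)

    return AncestralModel(
        loci=loci,
        p_ret=p_ret,
        p_max=p_max,
        chrom_lengths={str(c): chrom_length for c in range(1, n_chrom + 1)},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ancestry specifications


Block = tuple[int, int, str]  # (bp_start, bp_end, taxon), 1-based inclusive


def _check_tiling(blocks: list[Block], length: int) -> None:
    if not blocks:
        raise ValueError("homolog has no blocks")
    if blocks[0][0] != 1 or blocks[-1][1] != length:
        raise ValueError(f"blocks must tile [1, {length}]")
    for (s1, e1, t1), (s2, e2, t2) in zip(blocks, blocks[1:]):
        if s2 != e1 + 1:
            raise ValueError(f"gap or overlap between blocks at {e1}..{s2}")
    for s, e, t in blocks:
        if t not in (RET, MAX):
            raise ValueError(f"unknown taxon {t!r}")
        if s > e:
            raise ValueError(f"block start {s} > end {e}")


@dataclass
class AncestrySpec:
    """Per-homolog ancestry-block layout of one (synthetic) sample.

    ``blocks[chrom]`` holds two block lists — one per homolog — each
    tiling [1, chromosome length] exactly.
    """

    sample: str
    blocks: dict[str, tuple[list[Block], list[Block]]]
    pedigree: str = "explicit"

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        for chrom, length in chrom_lengths.items():
            if chrom not in self.blocks:
                raise ValueError(f"spec for {self.sample} lacks chromosome {chrom}")
            for hom in self.blocks[chrom]:
                _check_tiling(hom, length)

    # -- constructors --------------------------------------------------

    @classmethod
    def pure(cls, sample: str, taxon: str, chrom_lengths: dict[str, int]) -> "AncestrySpec":
        blocks = {
            c: ([(1, L, taxon)], [(1, L, taxon)]) for c, L in chrom_lengths.items()
        }
        return cls(sample, blocks, pedigree=f"PURE_{taxon}")

    @classmethod
    def f1(cls, sample: str, chrom_lengths: dict[str, int]) -> "AncestrySpec":
        blocks = {
            c: ([(1, L, RET)], [(1, L, MAX)]) for c, L in chrom_lengths.items()
        }
        return cls(sample, blocks, pedigree="F1")

    @classmethod
    def backcross(
        cls,
        sample: str,
        n: int,
        recurrent: str,
        chrom_lengths: dict[str, int],
        rng: np.random.Generator,
    ) -> "AncestrySpec":
        """BC(n): n successive meioses of the hybrid against the
        recurrent taxon, one uniform-random crossover per chromosome per
        meiosis.  Expected donor-genome fraction: 0.5^(n+1).
        """
        if n < 1:
            raise ValueError("backcross generation count must be >= 1")
        donor = MAX if recurrent == RET else RET
        hyb = {
            c: ([(1, L, donor)], [(1, L, recurrent)]) for c, L in chrom_lengths.items()
        }
        for _ in range(n):
            gamete = {
                c: _meiosis_one_crossover(hyb[c][0], hyb[c][1], L, rng)
                for c, L in chrom_lengths.items()
            }
            hyb = {c: (gamete[c], [(1, L, recurrent)]) for c, L in chrom_lengths.items()}
        return cls(sample, hyb, pedigree=f"BC({n},{recurrent})")

    @classmethod
    def from_blocks(
        cls, sample: str, blocks: dict[str, tuple[list[Block], list[Block]]]
    ) -> "AncestrySpec":
        return cls(sample, blocks, pedigree="explicit")

    def with_block(
        self, chrom: str, start: int, end: int, taxon: str, homologs=(0,)
    ) -> "AncestrySpec":
        """Copy of this spec with an introgression block planted."""
        new = {c: (list(h0), list(h1)) for c, (h0, h1) in self.blocks.items()}
        length = new[chrom][0][-1][1]
        if start < 1 or end > length:
            raise ValueError(f"block {start}..{end} outside chromosome {chrom}")
        for h in homologs:
            new[chrom] = tuple(
                _overlay(list(new[chrom][i]), (start, end, taxon)) if i == h else new[chrom][i]
                for i in range(2)
            )
        return AncestrySpec(self.sample, new, pedigree=self.pedigree + "+block")

    # -- queries -------------------------------------------------------

    def taxa_at(self, chrom: str, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-homolog taxon (as 'RET'/'MAX') at the given bp positions."""
        out = []
        for hom in self.blocks[chrom]:
            starts = np.array([b[0] for b in hom])
            taxa = np.array([b[2] for b in hom])
            idx = np.searchsorted(starts, positions, side="right") - 1
            out.append(taxa[idx])
        return out[0], out[1]

    def expected_prop_max(self, chrom_lengths=None, loci: pd.DataFrame | None = None) -> float:
        """True MAX fraction over both homologs.

        bp-weighted over the genome by default; marker-weighted when a
        loci table (chrom, pos) is given.
        """
        if loci is not None:
            tot = n_max = 0
            for chrom in loci["chrom"].unique():
                pos = loci.loc[loci["chrom"] == chrom, "pos"].to_numpy()
                t0, t1 = self.taxa_at(str(chrom), pos)
                n_max += int((t0 == MAX).sum() + (t1 == MAX).sum())
                tot += 2 * len(pos)
            return n_max / tot
        tot = sum(chrom_lengths.values()) * 2
        n_max = sum(
            e - s + 1
            for c in chrom_lengths
            for hom in self.blocks[c]
            for s, e, t in hom
            if t == MAX
        )
        return n_max / tot


def _overlay(hom: list[Block], block: Block) -> list[Block]:
    """Replace the ancestry of ``hom`` inside ``block``'s span."""
    s, e, taxon = block
    out: list[Block] = []
    for bs, be, bt in hom:
        if be < s or bs > e:
            out.append((bs, be, bt))
            continue
        if bs < s:
            out.append((bs, s - 1, bt))
        if be > e:
            out.append((e + 1, be, bt))
    out.append((s, e, taxon))
    out.sort()
    # merge same-taxon neighbours
    merged: list[Block] = []
    for b in out:
        if merged and merged[-1][2] == b[2] and merged[-1][1] + 1 == b[0]:
            merged[-1] = (merged[-1][0], b[1], b[2])
        else:
            merged.append(b)
    return merged


def _meiosis_one_crossover(
    hom_a: list[Block], hom_b: list[Block], length: int, rng: np.random.Generator
) -> list[Block]:
    """Gamete from one crossover at a uniform-random bp, random start homolog."""
    cut = int(rng.integers(1, length))  # crossover between cut and cut+1
    first, second = (hom_a, hom_b) if rng.random() < 0.5 else (hom_b, hom_a)
    left = [(s, min(e, cut), t) for s, e, t in first if s <= cut]
    right = [(max(s, cut + 1), e, t) for s, e, t in second if e > cut]
    gam = left + right
    merged: list[Block] = []
    for b in gam:
        if merged and merged[-1][2] == b[2]:
            merged[-1] = (merged[-1][0], b[1], b[2])
        else:
            merged.append(b)
    return merged


# ---------------------------------------------------------------------------
# genotype drawing


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset: the ancestry spec per sample."""

    specs: dict[str, AncestrySpec] = field(default_factory=dict)

    def expected_prop_max(self, sample: str, chrom_lengths=None, loci=None) -> float:
        return self.specs[sample].expected_prop_max(chrom_lengths, loci)


def simulate_genotypes(
    model: AncestralModel,
    specs: list[AncestrySpec],
    seed: int | None = None,
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Draw diploid genotypes for each ancestry spec.

    Each homolog's allele at each locus is a Bernoulli draw from the
    taxon frequency of the ancestry block covering that position (HWE
    within blocks, linkage equilibrium across loci).
    """
    rng = np.random.default_rng(seed)
    chrom_arr = model.loci["chrom"].to_numpy()
    pos_arr = model.loci["pos"].to_numpy()
    n = model.n_loci
    dosage = np.zeros((len(specs), n), dtype=np.int8)
    for i, spec in enumerate(specs):
        spec.validate(model.chrom_lengths)
        for chrom in model.chroms:
            m = chrom_arr == chrom
            pos = pos_arr[m]
            t0, t1 = spec.taxa_at(chrom, pos)
            for taxa in (t0, t1):
                p = np.where(taxa == RET, model.p_ret[m], model.p_max[m])
                dosage[i, m] += (rng.random(p.size) < p).astype(np.int8)
    gm = GenotypeMatrix([s.sample for s in specs], model.loci.copy(), dosage)
    return gm, SyntheticTruth({s.sample: s for s in specs})


def simulate_reference_panel(
    model: AncestralModel,
    n_ret: int = 11,
    n_max: int = 6,
    introgressions: dict[str, AncestrySpec] | None = None,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, SamplePanel, SyntheticTruth]:
    """Reference accessions of both taxa, optionally with planted introgressions.

    Samples are named ``ret01..`` / ``max01..``; ``introgressions`` maps
    a sample name to a replacement :class:`AncestrySpec` (build one with
    :meth:`AncestrySpec.pure` + :meth:`AncestrySpec.with_block`).
    """
    names_ret = [f"ret{i + 1:02d}" for i in range(n_ret)]
    names_max = [f"max{i + 1:02d}" for i in range(n_max)]
    specs = []
    for name in names_ret + names_max:
        taxon = RET if name.startswith("ret") else MAX
        spec = AncestrySpec.pure(name, taxon, model.chrom_lengths)
        if introgressions and name in introgressions:
            spec = introgressions[name]
        specs.append(spec)
    gm, truth = simulate_genotypes(model, specs, seed)
    roles = {n: "RET_REF" for n in names_ret} | {n: "MAX_REF" for n in names_max}
    return gm, SamplePanel(roles), truth


def simulate_admixed_variety(
    model: AncestralModel, spec: AncestrySpec, seed: int | None = None
) -> tuple[np.ndarray, AncestrySpec]:
    """Single admixed genome: the dosage row plus its truth entry."""
    gm, _ = simulate_genotypes(model, [spec], seed)
    return gm.dosage[0], spec


def simulate_queries(
    model: AncestralModel, specs: list[AncestrySpec], seed: int | None = None
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    return simulate_genotypes(model, specs, seed)


def combine_panels(gm_refs: GenotypeMatrix, gm_queries: GenotypeMatrix) -> GenotypeMatrix:
    """Stack reference and query matrices sharing the same loci."""
    if not gm_refs.loci[["chrom", "pos"]].equals(gm_queries.loci[["chrom", "pos"]]):
        raise ValueError("matrices must share identical loci")
    return GenotypeMatrix(
        gm_refs.samples + gm_queries.samples,
        gm_refs.loci,
        np.vstack([gm_refs.dosage, gm_queries.dosage]),
    )


def inject_missingness(
    gm: GenotypeMatrix,
    rate: float = DEFAULT_MISSING_RATE,
    seed: int | None = None,
    with_depth: bool = False,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
) -> tuple[GenotypeMatrix, DepthMatrix | None]:
    """Set each call missing independently with probability ``rate``.

    With ``with_depth`` a read-depth matrix is also returned in which
    exactly the missing cells carry fewer than 5 reads (uniform 0..4)
    and present cells carry Poisson(``mean_depth``) reads clipped to a
    minimum of 5 — so a depth-threshold pass reproduces the pattern.
    """
    if not 0 <= rate < 1:
        raise ValueError("missingness rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = gm.copy()
    drop = rng.random(out.dosage.shape) < rate
    out.dosage[drop] = MISSING
    dm = None
    if with_depth:
        reads = np.maximum(rng.poisson(mean_depth, size=out.dosage.shape), 5)
        reads[drop] = rng.integers(0, 5, size=int(drop.sum()))
        dm = DepthMatrix(reads)
    return out, dm


# ---------------------------------------------------------------------------
# truth in window space


def truth_windows(
    spec: AncestrySpec, dps: pd.DataFrame, win: int = 20
) -> list[str]:
    """Expected karyotype state of each successive ``win``-DP window.

    Uses the same window enumeration as the painting stage.  Windows
    whose span contains an ancestry breakpoint on either homolog are
    labelled ``BOUNDARY`` and should be excluded from recovery scoring.
    """
    from .karyotype import S_HET, S_MAX, S_RET

    states: list[str] = []
    chrom_arr = dps["chrom"].to_numpy()
    pos_arr = dps["pos"].to_numpy()
    seen: dict[str, None] = {}
    for c in chrom_arr:
        seen.setdefault(c, None)
    for chrom in seen:
        pos = pos_arr[chrom_arr == chrom]
        t0, t1 = spec.taxa_at(str(chrom), pos)
        for s, e in window_bounds(len(pos), win, win):
            w0, w1 = t0[s:e], t1[s:e]
            if len(set(w0)) > 1 or len(set(w1)) > 1:
                states.append(BOUNDARY)
                continue
            pair = {w0[0], w1[0]}
            if pair == {RET}:
                states.append(S_RET)
            elif pair == {MAX}:
                states.append(S_MAX)
            else:
                states.append(S_HET)
    return states
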