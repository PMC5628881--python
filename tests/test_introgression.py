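"""Introgression detection on planted blocks, and masking semantics."""

import numpy as np
import pytest

from phylokaryo import (
    MISSING,
    AncestrySpec,
    MaskSet,
    apply_mask,
    simulate_reference_panel,
)
from phylokaryo.dp import compute_gst_ret_max
from phylokaryo.introgression import (
    detect_introgressions,
    heterozygosity_track,
    scan_reference_panel,
    similarity_tracks,
)
from phylokaryo.stats import taxon_centroid

from conftest import make_gm


def _scan_setup(model, introgressions, seed):
    gm, panel, truth = simulate_reference_panel(
        model, introgressions=introgressions, seed=seed
    )
    gst1 = compute_gst_ret_max(gm, panel)
    cen_ret = taxon_centroid(gm, panel.ret_refs)
    cen_max = taxon_centroid(gm, panel.max_refs)
    return gm, panel, gst1, cen_ret, cen_max


def _jaccard(a, b):
    (s1, e1), (s2, e2) = a, b
    inter = max(0, min(e1, e2) - max(s1, s2) + 1)
    union = (e1 - s1 + 1) + (e2 - s2 + 1) - inter
    return inter / union


class TestDetection:
    def test_clean_references_empty_or_tiny_mask(self, small_model):
        gm, panel, gst1, cr, cm = _scan_setup(small_model, None, seed=31)
        masks = scan_reference_panel(gm, panel, cr, cm, gst1)
        genome = sum(small_model.chrom_lengths.values())
        for sample in panel.refs:
            masked = sum(
                e - s + 1
                for ivs in masks.for_sample(sample).values()
                for s, e in ivs
            )
            assert masked / genome < 0.05  # false-positive fraction

    def test_heterozygous_planted_block_recovered(self, small_model):
        L = small_model.chrom_lengths["1"]
        block = (int(L * 0.4), int(L * 0.7))  # ~ 9 Mb, spans many windows
        spec = AncestrySpec.pure("ret01", "RET", small_model.chrom_lengths).with_block(
            "1", *block, "MAX", homologs=(0,)
        )
        gm, panel, gst1, cr, cm = _scan_setup(small_model, {"ret01": spec}, seed=32)
        masks = scan_reference_panel(gm, panel, cr, cm, gst1)
        ivs = masks.for_sample("ret01").get("1", [])
        assert ivs, "planted block not detected"
        best = max(ivs, key=lambda iv: _jaccard(iv, block))
        assert _jaccard(best, block) >= 0.8
        # recovered interval overlaps >= 90% of the truth block
        s, e = best
        overlap = max(0, min(e, block[1]) - max(s, block[0]) + 1)
        assert overlap / (block[1] - block[0] + 1) >= 0.9

    def test_ponkan_like_het_hom_het_merges_to_one_interval(self, small_model):
        # heterozygous, then homozygous, then heterozygous MAX introgression
        # at the end of a chromosome -> one merged mask interval
        L = small_model.chrom_lengths["2"]
        a, b, c = int(L * 0.55), int(L * 0.75), int(L * 0.9)
        spec = (
            AncestrySpec.pure("ret02", "RET", small_model.chrom_lengths)
            .with_block("2", a, b - 1, "MAX", homologs=(0,))
            .with_block("2", b, c - 1, "MAX", homologs=(0, 1))
            .with_block("2", c, L, "MAX", homologs=(1,))
        )
        gm, panel, gst1, cr, cm = _scan_setup(small_model, {"ret02": spec}, seed=33)
        masks = scan_reference_panel(gm, panel, cr, cm, gst1)
        ivs = masks.for_sample("ret02").get("2", [])
        assert len(ivs) == 1
        s, e = ivs[0]
        overlap = max(0, min(e, L) - max(s, a) + 1)
        assert overlap / (L - a + 1) >= 0.9

    def test_no_flags_below_thresholds(self):
        from phylokaryo.windows import Window, WindowTrack

        def track(vals, chrom="1"):
            t = WindowTrack(chrom)
            for i, v in enumerate(vals):
                t.windows.append(Window(i * 40, i * 40 + 120, i * 1000 + 1,
                                        i * 1000 + 500, v))
            return t

        ho = {"1": track([0.1, 0.25, 0.30])}
        own = {"1": track([0.9, 0.85, 0.9])}
        other = {"1": track([0.2, 0.3, 0.25])}
        assert detect_introgressions(ho, own, other) == {}

    def test_ho_gap_zone_not_flagged_by_condition_a(self):
        from phylokaryo.windows import Window, WindowTrack

        t = WindowTrack("1")
        t.windows.append(Window(0, 120, 1, 500, 0.35))  # in (0.30, 0.40]
        own = WindowTrack("1")
        own.windows.append(Window(0, 60, 1, 500, 0.9))
        other = WindowTrack("1")
        other.windows.append(Window(0, 60, 1, 500, 0.2))
        assert detect_introgressions({"1": t}, {"1": own}, {"1": other}) == {}

    def test_detection_deterministic(self, small_model):
        gm, panel, gst1, cr, cm = _scan_setup(small_model, None, seed=34)
        m1 = scan_reference_panel(gm, panel, cr, cm, gst1)
        m2 = scan_reference_panel(gm, panel, cr, cm, gst1)
        assert m1.to_frame().equals(m2.to_frame())


class TestSimilarityTracks:
    def test_pure_reference_dominates_own_centroid(self, small_refs):
        gm, panel, _ = small_refs
        gst1 = compute_gst_ret_max(gm, panel)
        cr = taxon_centroid(gm, panel.ret_refs)
        cm = taxon_centroid(gm, panel.max_refs)
        s_ret, s_max = similarity_tracks(gm, panel.ret_refs[0], cr, cm, gst1)
        for chrom in s_ret:
            assert (s_ret[chrom].values > s_max[chrom].values).all()

    def test_hom_block_crosses_tracks_inside_block(self, small_model):
        L = small_model.chrom_lengths["1"]
        block = (int(L * 0.3), int(L * 0.7))
        spec = AncestrySpec.pure("ret01", "RET", small_model.chrom_lengths).with_block(
            "1", *block, "MAX", homologs=(0, 1)
        )
        gm, panel, gst1, cr, cm = _scan_setup(small_model, {"ret01": spec}, seed=35)
        s_ret, s_max = similarity_tracks(gm, "ret01", cr, cm, gst1)
        crossed = [
            w_max.value > w_ret.value
            for w_ret, w_max in zip(s_ret["1"].windows, s_max["1"].windows)
            if w_ret.bp_start >= block[0] and w_ret.bp_end <= block[1]
        ]
        assert crossed and np.mean(crossed) > 0.9


class TestApplyMask:
    def test_empty_mask_is_identity(self):
        gm = make_gm([[0, 1, 2]])
        out = apply_mask(gm, MaskSet())
        np.testing.assert_array_equal(out.dosage, gm.dosage)

    def test_whole_chromosome_mask(self):
        gm = make_gm([[1, 1, 1, 1], [2, 2, 2, 2]],
                     chroms=["1", "1", "2", "2"], positions=[10, 20, 10, 20])
        mask = MaskSet()
        mask.add("s0", "2", 1, 10**9)
        out = apply_mask(gm, mask)
        assert list(out.dosage[0]) == [1, 1, MISSING, MISSING]
        assert list(out.dosage[1]) == [2, 2, 2, 2]

    def test_brute_force_cell_containment(self):
        rng = np.random.default_rng(36)
        pos = sorted(rng.choice(range(1, 1000), 40, replace=False))
        gm = make_gm(rng.choice([0, 1, 2], size=(3, 40)), positions=[int(p) for p in pos])
        mask = MaskSet()
        mask.add("s0", "1", 100, 400)
        mask.add("s2", "1", 350, 900)
        out = apply_mask(gm, mask)
        for i, s in enumerate(gm.samples):
            for j, p in enumerate(pos):
                expect_masked = any(
                    a <= p <= b for a, b in mask.for_sample(s).get("1", [])
                )
                if expect_masked:
                    assert out.dosage[i, j] == MISSING
                else:
                    assert out.dosage[i, j] == gm.dosage[i, j]

    def test_masking_monotone(self):
        gm = make_gm(np.ones((2, 10), dtype=int))
        m1 = MaskSet()
        m1.add("s0", "1", 100, 130)
        out1 = apply_mask(gm, m1)
        m1.add("s0", "1", 150, 170)
        out2 = apply_mask(gm, m1)
        # adding an interval never un-masks a cell
        assert ((out1.dosage == MISSING) <= (out2.dosage == MISSING)).all()

    def test_unknown_chromosome_error(self):
        gm = make_gm([[0]])
        mask = MaskSet()
        mask.add("s0", "7", 1, 10)
        with pytest.raises(ValueError, match="unknown chromosome"):
            apply_mask(gm, mask)
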