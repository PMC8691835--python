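"""Tiling, mutant tiles, shuffles, controls, ATAC and combination designs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cheqseq import design, motifs
from cheqseq.design import RegionRecord, TileRecord

from conftest import random_sequence


def enumerate_tile_starts(L, tile_len, step, offset):
    """Exhaustive-enumeration oracle for the tile stop rule."""
    starts = []
    s = offset
    while s + tile_len - 1 <= L:
        starts.append(s)
        s += step
    return starts


class TestTiling:
    def test_1990bp_region_yields_91_tiles_last_at_1801(self):
        region = RegionRecord("R", "A" * 1990)
        tiles = design.generate_tiles(region)
        assert len(tiles) == 91
        assert tiles[-1].start == 1801
        assert tiles[-1].start + tiles[-1].length - 1 == 1990

    def test_exact_length_region_gives_single_tile(self):
        tiles = design.generate_tiles(RegionRecord("R", "C" * 190))
        assert len(tiles) == 1 and tiles[0].start == 1

    def test_stop_rule_boundary_209bp(self):
        tiles = design.generate_tiles(RegionRecord("R", "G" * 209))
        assert len(tiles) == 1  # a second tile would end at 210 > 209

    def test_too_short_region_raises_with_region_id(self):
        with pytest.raises(ValueError, match="shorty"):
            design.generate_tiles(RegionRecord("shorty", "A" * 100))

    @pytest.mark.parametrize("offset", [1, 11])
    def test_closed_form_equals_enumeration_for_random_lengths(self, offset):
        rng = np.random.default_rng(42)
        for L in rng.integers(200, 3001, size=100):
            L = int(L)
            expected = enumerate_tile_starts(L, 190, 20, offset)
            assert design.expected_tile_count(L, start_offset=offset) == len(expected)
            tiles = design.generate_tiles(
                RegionRecord("R", "A" * L), start_offset=offset
            )
            assert [t.start for t in tiles] == expected

    def test_sublibrary_union_forms_10bp_grid(self):
        region = RegionRecord("R", "T" * 1990)
        a = design.generate_tiles(region, start_offset=1)
        b = design.generate_tiles(region, start_offset=11)
        starts = sorted([t.start for t in a] + [t.start for t in b])
        assert all(s2 - s1 == 10 for s1, s2 in zip(starts, starts[1:]))
        assert {t.sublibrary for t in a} == {"A"}
        assert {t.sublibrary for t in b} == {"B"}

    @pytest.mark.parametrize("step", [20, 120])
    def test_consecutive_starts_differ_by_step(self, step):
        tiles = design.generate_tiles(RegionRecord("R", "A" * 1500), step=step)
        diffs = {t2.start - t1.start for t1, t2 in zip(tiles, tiles[1:])}
        assert diffs == {step}


class TestMutantTiles:
    def test_one_mutant_per_motif_with_hits(self, graded_pwm, palindromic_pwm):
        rng = np.random.default_rng(3)
        core = random_sequence(rng, 80) + "CACGTG" + random_sequence(rng, 104)
        tile = design.generate_tiles(RegionRecord("R", core))[0]
        mutants = design.generate_mutant_tiles(
            [tile], [palindromic_pwm, graded_pwm], threshold=5.0
        )
        by_motif = {m.mutated_motif for m in mutants}
        assert "EBOX" in by_motif
        for m in mutants:
            assert m.category == "mutated"
            n_diff = sum(a != b for a, b in zip(m.sequence, tile.sequence))
            assert n_diff == len(m.mutated_positions)
            assert n_diff % 2 == 0 and n_diff >= 2

    def test_motifs_mutated_separately_not_combined(self, palindromic_pwm):
        other = motifs.pwm_from_consensus("ACAAAGAC", name="SOXISH")
        rng = np.random.default_rng(5)
        seq = (random_sequence(rng, 30) + "CACGTG" + random_sequence(rng, 60)
               + "ACAAAGAC" + random_sequence(rng, 86))
        tile = design.generate_tiles(RegionRecord("R", seq))[0]
        mutants = design.generate_mutant_tiles(
            [tile], [palindromic_pwm, other], threshold=5.0
        )
        assert sorted(m.mutated_motif for m in mutants) == ["EBOX", "SOXISH"]

    def test_tile_without_hits_contributes_nothing(self, palindromic_pwm):
        tile = design.generate_tiles(RegionRecord("R", "AT" * 95))[0]
        assert design.generate_mutant_tiles([tile], [palindromic_pwm], 5.0) == []

    def test_non_wt_input_rejected(self, palindromic_pwm):
        tile = TileRecord("t", "R", 1, 190, "A" * 190, "shuffled")
        with pytest.raises(ValueError, match="not category WT"):
            design.generate_mutant_tiles([tile], [palindromic_pwm], 5.0)

    def test_overlapping_hits_skip_already_modified_windows(self, palindromic_pwm):
        # back-to-back overlapping E-boxes: CACGTGTG contains one clean hit,
        # CACGTGCACGTG two non-overlapping ones
        rng = np.random.default_rng(9)
        seq = random_sequence(rng, 40) + "CACGCACGTGTG" + random_sequence(rng, 138)
        tile = design.generate_tiles(RegionRecord("R", seq))[0]
        mutants = design.generate_mutant_tiles([tile], [palindromic_pwm], 5.0)
        for m in mutants:
            rescan = motifs.scan(m.sequence, palindromic_pwm, threshold=5.0)
            assert rescan == []


class TestShuffle:
    def test_forced_homopolymer_is_identity(self):
        assert design.shuffle_klet("AAAA", k=2, seed=0) == "AAAA"

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=190), st.integers(0, 10))
    def test_dinucleotide_counts_preserved(self, seq, seed):
        shuffled = design.shuffle_klet(seq, k=2, seed=seed)
        assert design.klet_counts(shuffled, 2) == design.klet_counts(seq, 2)
        assert sorted(shuffled) == sorted(seq)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_klet_counts_preserved_for_all_k(self, k):
        rng = np.random.default_rng(12)
        for _ in range(10):
            seq = random_sequence(rng, 190)
            shuffled = design.shuffle_klet(seq, k=k, seed=int(rng.integers(1 << 30)))
            if k > 1:
                assert design.klet_counts(shuffled, k) == design.klet_counts(seq, k)
            assert sorted(shuffled) == sorted(seq)

    def test_seed_determinism(self):
        seq = random_sequence(np.random.default_rng(1), 190)
        assert design.shuffle_klet(seq, seed=5) == design.shuffle_klet(seq, seed=5)
        outputs = {design.shuffle_klet(seq, seed=s) for s in range(10)}
        assert len(outputs) > 1

    def test_k_longer_than_sequence_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            design.shuffle_klet("ACG", k=4)


class TestHomopolymerFilter:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGTAAAAAAGT", True),   # run of 6
            ("ACGTAAAAAGT", False),   # run of 5
            ("GGGGGG", True),
            ("ACGT", False),
        ],
    )
    def test_boundary(self, seq, expected):
        assert design.has_homopolymer(seq) is expected

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            design.has_homopolymer("")


class TestShuffledControls:
    def _candidates(self, n, rng, planted=None, prefix="c"):
        out = []
        for i in range(n):
            seq = random_sequence(rng, 190)
            if planted is not None:
                seq = seq[:50] + planted + seq[50 + len(planted):]
            out.append(
                TileRecord(f"{prefix}{i}", "shuffled", 1, 190, seq, "shuffled")
            )
        return out

    def test_selection_is_reproducible_and_sized(self, palindromic_pwm):
        rng = np.random.default_rng(21)
        pool = self._candidates(300, rng)
        sel1 = design.select_shuffled_controls(pool, [palindromic_pwm], 5.0,
                                               n=100, seed=7)
        sel2 = design.select_shuffled_controls(pool, [palindromic_pwm], 5.0,
                                               n=100, seed=7)
        assert len(sel1) == 100
        assert [t.tile_id for t in sel1] == [t.tile_id for t in sel2]

    def test_planted_motif_candidates_never_selected(self, palindromic_pwm):
        rng = np.random.default_rng(22)
        clean = self._candidates(80, rng)
        dirty = self._candidates(40, rng, planted="CACGTG", prefix="dirty")
        sel = design.select_shuffled_controls(clean + dirty, [palindromic_pwm],
                                              10.0, n=50, seed=1)
        dirty_ids = {t.tile_id for t in dirty}
        assert not ({t.tile_id for t in sel} & dirty_ids)

    def test_requesting_more_than_pool_raises_with_count(self, palindromic_pwm):
        rng = np.random.default_rng(23)
        pool = self._candidates(10, rng)
        with pytest.raises(ValueError, match="motif-free candidates available"):
            design.select_shuffled_controls(pool, [palindromic_pwm], 10.0, n=50)

    def test_make_shuffled_controls_end_to_end(self, palindromic_pwm):
        rng = np.random.default_rng(24)
        tiles = [
            TileRecord(f"t{i}", "R", 1, 190, random_sequence(rng, 190), "WT")
            for i in range(120)
        ]
        controls = design.make_shuffled_controls(tiles, [palindromic_pwm], 10.0,
                                                 n=50, seed=3)
        assert len(controls) == 50
        for c in controls:
            assert c.category == "shuffled"
            assert not design.has_homopolymer(c.sequence)
            assert motifs.scan(c.sequence, palindromic_pwm, threshold=10.0) == []


class TestAtacDesign:
    def test_summit_arithmetic_and_total_length(self):
        genome = {"chr1": "".join(
            "ACGT"[i % 4] for i in range(1000))}
        oligos = design.design_atac_regions(
            [("REG_1", "chr1", 300)], genome, {"REG_1": "ACGTACGT"},
            spacer="T" * 16,
        )
        (o,) = oligos
        assert (o.start, o.end) == (50, 550)
        assert len(o.sequence) == 501
        assert len(o.oligo) == 501 + 16 + 8
        assert o.sequence == genome["chr1"][49:550]

    def test_duplicate_barcodes_rejected(self):
        genome = {"chr1": "A" * 1000}
        with pytest.raises(ValueError, match="duplicate"):
            design.design_atac_regions(
                [("R1", "chr1", 300), ("R2", "chr1", 600)], genome,
                {"R1": "AAAAAAAA", "R2": "AAAAAAAA"},
            )

    def test_summit_too_close_to_edge_raises(self):
        genome = {"chr1": "A" * 1000}
        with pytest.raises(ValueError, match="R1"):
            design.design_atac_regions([("R1", "chr1", 100)], genome,
                                       {"R1": "ACGTACGT"})


class TestComboDesign:
    def _background(self, seed=0):
        return random_sequence(np.random.default_rng(seed), 259)

    def test_empty_layout_leaves_background_unchanged(self):
        bg = self._background()
        (combo,) = design.design_sox_mitf_combos(
            [bg], [design.ComboLayout("empty", ())], ["ACGTACGTACG"]
        )
        assert combo.designed_sequence == bg
        assert combo.oligo == design.COMBO_ADAPTOR5 + combo.barcode + bg + design.COMBO_ADAPTOR3

    def test_centered_sox_occupies_positions_123_to_138(self):
        bg = self._background(1)
        (combo,) = design.design_sox_mitf_combos(
            [bg], [design.ComboLayout("sox_center", (("SOX_dimer", 0),))],
            ["ACGTACGTACG"],
        )
        s = combo.designed_sequence
        assert len(s) == 259
        assert s[122:138] == design.SOX_DIMER_SITE
        assert s[:122] == bg[:122] and s[138:] == bg[138:]

    def test_oligo_length_is_300(self):
        layout = design.layout_from_spacing(
            "m_s_m_25", ["MITF", "SOX_dimer", "MITF"], 25
        )
        combos = design.design_sox_mitf_combos(
            [self._background(2), self._background(3)], [layout],
            ["AAAAAAAAAAC", "AAAAAAAAAAG"],
        )
        assert len(combos) == 2
        for c in combos:
            assert len(c.oligo) == 15 + 11 + 259 + 15 == 300

    def test_edge_spacing_is_respected(self):
        layout = design.layout_from_spacing(
            "s50", ["MITF", "SOX_dimer", "MITF"], 50
        )
        bg = self._background(4)
        (combo,) = design.design_sox_mitf_combos([bg], [layout], ["ACGTACGTACG"])
        s = combo.designed_sequence
        sox_at = s.find(design.SOX_DIMER_SITE)
        assert s[122:138] == design.SOX_DIMER_SITE
        left_mitf_end = sox_at - 50
        assert s[left_mitf_end - 6 : left_mitf_end] == design.MITF_SITE
        right_mitf_start = sox_at + 16 + 50
        assert s[right_mitf_start : right_mitf_start + 6] == design.MITF_SITE

    def test_overlapping_layout_raises(self):
        layout = design.ComboLayout(
            "clash", (("SOX_dimer", 0), ("MITF", 5))
        )
        with pytest.raises(ValueError, match="clash"):
            design.design_sox_mitf_combos([self._background(5)], [layout],
                                          ["ACGTACGTACG"])

    def test_duplicate_barcodes_rejected(self):
        layouts = [design.ComboLayout("a", ()), design.ComboLayout("b", ())]
        with pytest.raises(ValueError, match="unique"):
            design.design_sox_mitf_combos([self._background(6)], layouts,
                                          ["AAAAAAAAAAA", "AAAAAAAAAAA"])


class TestAdaptorsAndManifest:
    def test_add_adaptors_concatenates_in_order(self):
        tiles = [
            TileRecord("t1", "R", 1, 190, "A" * 190, "WT"),
            TileRecord("t2", "R", 21, 190, "C" * 190, "WT"),
        ]
        oligos = design.add_adaptors(tiles, "G" * 15, "T" * 15)
        assert [len(o) for o in oligos] == [220, 220]
        assert oligos[0] == "G" * 15 + "A" * 190 + "T" * 15
        assert design.add_adaptors([], "G", "T") == []
        with pytest.raises(ValueError):
            design.add_adaptors(tiles, "", "T")

    def test_design_round_trip_is_lossless(self, tmp_path, palindromic_pwm):
        rng = np.random.default_rng(31)
        seq = random_sequence(rng, 80) + "CACGTG" + random_sequence(rng, 304)
        tiles = design.generate_tiles(RegionRecord("GENE_-001I", seq))
        mutants = design.generate_mutant_tiles(tiles, [palindromic_pwm], 5.0)
        all_tiles = tiles + mutants
        design.write_design(all_tiles, tmp_path / "d.fa", tmp_path / "d.tsv")
        back = design.read_design(tmp_path / "d.tsv")
        assert back == all_tiles
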