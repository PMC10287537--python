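"""Fractional counting, TPM, rRNA depletion, coverage, downsampling."""

import numpy as np
import pandas as pd
import pytest

from dosagecomp import (
    GeneCopy,
    InputError,
    UndefinedValueError,
    antisense_fraction,
    count_fragments,
    downsample,
    filter_rrna,
    fragments_frame,
    per_base_coverage,
    tpm,
)


class TestCountFragments:
    def test_fragment_inside_single_gene_counts_one(self):
        genes = [GeneCopy("g1", "f1", "c", 100, 400, "+")]
        frags = fragments_frame(["c"], [150], [250], ["+"])
        counts = count_fragments(frags, genes, "sense")
        assert counts["g1"] == 1.0

    def test_proportional_split_between_two_genes(self):
        genes = [
            GeneCopy("g1", "f1", "c", 0, 160, "+"),
            GeneCopy("g2", "f2", "c", 160, 300, "+"),
        ]
        # fragment [100, 200): 60 bp in g1, 40 bp in g2
        frags = fragments_frame(["c"], [100], [200], ["+"])
        counts = count_fragments(frags, genes, "sense")
        assert counts["g1"] == pytest.approx(0.6)
        assert counts["g2"] == pytest.approx(0.4)

    def test_hand_enumerated_mixed_strand_fixture(
        self, overlap_genes, overlap_fragments
    ):
        sense = count_fragments(overlap_fragments, overlap_genes, "sense")
        anti = count_fragments(overlap_fragments, overlap_genes, "antisense")
        # enumerated fragment-by-fragment by hand:
        assert sense["gA"] == pytest.approx(1 + 60 / 130)
        assert sense["gB"] == pytest.approx(70 / 130 + 1.0)
        assert sense["gC"] == pytest.approx(1.0)
        assert anti["gA"] == 0.0
        assert anti["gB"] == pytest.approx(1.0)
        assert anti["gC"] == pytest.approx(1.0)
        assert sense.attrs["library_size"] == 4

    def test_order_independence(self, overlap_genes, overlap_fragments, rng):
        base = count_fragments(overlap_fragments, overlap_genes, "sense")
        perm = overlap_fragments.sample(frac=1.0, random_state=3).reset_index(
            drop=True
        )
        shuffled = count_fragments(perm, overlap_genes, "sense")
        pd.testing.assert_series_equal(base, shuffled, check_names=False)

    def test_strand_swap_exchanges_sense_and_antisense(
        self, overlap_genes, overlap_fragments
    ):
        flipped = overlap_fragments.assign(
            strand=np.where(overlap_fragments["strand"] == "+", "-", "+")
        )
        s0 = count_fragments(overlap_fragments, overlap_genes, "sense")
        a0 = count_fragments(overlap_fragments, overlap_genes, "antisense")
        s1 = count_fragments(flipped, overlap_genes, "sense")
        a1 = count_fragments(flipped, overlap_genes, "antisense")
        pd.testing.assert_series_equal(s0, a1, check_names=False)
        pd.testing.assert_series_equal(a0, s1, check_names=False)

    def test_mass_conservation_on_random_data(self, rng):
        genes = [
            GeneCopy(f"g{i}", f"f{i}", "c", 200 * i, 200 * i + 150, "+" if i % 2 else "-")
            for i in range(10)
        ]
        starts = rng.integers(0, 1900, size=500)
        frags = fragments_frame(
            ["c"] * 500,
            starts,
            starts + 100,
            np.where(rng.random(500) < 0.5, "+", "-"),
        )
        sense = count_fragments(frags, genes, "sense")
        anti = count_fragments(frags, genes, "antisense")
        gdf = pd.DataFrame(
            {
                "start": [g.start for g in genes],
                "end": [g.end for g in genes],
                "strand": [g.strand for g in genes],
            }
        )
        n_sense = n_anti = 0
        for _, f in frags.iterrows():
            ol = (gdf["start"] < f["end"]) & (gdf["end"] > f["start"])
            if (ol & (gdf["strand"] == f["strand"])).any():
                n_sense += 1
            if (ol & (gdf["strand"] != f["strand"])).any():
                n_anti += 1
        assert float(sense.sum()) == pytest.approx(n_sense, abs=1e-9)
        assert float(anti.sum()) == pytest.approx(n_anti, abs=1e-9)

    def test_unknown_contig_raises_naming_fragment(self, overlap_genes):
        frags = fragments_frame(["nowhere"], [0], [50], ["+"])
        with pytest.raises(InputError, match="nowhere"):
            count_fragments(frags, overlap_genes, "sense")


class TestAntisenseFraction:
    def test_ninety_ten(self):
        s = pd.Series({"g1": 90.0})
        a = pd.Series({"g1": 10.0})
        assert antisense_fraction(s, a) == pytest.approx(10.0)

    def test_zero_antisense_is_zero_percent(self):
        assert antisense_fraction(pd.Series({"g": 5.0}), pd.Series({"g": 0.0})) == 0.0

    def test_no_counts_at_all_is_undefined(self):
        with pytest.raises(UndefinedValueError):
            antisense_fraction(pd.Series({"g": 0.0}), pd.Series({"g": 0.0}))

    def test_mismatched_universe_rejected(self):
        with pytest.raises(InputError):
            antisense_fraction(pd.Series({"g": 1.0}), pd.Series({"h": 1.0}))


class TestTpm:
    def test_length_normalization(self):
        genes = [
            GeneCopy("g1", "f1", "c", 0, 1000, "+"),
            GeneCopy("g2", "f2", "c", 1000, 3000, "+"),
        ]
        counts = pd.Series({"g1": 10.0, "g2": 10.0})
        out = tpm(counts, genes)
        assert out.loc["g1", "tpm"] == pytest.approx(666666.6667, rel=1e-9)
        assert out.loc["g2", "tpm"] == pytest.approx(333333.3333, rel=1e-9)

    def test_single_gene_gets_the_million(self):
        genes = [GeneCopy("g1", "f1", "c", 0, 500, "+")]
        out = tpm(pd.Series({"g1": 3.0}), genes)
        assert out.loc["g1", "tpm"] == pytest.approx(1e6)

    def test_scale_invariance_and_sum(self, rng):
        genes = [
            GeneCopy(f"g{i}", f"f{i}", "c", 500 * i, 500 * i + 300 + 10 * i, "+")
            for i in range(8)
        ]
        counts = pd.Series(rng.random(8) * 50, index=[f"g{i}" for i in range(8)])
        a = tpm(counts, genes)["tpm"]
        b = tpm(counts * 2, genes)["tpm"]
        pd.testing.assert_series_equal(a, b)
        assert a.sum() == pytest.approx(1e6, rel=1e-9)

    def test_rrna_excluded_from_universe(self):
        genes = [
            GeneCopy("g1", "f1", "c", 0, 1000, "+"),
            GeneCopy("r1", "rRNA_1", "c", 1000, 2500, "+", biotype="rRNA"),
        ]
        out = tpm(pd.Series({"g1": 1.0, "r1": 999.0}), genes)
        assert list(out.index) == ["g1"]
        assert out["tpm"].sum() == pytest.approx(1e6)

    def test_all_zero_counts_error(self):
        genes = [GeneCopy("g1", "f1", "c", 0, 500, "+")]
        with pytest.raises(UndefinedValueError):
            tpm(pd.Series({"g1": 0.0}), genes)


class TestFilterRrna:
    def test_no_rrna_passthrough(self, overlap_genes, overlap_fragments):
        out = filter_rrna(overlap_fragments, overlap_genes)
        pd.testing.assert_frame_equal(out, overlap_fragments)

    def test_one_bp_overlap_removed_either_strand(self):
        genes = [GeneCopy("r1", "rRNA_1", "c", 100, 200, "+", biotype="rRNA")]
        frags = fragments_frame(
            ["c"] * 3, [199, 50, 200], [260, 100, 280], ["-", "+", "+"]
        )
        out = filter_rrna(frags, genes)
        # [199,260) overlaps 1 bp (opposite strand, still removed);
        # [50,100) and [200,280) touch but do not overlap
        assert list(out["start"]) == [50, 200]

    def test_hand_counted_survivors(self):
        genes = [GeneCopy("r1", "rRNA_1", "c", 1000, 2000, "+", biotype="rRNA")]
        starts = [0, 100, 200, 300, 400, 500, 600, 950, 1500, 1990]
        frags = fragments_frame(["c"] * 10, starts, [s + 100 for s in starts], ["+"] * 10)
        out = filter_rrna(frags, genes)
        assert len(out) == 7  # 950, 1500 and 1990 overlap the rRNA


class TestPerBaseCoverage:
    def test_single_fragment_track(self):
        frags = fragments_frame(["c"], [10], [20], ["+"])
        tracks = per_base_coverage(frags, {"c": 30})
        plus = tracks[("c", "+")]
        assert plus[10:20].tolist() == [1] * 10
        assert plus.sum() == 10
        assert tracks[("c", "-")].sum() == 0

    def test_total_depth_conserved(self, rng):
        starts = rng.integers(0, 900, size=200)
        frags = fragments_frame(
            ["c"] * 200, starts, starts + 50,
            np.where(rng.random(200) < 0.5, "+", "-"),
        )
        tracks = per_base_coverage(frags, {"c": 1000})
        total = sum(t.sum() for t in tracks.values())
        assert total == (frags["end"] - frags["start"]).sum()

    def test_overlap_of_five_bases(self):
        frags = fragments_frame(["c", "c"], [0, 15], [20, 40], ["+", "+"])
        track = per_base_coverage(frags, {"c": 50})[("c", "+")]
        assert (track == 2).sum() == 5
        assert track.max() == 2

    def test_fragment_past_contig_end_rejected(self):
        frags = fragments_frame(["c"], [90], [120], ["+"])
        with pytest.raises(InputError):
            per_base_coverage(frags, {"c": 100})


class TestDownsample:
    @pytest.fixture
    def big(self, rng):
        starts = rng.integers(0, 9_900, size=100_000)
        return fragments_frame(
            ["c"] * 100_000, starts, starts + 100,
            np.where(rng.random(100_000) < 0.5, "+", "-"),
        )

    def test_target_above_current_is_identity(self, big):
        out = downsample(big, 1e9, {"c": 10_000}, seed=0)
        pd.testing.assert_frame_equal(out, big)

    def test_achieved_coverage_near_target(self, big):
        target = 450.0
        out = downsample(big, target, {"c": 10_000}, seed=1)
        achieved = (out["end"] - out["start"]).sum() / 10_000
        assert abs(achieved - target) / target < 0.05

    def test_seed_determinism(self, big):
        a = downsample(big, 100.0, {"c": 10_000}, seed=7)
        b = downsample(big, 100.0, {"c": 10_000}, seed=7)
        pd.testing.assert_frame_equal(a, b)
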