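"""Read splitting, demultiplexing, artifact filtering, dedup, counting, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_counts, processed_from_truth
from ms4c import readproc as rp
from ms4c import simulate as sim


def bait_spec_of(bait: sim.SimulatedBait, **kw) -> rp.BaitSpec:
    return rp.BaitSpec(name=bait.name, bait_side_sequence=bait.bait_side_sequence,
                       bait_fragment=bait.bait_fragment, **kw)


class TestSplitAndDemultiplex:
    def test_split_keeps_motif_on_both_parts(self):
        baits = [rp.BaitSpec("A", "ACGTAAGCTT", ("chr1", 0, 100))]
        split, tally = rp.split_and_demultiplex([("ACGTAAGCTTTTTT", "GGGG")], baits)
        assert len(split) == 1
        assert split[0].bait_name == "A"
        assert split[0].target_part == "AAGCTTTTTT"
        assert tally.kept == 0 and tally.input_pairs == 1

    def test_motif_free_read_dropped_and_tallied(self):
        baits = [rp.BaitSpec("A", "ACGTAAGCTT", ("chr1", 0, 100))]
        split, tally = rp.split_and_demultiplex([("ACGTACGTACGT", "GGGG")], baits)
        assert split == [] and tally.no_motif == 1

    def test_split_at_first_motif_occurrence(self):
        baits = [rp.BaitSpec("A", "CCAAGCTT", ("chr1", 0, 100))]
        split, _ = rp.split_and_demultiplex([("CCAAGCTTGGAAGCTTCC", "G")], baits)
        assert split[0].target_part == "AAGCTTGGAAGCTTCC"

    def test_snp_discriminates_paralogous_baits(self):
        # identical primer sequences except an N at the SNP offset
        common = "ACGTNCGAAGCTT"
        baits = [
            rp.BaitSpec("locus", common, ("chr1", 0, 100),
                        discriminating_variants=[(4, "A")]),
            rp.BaitSpec("pseudogene", common, ("chr2", 0, 100),
                        discriminating_variants=[(4, "G")]),
        ]
        split, tally = rp.split_and_demultiplex(
            [("ACGTGCGAAGCTTTTTT", "C"), ("ACGTACGAAGCTTTTTT", "C")], baits)
        assert [s.bait_name for s in split] == ["pseudogene", "locus"]
        assert tally.ambiguous == 0

    def test_unbreakable_tie_dropped_as_ambiguous(self):
        common = "ACGTNCGAAGCTT"
        baits = [
            rp.BaitSpec("a", common, ("chr1", 0, 100)),
            rp.BaitSpec("b", common, ("chr2", 0, 100)),
        ]
        split, tally = rp.split_and_demultiplex([("ACGTGCGAAGCTTTT", "C")], baits)
        assert split == [] and tally.ambiguous == 1

    def test_unmatched_read_tallied(self):
        baits = [rp.BaitSpec("A", "CCCCAAGCTT", ("chr1", 0, 100))]
        _, tally = rp.split_and_demultiplex([("GGGGAAGCTTAA", "C")], baits)
        assert tally.unmatched == 1


class TestMapAndFilter:
    @pytest.fixture()
    def mapped(self, seq_genome, seq_bait):
        model = sim.ContactModel(read_count=800, duplication_rate=0.0,
                                 background_trans_fraction=0.2, seed=31)
        pairs, truth = sim.simulate_pairs(seq_genome, seq_bait, model)
        bs = bait_spec_of(seq_bait)
        split, tally = rp.split_and_demultiplex([(p.r1, p.r2) for p in pairs], [bs])
        processed, tally = rp.map_and_filter(split, seq_genome, [bs], tally)
        return processed, truth, tally

    def test_all_synthetic_reads_map_to_truth_sites(self, mapped):
        processed, truth, tally = mapped
        assert tally.unmapped == 0
        assert len(processed) == len(truth)
        for pp, row in zip(processed, truth.itertuples(index=False)):
            assert (pp.chrom, pp.site_index) == (row.chrom, row.site_index)
            assert pp.breakpoint == row.breakpoint

    def test_artifact_flags_follow_fragment_adjacency(self, mapped, seq_bait):
        processed, _, _ = mapped
        for pp in processed:
            if pp.chrom != "chr1":
                assert not pp.self_ligation and not pp.undigested
                continue
            d = pp.site_index - seq_bait.frag_index
            assert pp.self_ligation == (d == 0)
            assert pp.undigested == (abs(d) == 1)

    def test_trans_pairs_kept(self, mapped):
        processed, _, _ = mapped
        trans = [p for p in processed if p.chrom == "chr2"]
        assert trans and all(p.kept for p in trans)


class TestLoadPremapped:
    def test_position_assigned_to_containing_fragment(self, grid_rmap):
        import pandas as pd

        baits = [rp.BaitSpec("B", "AAGCTT", ("chr1", 100, 3100))]
        table = pd.DataFrame({
            "bait": ["B"] * 3, "chrom": ["chr1"] * 3,
            "pos": [3_500, 50, 300_500], "strand": ["+"] * 3,
            "breakpoint": [4000, 600, 301_000],
        })
        pairs, tally = rp.load_premapped_pairs(table, grid_rmap, baits)
        assert [p.site_pos for p in pairs] == [3100, 100, 300_100]
        assert pairs[0].undigested  # fragment adjacent to the bait
        assert pairs[1].self_ligation
        assert pairs[2].kept


class TestDeduplicate:
    def _pair(self, pos=5000, bp=5400, strand="+"):
        return rp.ProcessedPair("B", "chr1", strand, pos, 1, bp)

    def test_identical_tuples_collapse_to_one(self):
        pairs = [self._pair(), self._pair(), self._pair()]
        out = rp.deduplicate(pairs)
        assert [p.duplicate for p in out] == [False, True, True]

    def test_distinct_breakpoints_all_kept(self):
        out = rp.deduplicate([self._pair(bp=5400), self._pair(bp=5401),
                              self._pair(bp=5400, strand="-")])
        assert all(not p.duplicate for p in out)

    def test_idempotence(self, seq_genome, seq_bait):
        model = sim.ContactModel(read_count=400, duplication_rate=0.4, seed=41)
        _, truth = sim.simulate_pairs(seq_genome, seq_bait, model)
        pairs = processed_from_truth(truth)
        once = rp.deduplicate(pairs)
        flags = [p.duplicate for p in once]
        twice = rp.deduplicate(once)
        assert [p.duplicate for p in twice] == flags

    def test_survivors_match_truth_sidecar_unique_count(self, seq_genome, seq_bait):
        model = sim.ContactModel(read_count=2000, duplication_rate=0.3, seed=42)
        _, truth = sim.simulate_pairs(seq_genome, seq_bait, model)
        out = rp.deduplicate(processed_from_truth(truth))
        survivors = sum(1 for p in out if not p.duplicate)
        truth_unique = truth.groupby(["chrom", "site_pos", "breakpoint"]).ngroups
        assert survivors == truth_unique


class TestCountPerSite:
    def test_single_pair_increments_single_site(self, grid_rmap):
        bait = rp.BaitSpec("B", "AAGCTT", ("chr1", 100, 3100))
        pair = rp.ProcessedPair("B", "chr1", "+", 300_100, 100, 300_500)
        sc = rp.count_per_site([pair], grid_rmap, bait)
        assert sc.counts["chr1"][100] == 1 and sc.counts["chr1"].sum() == 1
        assert sc.raw["chr1"][100] == 1
        assert sc.cis == 1 and sc.trans == 0

    def test_sites_within_a_kilobase_share_the_read(self):
        rmap = {"chr1": np.array([1000, 2600, 10_000], dtype=np.int64)}
        bait = rp.BaitSpec("B", "AAGCTT", ("chr1", 1000, 2600))
        pair = rp.ProcessedPair("B", "chr1", "+", 2600, 1, 3000)
        sc = rp.count_per_site([pair], rmap, bait)
        # site at 1000 is 1600 bp away (not counted); both within 1000 of 2600? no:
        # |2600-1000| = 1600 > 1000, |2600-2600| = 0 -> only the target site
        assert list(sc.counts["chr1"]) == [0, 1, 0]
        pair2 = rp.ProcessedPair("B", "chr1", "+", 10_000, 2, 10_300)
        rmap2 = {"chr1": np.array([9_200, 10_000], dtype=np.int64)}
        bait2 = rp.BaitSpec("B", "AAGCTT", ("chr1", 9_200, 10_000))
        sc2 = rp.count_per_site([pair2], rmap2, bait2)
        assert list(sc2.counts["chr1"]) == [1, 1]  # 800 bp apart: both incremented

    def test_window_boundary_inclusive(self):
        rmap = {"chr1": np.array([5000, 6000], dtype=np.int64)}
        bait = rp.BaitSpec("B", "AAGCTT", ("chr1", 5000, 6000))
        pair = rp.ProcessedPair("B", "chr1", "+", 6000, 1, 6400)
        sc = rp.count_per_site([pair], rmap, bait)
        assert list(sc.counts["chr1"]) == [1, 1]  # exactly 1000 bp counts

    def test_off_map_target_is_hard_error(self, grid_rmap):
        bait = rp.BaitSpec("B", "AAGCTT", ("chr1", 100, 3100))
        pair = rp.ProcessedPair("B", "chr1", "+", 4242, 1, 5000)
        with pytest.raises(ValueError, match="not a restriction-map member"):
            rp.count_per_site([pair], grid_rmap, bait)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_counting_matches_brute_force_window_scan(self, seed):
        rng = np.random.default_rng(seed)
        sites = np.unique(rng.integers(0, 100_000, size=60)).astype(np.int64)
        rmap = {"chr1": sites}
        bait = rp.BaitSpec("B", "AAGCTT", ("chr1", int(sites[0]), int(sites[1])))
        idx = rng.integers(0, len(sites), size=200)
        pairs = [rp.ProcessedPair("B", "chr1", "+", int(sites[i]), int(i),
                                  int(sites[i]) + int(rng.integers(150, 600)))
                 for i in idx]
        sc = rp.count_per_site(pairs, rmap, bait)
        brute = np.zeros(len(sites), dtype=int)
        for p in pairs:
            for j, s in enumerate(sites):
                if abs(s - p.site_pos) <= 1000:
                    brute[j] += 1
        assert np.array_equal(sc.counts["chr1"], brute)


class TestQCReport:
    def test_cis_trans_ratio_arithmetic(self, grid_rmap):
        raw = {"chr1": np.zeros(len(grid_rmap["chr1"]), dtype=np.int64)}
        sc = make_counts(grid_rmap, raw)
        sc.total, sc.cis, sc.trans = 150, 100, 50
        rep = rp.qc_report(sc, [])
        assert rep.cis_trans_ratio == 2.0

    def test_extrapolation_never_shrinks(self):
        mult = np.ones(5000, dtype=np.int64)
        est, saturated = rp.extrapolate_distinct(mult)
        assert est >= 5000 and not saturated

    def test_saturated_library_flagged(self):
        mult = np.full(100, 7, dtype=np.int64)  # every interaction seen 7 times
        est, saturated = rp.extrapolate_distinct(mult)
        assert saturated and est == 100.0

    def test_extrapolation_within_20pct_under_resampling_model(self):
        # uniform interaction rates: the zero-truncated mixture model holds
        rng = np.random.default_rng(77)
        universe = 135_300
        def distinct(n, seed):
            r = np.random.default_rng(seed)
            return np.unique(r.integers(0, universe, size=n), return_counts=True)
        _, mult = distinct(20_000, 1)
        est, _ = rp.extrapolate_distinct(mult, fold=10.0)
        truth = len(distinct(200_000, 2)[0])
        assert abs(est - truth) / truth < 0.20

    def test_heavy_tailed_library_estimate_is_conservative(self, std_genome, std_bait):
        model = sim.ContactModel(decay_exponent=1.0, read_count=10_000, seed=5)
        rng = np.random.default_rng(5)
        w = sim.cis_target_weights(std_genome, std_bait, model)
        p = w / w.sum()
        draws = rng.choice(len(p), size=10_000, p=p)
        offs = rng.integers(150, 601, size=10_000)
        _, mult = np.unique(draws * 1000 + offs, return_counts=True)
        est, _ = rp.extrapolate_distinct(mult, fold=10.0)
        draws10 = rng.choice(len(p), size=100_000, p=p)
        offs10 = rng.integers(150, 601, size=100_000)
        truth = len(np.unique(draws10 * 1000 + offs10))
        assert len(mult) <= est <= truth * 1.1  # lower-bound behaviour


class TestPipelineConservation:
    def test_read_accounting_identity(self, seq_genome, seq_bait):
        model = sim.ContactModel(read_count=1500, duplication_rate=0.3,
                                 background_trans_fraction=0.15, seed=51)
        pairs, _ = sim.simulate_pairs(seq_genome, seq_bait, model)
        bs = bait_spec_of(seq_bait)
        counts, reports, tally = rp.process_library(
            [(p.r1, p.r2) for p in pairs], [bs], seq_genome)
        assert tally.check()
        assert tally.input_pairs == len(pairs)
        assert counts["B1"].total == tally.kept
        assert counts["B1"].cis + counts["B1"].trans == counts["B1"].total
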