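import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radpop import filtering, simulate, sweep
from radpop.datamodel import GeneRecord, RadpopError

from conftest import make_dataset


class TestMakeWindows:
    def test_250kb_contig_yields_16_windows(self):
        windows = sweep.make_windows({"c": 250_000}, size=100_000, step=10_000)
        assert len(windows) == 16
        assert windows[0].start == 0 and windows[-1].start == 150_000
        assert all(w.end - w.start == 100_000 for w in windows)

    def test_contig_shorter_than_window(self):
        assert sweep.make_windows({"c": 99_999}) == []

    def test_size_equals_step_tiles_without_overlap(self):
        windows = sweep.make_windows({"c": 300_000}, size=100_000, step=100_000)
        assert [(w.start, w.end) for w in windows] == [
            (0, 100_000), (100_000, 200_000), (200_000, 300_000),
        ]

    def test_step_larger_than_size_rejected(self):
        with pytest.raises(ValueError):
            sweep.make_windows({"c": 10_000}, size=10, step=20)


class TestWindowStats:
    def test_pi_ratio_definition(self):
        # target pi half of control pi inside the window -> ratio 2
        dosages = np.zeros((8, 12), dtype=np.int8)
        dosages[4:, :] = [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]  # control het everywhere
        dosages[:4, ::2] = 1  # target het at every second site
        gd = make_dataset(
            dosages,
            positions=[50 * (j + 1) for j in range(12)],
            pops=["T"] * 4 + ["C"] * 4,
            contig_length=1_000,
        )
        stats = sweep.window_stats(
            gd, "T", "C", [sweep.Window("chr1", 0, 1_000)], min_snps=1
        )
        assert stats["pi_ratio"].iloc[0] == pytest.approx(2.0)

    def test_sparse_window_unusable(self):
        dosages = np.tile([0, 1, 2, 1], (3, 1)).T
        gd = make_dataset(
            dosages, positions=[100, 200, 300],
            pops=["T", "T", "C", "C"], contig_length=1_000,
        )
        stats = sweep.window_stats(
            gd, "T", "C", [sweep.Window("chr1", 0, 1_000)], min_snps=10
        )
        assert not stats["usable"].iloc[0]
        assert np.isnan(stats["pi_ratio"].iloc[0])

    def test_sweep_window_extreme_in_both_statistics(self, standard_run):
        gd, _, _, truth = standard_run
        windows = sweep.make_windows(gd.effective_contig_lengths())
        stats = sweep.window_stats(gd, "WZ", "SB", windows)
        sw = truth.sweeps[0]
        usable = stats[stats["usable"]]
        in_sweep = usable[
            (usable["chrom"] == sw.contig)
            & (usable["start"] >= sw.start)
            & (usable["end"] <= sw.end)
        ]
        assert len(in_sweep) > 0
        assert in_sweep["fst"].max() > usable["fst"].median()
        assert in_sweep["pi_ratio"].max() > usable["pi_ratio"].median()


def synthetic_stats(n=100, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "chrom": ["c"] * n,
            "start": np.arange(n) * 10_000,
            "end": np.arange(n) * 10_000 + 100_000,
            "fst": rng.random(n),
            "pi_ratio": rng.random(n) + 0.5,
            "usable": True,
        }
    )


class TestSelection:
    def test_single_window_in_both_top_sets(self):
        stats = synthetic_stats(100)
        stats.loc[7, ["fst", "pi_ratio"]] = [10.0, 10.0]
        # make the rest of each top-5 set disjoint
        stats.loc[10:13, "fst"] = [5, 5, 5, 5]
        stats.loc[20:23, "pi_ratio"] = [5, 5, 5, 5]
        sel = sweep.select_candidates(stats, top_frac=0.05)
        assert sel["start"].tolist() == [70_000]

    def test_top_frac_one_selects_all_usable(self):
        stats = synthetic_stats(50)
        stats.loc[3, "usable"] = False
        sel = sweep.select_candidates(stats, top_frac=1.0)
        assert len(sel) == 49

    def test_selection_monotone_in_top_frac(self):
        stats = synthetic_stats(200, seed=3)
        prev: set = set()
        for frac in (0.02, 0.05, 0.1, 0.3, 1.0):
            sel = set(sweep.select_candidates(stats, top_frac=frac)["start"])
            assert prev <= sel
            prev = sel

    def test_union_mode_superset_of_intersection(self):
        stats = synthetic_stats(100, seed=5)
        inter = set(sweep.select_candidates(stats, mode="intersection")["start"])
        union = set(sweep.select_candidates(stats, mode="union")["start"])
        assert inter <= union

    def test_too_few_usable_windows_rejected(self):
        with pytest.raises(RadpopError):
            sweep.select_candidates(synthetic_stats(10))


class TestMergeRegions:
    def _frame(self, intervals, chrom="c"):
        return pd.DataFrame(
            {
                "chrom": [chrom] * len(intervals),
                "start": [s for s, _ in intervals],
                "end": [e for _, e in intervals],
                "fst": 0.5,
                "pi_ratio": 2.0,
            }
        )

    def test_overlapping_windows_merge(self):
        regions = sweep.merge_regions(self._frame([(0, 100_000), (10_000, 110_000)]))
        assert [(r.start, r.end) for r in regions] == [(0, 110_000)]

    def test_different_chromosomes_never_merge(self):
        df = pd.concat(
            [self._frame([(0, 100_000)], "c1"), self._frame([(0, 100_000)], "c2")]
        )
        assert len(sweep.merge_regions(df)) == 2

    def test_chained_overlaps_transitive(self):
        regions = sweep.merge_regions(
            self._frame([(0, 100_000), (50_000, 150_000), (140_000, 240_000)])
        )
        assert [(r.start, r.end) for r in regions] == [(0, 240_000)]

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(0, 50), min_size=1, max_size=15),
        st.integers(0, 3),
    )
    def test_disjoint_and_covering(self, starts, max_gap_units):
        iv = [(s * 10, s * 10 + 25) for s in sorted(set(starts))]
        gap = max_gap_units * 10
        regions = sweep.merge_regions(self._frame(iv), max_gap=gap)
        # pairwise disjoint beyond the gap, sorted
        for r1, r2 in zip(regions, regions[1:]):
            assert r2.start > r1.end + gap
        # cover exactly the union of inputs
        covered = set()
        for r in regions:
            covered.update(range(r.start, r.end))
        expected = set()
        for s, e in iv:
            expected.update(range(s, e))
        assert expected <= covered


class TestAnnotation:
    REGION = sweep.CandidateRegion(
        chrom="c", start=100_000, end=200_000, windows=[], max_fst=1, max_pi_ratio=1
    )

    def _annotate(self, gene):
        regions, genes = sweep.annotate_regions(
            [sweep.CandidateRegion(**{**self.REGION.__dict__, "gene_ids": []})],
            [gene],
        )
        return regions[0].gene_ids

    def test_gene_inside_region_assigned(self):
        g = GeneRecord("g1", "c", 120_001, 130_000)
        assert self._annotate(g) == ["g1"]

    def test_gene_ending_at_region_start_not_assigned(self):
        # 1-based gene end 100_000 occupies [99_999, 100_000) -> no overlap
        g = GeneRecord("g1", "c", 90_001, 100_000)
        assert self._annotate(g) == []

    def test_one_bp_overlap_assigned(self):
        g = GeneRecord("g1", "c", 90_001, 100_001)
        assert self._annotate(g) == ["g1"]

    def test_sweep_genes_recovered_end_to_end(self, standard_run):
        gd, _, genes, truth = standard_run
        windows = sweep.make_windows(gd.effective_contig_lengths())
        stats = sweep.window_stats(gd, "WZ", "SB", windows)
        selected = sweep.select_candidates(stats)
        regions = sweep.merge_regions(selected)
        _, gene_list = sweep.annotate_regions(regions, genes)
        sweep_genes = {g.gene_id for g in genes if g.gene_id.startswith("sweep")}
        assert sweep_genes & set(gene_list)


class TestEnrichment:
    def test_exact_combinatorial_p(self):
        bg = [f"g{i}" for i in range(20)]
        term = {"t": bg[:5]}
        res = sweep.hypergeom_enrichment(bg[:5], bg, term)
        assert res["p"].iloc[0] == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        res = sweep.hypergeom_enrichment(bg[:3], bg, {"t": bg[5:]})
        assert res["p"].iloc[0] == 1.0

    def test_single_term_q_equals_p(self):
        bg = [f"g{i}" for i in range(10)]
        res = sweep.hypergeom_enrichment(bg[:3], bg, {"t": bg[2:6]})
        assert res["q"].iloc[0] == res["p"].iloc[0]

    def test_selected_outside_background_rejected(self):
        with pytest.raises(RadpopError, match="not in background"):
            sweep.hypergeom_enrichment(["x"], ["a", "b"], {"t": ["a"]})

    def test_bh_q_at_least_p_and_order_preserved(self):
        rng = np.random.default_rng(1)
        bg = [f"g{i}" for i in range(50)]
        terms = {
            f"t{j}": list(rng.choice(bg, size=rng.integers(3, 20), replace=False))
            for j in range(12)
        }
        res = sweep.hypergeom_enrichment(bg[:10], bg, terms)
        assert (res["q"] >= res["p"] - 1e-15).all()
        assert res["p"].is_monotonic_increasing
        assert res["q"].is_monotonic_increasing
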