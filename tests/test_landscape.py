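import numpy as np
import pandas as pd
import pytest

from nonself.landscape import (
    _merge_runs,
    call_expression_hotspots,
    call_versatility_troughs,
    flag_telomeric,
    region_coincidence,
    window_profiles,
)
from nonself.model import GeneRecord, GenomicRegion, ResponseSet, ValidationError
from nonself.versatility import VersatilityAssignment
from oracles import naive_window_means


def _chromosome(indices, chrom="1", up_genes=()):
    """Build (genes, assignment, up_sets) for one chromosome of given
    per-gene versatility indices."""
    genes = [
        GeneRecord(f"{chrom}g{i:04d}", chrom, i + 1, 100)
        for i in range(len(indices))
    ]
    category = {g.gene_id: "bin1" for g in genes}
    index = {g.gene_id: int(v) for g, v in zip(genes, indices)}
    assignment = VersatilityAssignment(category=category, index=index,
                                       n_bins=10)
    up = ResponseSet("c_up", "up", 2, 0.01,
                     frozenset(genes[i].gene_id for i in up_genes))
    return genes, assignment, {"c": up}


class TestWindowProfiles:
    def test_single_window_when_chromosome_equals_window(self):
        genes, a, ups = _chromosome([5] * 100)
        df = window_profiles(genes, a, ups, window=100)
        assert len(df) == 1
        assert df.start.iloc[0] == 1 and df.end.iloc[0] == 100

    def test_constant_index_gives_constant_mean(self):
        genes, a, ups = _chromosome([5] * 120)
        df = window_profiles(genes, a, ups, window=100)
        assert (df.mean_index == 5.0).all()

    def test_means_match_naive_recomputation(self):
        rng = np.random.default_rng(0)
        idx = rng.integers(0, 12, 300)
        genes, a, ups = _chromosome(idx, up_genes=range(0, 300, 7))
        df = window_profiles(genes, a, ups, window=50)
        expect = naive_window_means([float(v) for v in idx], 50)
        assert np.allclose(df.mean_index, expect)
        member = [1.0 if i % 7 == 0 else 0.0 for i in range(300)]
        assert np.allclose(df.frac_c, naive_window_means(member, 50))

    def test_rolling_update_identity(self):
        rng = np.random.default_rng(1)
        idx = rng.integers(0, 12, 400)
        genes, a, ups = _chromosome(idx)
        m = window_profiles(genes, a, ups, window=100).mean_index.to_numpy()
        for i in range(len(m) - 1):
            assert abs(m[i + 1] - (m[i] + (idx[i + 100] - idx[i]) / 100)) < 1e-9

    def test_short_chromosome_skipped_with_warning(self, caplog):
        genes, a, ups = _chromosome([5] * 10)
        df = window_profiles(genes, a, ups, window=100)
        assert df.empty

    def test_window_below_two_rejected(self):
        genes, a, ups = _chromosome([5] * 10)
        with pytest.raises(ValidationError):
            window_profiles(genes, a, ups, window=1)

    def test_step_thins_windows(self):
        genes, a, ups = _chromosome([5] * 130)
        df = window_profiles(genes, a, ups, window=100, step=10)
        assert list(df.start) == [1, 11, 21, 31]


class TestTroughCalling:
    def test_uniform_chromosome_yields_no_regions(self):
        genes, a, ups = _chromosome([5] * 200)
        profiles = window_profiles(genes, a, ups, window=50)
        assert call_versatility_troughs(profiles=profiles) == []

    def test_implanted_low_block_recovered_within_window(self):
        idx = [8] * 500
        idx[220:280] = [1] * 60
        genes, a, ups = _chromosome(idx)
        profiles = window_profiles(genes, a, ups, window=100)
        regions = call_versatility_troughs(profiles=profiles)
        assert len(regions) == 1
        r = regions[0]
        assert abs(r.start - 221) <= 100 and abs(r.end - 280) <= 100
        assert r.start <= 221 <= 280 <= r.end or (r.start <= 280 and r.end >= 221)

    def test_two_separated_blocks_give_two_regions(self):
        idx = [8] * 900
        idx[100:160] = [1] * 60
        idx[600:660] = [1] * 60
        genes, a, ups = _chromosome(idx)
        profiles = window_profiles(genes, a, ups, window=100)
        regions = call_versatility_troughs(profiles=profiles)
        assert len(regions) == 2
        assert [r.label for r in regions] == ["a", "b"]

    def test_gene_mode_matches_construction(self):
        idx = [8] * 300
        idx[100:160] = [0] * 60
        genes, a, _ = _chromosome(idx)
        regions = call_versatility_troughs(genes=genes, assignment=a,
                                           mode="gene")
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (101, 160)

    def test_region_calls_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        idx = [8] * 400
        idx[50:120] = [1] * 70
        genes, a, ups = _chromosome(idx)
        profiles = window_profiles(genes, a, ups, window=60)
        shuffled = profiles.sample(frac=1.0, random_state=4)
        assert call_versatility_troughs(profiles=profiles) == \
            call_versatility_troughs(profiles=shuffled)

    def test_merge_runs_idempotent(self):
        spans = [(1, 5), (4, 9), (20, 30), (31, 35)]
        merged = _merge_runs(spans)
        assert merged == [(1, 9), (20, 35)]
        assert _merge_runs(merged) == merged

    def test_shuffled_gene_order_destroys_clustering(self):
        """The trough statistic detects spatial clustering, not composition:
        permuting gene positions removes the implanted signal."""
        rng = np.random.default_rng(9)
        idx = np.where(rng.uniform(size=2000) < 0.03, 1, 8)
        idx[950:1010] = 1
        implant = GenomicRegion("1", 951, 1010, "versatility_trough")

        def recovered(indices) -> bool:
            genes, a, _ = _chromosome(indices)
            regions = call_versatility_troughs(genes=genes, assignment=a,
                                               mode="gene")
            return any(r.overlap_genes(implant) >= 45 for r in regions)

        assert recovered(idx)
        hits = sum(
            recovered(np.random.default_rng(seed).permutation(idx))
            for seed in range(5)
        )
        assert hits == 0


class TestHotspots:
    def test_no_regulated_genes_yields_no_hotspots(self):
        genes, a, ups = _chromosome([5] * 300)
        profiles = window_profiles(genes, a, ups, window=100)
        assert call_expression_hotspots(profiles, "c") == []

    def test_implanted_dense_block_recovered(self):
        rng = np.random.default_rng(2)
        background = set(np.flatnonzero(rng.uniform(size=500) < 0.10))
        block = set(i for i in range(200, 250) if rng.uniform() < 0.8)
        genes, a, ups = _chromosome([5] * 500,
                                    up_genes=background | block)
        profiles = window_profiles(genes, a, ups, window=100)
        regions = call_expression_hotspots(profiles, "c")
        assert len(regions) == 1
        assert regions[0].overlap_genes(
            GenomicRegion("1", 201, 250, "expression_hotspot")) >= 40

    def test_missing_condition_column_rejected(self):
        genes, a, ups = _chromosome([5] * 300)
        profiles = window_profiles(genes, a, ups, window=100)
        with pytest.raises(ValidationError):
            call_expression_hotspots(profiles, "nope")


class TestCoincidence:
    @staticmethod
    def _region(chrom, start, end, kind="versatility_trough", label=None):
        return GenomicRegion(chrom, start, end, kind, label=label)

    def test_disjoint_region_lists_do_not_coincide(self):
        troughs = [self._region("1", 1, 50, label="a")]
        hotspots = {"c": [GenomicRegion("1", 100, 150, "expression_hotspot",
                                        "c")]}
        df = region_coincidence(troughs, hotspots)
        assert df.coincides.sum() == 0

    def test_identical_region_lists_all_coincide(self):
        troughs = [self._region("1", 1, 50, label="a"),
                   self._region("2", 5, 80, label="b")]
        hotspots = {"c": [
            GenomicRegion(r.chromosome, r.start, r.end, "expression_hotspot", "c")
            for r in troughs
        ]}
        df = region_coincidence(troughs, hotspots)
        assert df.coincides.all() and len(df) == 2

    def test_min_overlap_threshold_respected(self):
        troughs = [self._region("1", 1, 50, label="a")]
        hotspots = {"c": [GenomicRegion("1", 48, 120, "expression_hotspot", "c")]}
        assert region_coincidence(troughs, hotspots, min_overlap=3
                                  ).coincides.all()
        assert not region_coincidence(troughs, hotspots, min_overlap=4
                                      ).coincides.any()

    def test_synthetic_genome_recovers_13_of_19(self, full_bundle,
                                                full_expression):
        """The generator implants 19 lineage-specific clusters, 13 of them
        with co-located up-regulation hotspots; the landscape stage recovers
        exactly that coincidence count."""
        from nonself.sets import build_response_set, pool_conditions
        from nonself.versatility import assign_versatility

        tables, truth = full_expression
        a = assign_versatility(full_bundle.hits, full_bundle.core_ids)
        ups = {}
        for pool, (t1, t2) in (("VsSf", ("VsSf2h", "VsSf6h")),
                               ("VsSm", ("VsSm2h", "VsSm6h"))):
            ups[pool] = pool_conditions(
                build_response_set(tables[t1], "up", 2.0, 0.01),
                build_response_set(tables[t2], "up", 2.0, 0.01),
            )
        ups["VI"] = build_response_set(tables["VI"], "up", 2.0, 0.01)
        profiles = window_profiles(full_bundle.genes, a, ups, 100, 1)
        troughs = call_versatility_troughs(profiles=profiles)
        hotspots = {c: call_expression_hotspots(profiles, c) for c in ups}
        assert len(troughs) == 19
        df = region_coincidence(troughs, hotspots)
        assert int(df.coincides.sum()) == 13
        telo = flag_telomeric(troughs, full_bundle.genes)
        assert int(telo.telomeric.sum()) == 8
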