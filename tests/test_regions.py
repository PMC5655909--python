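"""Cross-sample clustering, region typing and cohort summaries."""

import itertools

import numpy as np
import pytest

from cnvcons import (
    ConsensusVariant,
    GenomicInterval,
    SampleMeta,
    build_region,
    build_regions,
    cluster_across_samples,
    reciprocal_overlap,
    summarize_regions,
)


def cv(start, end, chrom="chr1", svtype="DEL", sample="s1",
       tools=("pindel", "delly")):
    return ConsensusVariant(
        interval=GenomicInterval(chrom, start, end), svtype=svtype,
        sample_id=sample, tools=frozenset(tools), source_calls=[],
        tool_pairs=frozenset({frozenset(tools)}),
    )


class TestClustering:
    def test_seventy_percent_threshold(self):
        a = cv(100, 500, sample="sample1")
        b = cv(150, 600, sample="sample2")
        # RO = 351/451 ~ 0.778 >= 0.70 -> one cluster
        assert reciprocal_overlap(a.interval, b.interval) == pytest.approx(351 / 451)
        assert len(cluster_across_samples([a, b], 0.70)) == 1
        # same intervals at a stricter 0.80 threshold -> two clusters
        assert len(cluster_across_samples([a, b], 0.80)) == 2

    def test_singleton_kept(self):
        clusters = cluster_across_samples([cv(100, 500)], 0.70)
        assert len(clusters) == 1 and len(clusters[0]) == 1

    def test_threshold_zero_merges_touching_only(self):
        a, b, c = cv(100, 200), cv(200, 300), cv(301, 400)
        clusters = cluster_across_samples([a, b, c], 0.0)
        # a-b share base 200; c touches nothing
        assert sorted(len(cl) for cl in clusters) == [1, 2]

    def test_threshold_one_merges_identical_only(self):
        a = cv(100, 500, sample="s1")
        b = cv(100, 500, sample="s2")
        c = cv(100, 501, sample="s3")
        clusters = cluster_across_samples([a, b, c], 1.0)
        assert sorted(len(cl) for cl in clusters) == [1, 2]

    def test_del_dup_may_share_cluster(self):
        a = cv(100, 500, svtype="DEL")
        b = cv(120, 520, svtype="DUP", sample="s2")
        assert len(cluster_across_samples([a, b], 0.70)) == 1

    def test_brute_force_oracle_equivalence(self):
        """Pairwise matrix + transitive closure equals the sweep clusters."""
        rng = np.random.default_rng(17)
        variants = []
        for k in range(150):
            s = int(rng.integers(1, 200_000))
            l = int(rng.integers(100, 8000))
            variants.append(cv(s, s + l, sample=f"s{k % 20}",
                               svtype="DEL" if rng.random() < 0.9 else "DUP"))
        n = len(variants)
        adj = np.eye(n, dtype=bool)
        for i, j in itertools.combinations(range(n), 2):
            if reciprocal_overlap(variants[i].interval, variants[j].interval) >= 0.70:
                adj[i, j] = adj[j, i] = True
        closure = adj.copy()
        while True:
            nxt = closure @ closure
            if (nxt == closure).all():
                break
            closure = nxt
        expected = set()
        seen = set()
        for i in range(n):
            if i not in seen:
                comp = frozenset(np.flatnonzero(closure[i]).tolist())
                seen |= comp
                expected.add(frozenset(
                    (variants[k].start, variants[k].end, variants[k].sample_id)
                    for k in comp))
        got = {
            frozenset((v.start, v.end, v.sample_id) for v in cl)
            for cl in cluster_across_samples(variants, 0.70)
        }
        assert got == expected


class TestBuildRegion:
    def test_bounds_and_size(self):
        r = build_region([cv(100, 500), cv(150, 600, sample="s2")])
        assert (r.start, r.end, r.size) == (100, 600, 501)
        assert r.region_type == "deletion-only"
        assert r.carriers == frozenset({"s1", "s2"})

    def test_mixed_types_become_cnvr(self):
        r = build_region([cv(100, 500, svtype="DEL"),
                          cv(120, 520, svtype="DUP", sample="s2")])
        assert r.region_type == "CNVR"

    def test_duplication_only(self):
        r = build_region([cv(100, 500, svtype="DUP")])
        assert r.region_type == "duplication-only"
        assert r.interval == GenomicInterval("chr1", 100, 500)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            build_region([])

    def test_region_contains_all_members(self):
        rng = np.random.default_rng(23)
        variants = [cv(int(s), int(s + rng.integers(100, 3000)),
                       sample=f"s{k % 5}")
                    for k, s in enumerate(rng.integers(1, 100_000, size=80))]
        for r in build_regions(variants, 0.70):
            for m in r.members:
                assert r.start <= m.start and m.end <= r.end

    def test_sequential_ids_in_position_order(self):
        variants = [cv(50_000, 51_000), cv(100, 500), cv(2000, 2500, chrom="chr2")]
        regions = build_regions(variants, 0.70)
        assert [r.region_id for r in regions] == \
            ["CNVR_00001", "CNVR_00002", "CNVR_00003"]
        assert [(r.chrom, r.start) for r in regions] == \
            [("chr1", 100), ("chr1", 50_000), ("chr2", 2000)]


class TestSummaries:
    def _meta(self):
        return [SampleMeta("s1", "Holstein", "dairy", 10.0),
                SampleMeta("s2", "Holstein", "dairy", 20.0),
                SampleMeta("s3", "Charolaise", "beef", 30.0)]

    def test_covered_fraction_uses_union(self):
        regions = build_regions(
            [cv(1, 100), cv(201, 300, sample="s2")], 0.70)
        summary = summarize_regions(regions, self._meta(), {"chr1": 1000})
        row = summary.per_chrom.iloc[0]
        assert row.covered_bp == 200
        assert row.covered_frac == pytest.approx(0.2)

    def test_overlapping_regions_not_double_counted(self):
        # two clusters can overlap after the min/max span rule; union bp counts once
        regions = build_regions([cv(1, 100), cv(51, 150, sample="s2")], 0.95)
        assert len(regions) == 2
        summary = summarize_regions(regions, self._meta(), {"chr1": 1000})
        assert summary.per_chrom.iloc[0].covered_bp == 150

    def test_perfect_proportionality_gives_r_one(self):
        lengths = {"chr1": 1_000_000, "chr2": 2_000_000, "chr3": 3_000_000}
        variants = []
        k = 0
        for i, chrom in enumerate(("chr1", "chr2", "chr3")):
            for j in range(2 * (i + 1)):  # 2, 4, 6 regions
                variants.append(cv(10_000 * (j + 1), 10_000 * (j + 1) + 500,
                                   chrom=chrom, sample=f"s{k % 3 + 1}"))
                k += 1
        regions = build_regions(variants, 0.70)
        summary = summarize_regions(regions, self._meta(), lengths)
        assert summary.corr_chrom_count[0] == pytest.approx(1.0)

    def test_equal_breed_counts_give_zero_chi_square(self):
        meta = [SampleMeta("s1", "A", "dairy", 10.0),
                SampleMeta("s2", "B", "beef", 10.0)]
        variants = [cv(1000, 2000, sample="s1"), cv(5000, 6000, sample="s2")]
        regions = build_regions(variants, 0.70)
        summary = summarize_regions(regions, meta, {"chr1": 100_000})
        assert summary.breed_chi2["statistic"] == pytest.approx(0.0)

    def test_unknown_chromosome_errors(self):
        regions = build_regions([cv(100, 500)], 0.70)
        with pytest.raises(ValueError, match="without a length"):
            summarize_regions(regions, self._meta(), {"chr9": 1000})

    def test_union_bp_never_exceeds_genome(self):
        rng = np.random.default_rng(29)
        lengths = {"chr1": 50_000, "chr2": 30_000}
        variants = [cv(int(s), min(int(s + rng.integers(100, 20_000)), lengths[c]),
                       chrom=c, sample=f"s{k % 3 + 1}")
                    for k, (s, c) in enumerate(
                        zip(rng.integers(1, 30_000, size=60),
                            rng.choice(["chr1", "chr2"], size=60)))]
        regions = build_regions(variants, 0.70)
        summary = summarize_regions(regions, self._meta(), lengths)
        assert summary.total_covered_bp <= summary.genome_length
        for _, row in summary.per_chrom.iterrows():
            assert row.covered_bp <= row.length
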