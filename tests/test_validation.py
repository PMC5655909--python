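"""Mendelian, replicate-run and external-array validation logic."""

import math

import numpy as np
import pytest

from cnvcons import (
    CNVRegion,
    ConsensusVariant,
    GenomicInterval,
    PedigreeRecord,
    VariantCall,
    external_validate,
    mendelian_validate,
    replicate_validate,
    validation_rate,
    validation_summary,
)
from cnvcons.validation import ValidationFlags, mendelian_percentage, round_half_up


def region(rid, carriers, start=1000, end=2000, rtype="deletion-only",
           tools=("pindel", "delly")):
    svtype = "DUP" if rtype == "duplication-only" else "DEL"
    members = [ConsensusVariant(
        interval=GenomicInterval("chr1", start, end), svtype=svtype,
        sample_id=c, tools=frozenset(tools), source_calls=[],
        tool_pairs=frozenset({frozenset(tools)}))
        for c in carriers]
    return CNVRegion(
        interval=GenomicInterval("chr1", start, end), region_type=rtype,
        members=members, carriers=frozenset(carriers), region_id=rid)


def call(start, end, sample, run="run1", svtype="DEL", tool="pindel"):
    return VariantCall(
        interval=GenomicInterval("chr1", start, end), svtype=svtype,
        tool=tool, sample_id=sample, support_reads=10, run_id=run)


class TestMendelian:
    def test_sire_son_pair_transmission(self):
        regions = [region("R1", {"sire", "son"}),
                   region("R2", {"son"}, start=5000, end=6000),
                   region("R3", {"sire"}, start=9000, end=9900)]
        ped = [PedigreeRecord("son", "sire")]
        flags, table = mendelian_validate(regions, ped)
        assert flags["R1"].mendelian is True
        assert flags["R2"].mendelian is False  # offspring only
        assert flags["R3"].mendelian is False  # parent only
        row = table.iloc[0]
        assert row.n_parent_carried == 2 and row.n_shared == 1
        assert row.fraction_transmitted == pytest.approx(0.5)

    def test_trio_either_parent_suffices(self):
        regions = [region("R1", {"dam", "son"}),
                   region("R2", {"sire", "dam", "son"}, start=5000, end=6000)]
        ped = [PedigreeRecord("son", "sire", "dam")]
        flags, _ = mendelian_validate(regions, ped)
        assert flags["R1"].mendelian and flags["R2"].mendelian

    def test_unknown_pedigree_sample_errors(self):
        regions = [region("R1", {"a", "b"})]
        with pytest.raises(ValueError, match="unknown sample"):
            mendelian_validate(regions, [PedigreeRecord("b", "ghost")],
                               cohort_ids={"a", "b"})

    def test_transmission_prob_one_validates_all_parent_carried(self):
        """Deterministic transmission: every parent-carried region is also
        in the offspring, so all of them validate."""
        rng = np.random.default_rng(0)
        regions = []
        for k in range(100):
            carriers = {"sire"} if rng.random() < 0.5 else {"other"}
            if "sire" in carriers:
                carriers.add("son")  # transmission probability 1
            regions.append(region(f"R{k}", carriers,
                                  start=10_000 * (k + 1),
                                  end=10_000 * (k + 1) + 500))
        flags, _ = mendelian_validate(regions, [PedigreeRecord("son", "sire")])
        for r in regions:
            if "sire" in r.carriers:
                assert flags[r.region_id].mendelian


class TestReplicate:
    def _regions(self):
        return [region("R1", {"rep1"}, 1000, 2000)]

    def test_identical_call_in_both_runs_validates(self):
        run_calls = {("rep1", "run1"): [call(1000, 2000, "rep1", "run1")],
                     ("rep1", "run2"): [call(1000, 2000, "rep1", "run2")]}
        flags, rate = replicate_validate(self._regions(), run_calls)
        assert flags["R1"].twice_sequenced is True
        assert rate == 1.0

    def test_call_in_one_run_only_fails(self):
        run_calls = {("rep1", "run1"): [call(1000, 2000, "rep1", "run1")],
                     ("rep1", "run2"): []}
        flags, rate = replicate_validate(self._regions(), run_calls)
        assert flags["R1"].twice_sequenced is False
        assert rate == 0.0

    def test_jittered_run_above_threshold_validates(self):
        # run2 call (1290, 2290): RO with the region = 711/1001 ~ 0.710 >= 0.70
        run_calls = {("rep1", "run1"): [call(1000, 2000, "rep1", "run1")],
                     ("rep1", "run2"): [call(1290, 2290, "rep1", "run2")]}
        flags, _ = replicate_validate(self._regions(), run_calls)
        assert flags["R1"].twice_sequenced is True
        # the same jitter fails a 0.75 threshold
        flags2, _ = replicate_validate(self._regions(), run_calls, match_thresh=0.75)
        assert flags2["R1"].twice_sequenced is False

    def test_wrong_type_does_not_validate(self):
        run_calls = {("rep1", "run1"): [call(1000, 2000, "rep1", "run1", svtype="DUP")],
                     ("rep1", "run2"): [call(1000, 2000, "rep1", "run2", svtype="DUP")]}
        flags, _ = replicate_validate(self._regions(), run_calls)
        assert flags["R1"].twice_sequenced is False  # deletion-only region

    def test_symmetric_in_run_order(self):
        run_calls = {("rep1", "run2"): [call(1000, 2000, "rep1", "run2")],
                     ("rep1", "run1"): [call(1000, 2000, "rep1", "run1")]}
        flags, _ = replicate_validate(self._regions(), run_calls)
        assert flags["R1"].twice_sequenced is True

    def test_single_run_animal_rejected(self):
        with pytest.raises(ValueError, match="single run"):
            replicate_validate(self._regions(),
                               {("rep1", "run1"): []})


class TestExternal:
    def test_exact_coordinate_match(self):
        regions = [region("R1", {"s1"})]
        flags = external_validate(regions, [call(1000, 2000, "s1", tool="cgh")])
        assert flags["R1"].cgh is True

    def test_threshold_semantics(self):
        regions = [region("R1", {"s1"}, 1000, 2000)]
        # external call with RO = 0.4: overlap 401 bp of a 1001-bp region
        ext = [call(1600, 2600, "s1", tool="cgh")]
        assert external_validate(regions, ext, 0.50)["R1"].cgh is False
        assert external_validate(regions, ext, 0.20)["R1"].cgh is True

    def test_per_sample_requires_carrier_match(self):
        regions = [region("R1", {"s1"})]
        ext = [call(1000, 2000, "other_animal", tool="cgh")]
        assert external_validate(regions, ext, per_sample=True)["R1"].cgh is False
        assert external_validate(regions, ext, per_sample=False)["R1"].cgh is True

    def test_snp_array_flag_separate(self):
        regions = [region("R1", {"s1"})]
        flags = external_validate(regions, [call(1000, 2000, "s1")],
                                  flag_attr="snp_array")
        assert flags["R1"].snp_array is True
        assert flags["R1"].validated is False  # SNP support alone never retains

    def test_lowering_threshold_monotone(self):
        rng = np.random.default_rng(7)
        regions = [region(f"R{k}", {"s1"}, 10_000 * (k + 1), 10_000 * (k + 1) + 1000)
                   for k in range(30)]
        ext = [call(int(r.start + rng.integers(0, 900)),
                    int(r.end + rng.integers(0, 900)), "s1")
               for r in regions]
        counts = []
        for thresh in (0.9, 0.7, 0.5, 0.2, 0.01):
            flags = external_validate(regions, ext, thresh)
            counts.append(sum(f.cgh for f in flags.values()))
        assert counts == sorted(counts)


class TestSummaryArithmetic:
    @pytest.mark.parametrize("validated, predicted, expected", [
        (3169, 7510, 42.2),
        (1047, 2048, 51.1),
        (3161, 7364, 42.9),
        (2139, 4840, 44.2),
        (4075, 17_479, 23.3),
        (2327, 6060, 38.4),
    ])
    def test_rate_one_decimal_half_up(self, validated, predicted, expected):
        assert validation_rate(validated, predicted) == expected

    def test_zero_predicted_is_nan(self):
        assert math.isnan(validation_rate(0, 0))

    def test_half_up_rounding(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(42.15, 1) == 42.2
        assert round_half_up(56.5, 0) == 57.0

    def test_prose_percentages(self):
        assert mendelian_percentage(4596, 8088) == 57.0
        assert mendelian_percentage(23, 68) == 34.0

    def test_summary_table_counts_pairs_and_totals(self):
        regions = [
            region("R1", {"s1"}, tools=("pindel", "delly")),
            region("R2", {"s1"}, 5000, 6000, tools=("pindel", "delly")),
            region("R3", {"s1"}, 9000, 9900, tools=("delly", "cnvnator")),
        ]
        flags = {"R1": ValidationFlags("R1", mendelian=True),
                 "R2": ValidationFlags("R2"),
                 "R3": ValidationFlags("R3", cgh=True)}
        df = validation_summary(regions, flags)
        pd_row = df[df.combination == "delly + pindel"].iloc[0]
        assert (pd_row.n_predicted, pd_row.n_validated) == (2, 1)
        assert pd_row.validation_rate_pct == 50.0
        total = df[df.combination == "Total"].iloc[0]
        assert (total.n_predicted, total.n_validated) == (3, 2)
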