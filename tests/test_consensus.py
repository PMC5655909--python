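"""Within-sample two-tool consensus: matching rules and component building."""

import itertools
import random

import numpy as np
import pytest

from cnvcons import ConsensusConfig, GenomicInterval, build_consensus, combination_counts, match_rule


class TestMatchRule:
    def test_pindel_delly_breakpoint_rule(self, make_call):
        a = make_call(1000, 5000, tool="pindel")
        b = make_call(1099, 5099, tool="delly")
        assert match_rule("pindel", "delly", a, b) is True
        c = make_call(1101, 5000, tool="delly")
        assert match_rule("pindel", "delly", a, c) is False

    def test_other_pairs_use_reciprocal_overlap(self, make_call):
        a = make_call(1000, 2000, tool="cnvnator")
        b = make_call(1010, 1990, tool="breakdancer")
        # RO = 981/1001 ~ 0.980 >= 0.90
        assert match_rule("cnvnator", "breakdancer", a, b) is True
        c = make_call(1600, 2600, tool="breakdancer")
        # RO = 401/1001 ~ 0.40
        assert match_rule("cnvnator", "breakdancer", a, c) is False

    def test_breakpoint_rule_replaces_ro_for_designated_pair(self, make_call):
        """Short calls with matching breakpoints but RO < 0.90 still match
        for the pindel+delly pair (rule is a replacement, not an addition)."""
        a = make_call(1000, 1400, tool="pindel")
        b = make_call(1090, 1490, tool="delly")  # RO = 311/401 ~ 0.776
        assert match_rule("pindel", "delly", a, b) is True
        assert match_rule("pindel", "delly", a, b,
                          ConsensusConfig(strict_bp_pair=True)) is False

    def test_same_tool_is_contract_violation(self, make_call):
        a = make_call(1000, 2000)
        with pytest.raises(ValueError):
            match_rule("pindel", "pindel", a, a)


class TestBuildConsensus:
    def test_two_tool_breakpoint_pair(self, make_call):
        calls = [make_call(1000, 5000, tool="pindel"),
                 make_call(1099, 5099, tool="delly")]
        (v,) = build_consensus(calls)
        assert v.tools == frozenset({"pindel", "delly"})
        assert (v.start, v.end) == (1000, 5099)  # union span
        assert v.tool_pairs == frozenset({frozenset({"pindel", "delly"})})

    def test_single_tool_discarded(self, make_call):
        assert build_consensus([make_call(1000, 2000, tool="cnvnator")]) == []

    def test_same_tool_duplicates_discarded(self, make_call):
        calls = [make_call(1000, 2000, tool="cnvnator"),
                 make_call(1000, 2000, tool="cnvnator")]
        assert build_consensus(calls) == []

    def test_four_tools_six_pairs(self, make_call):
        calls = [make_call(1000, 2000, tool=t)
                 for t in ("cnvnator", "breakdancer", "pindel", "delly")]
        (v,) = build_consensus(calls)
        assert len(v.tools) == 4
        assert len(v.tool_pairs) == 6  # C(4,2); identical intervals match all rules

    def test_del_and_dup_never_merge_within_sample(self, make_call):
        calls = [make_call(1000, 2000, tool="pindel", svtype="DEL"),
                 make_call(1000, 2000, tool="delly", svtype="DEL"),
                 make_call(1000, 2000, tool="pindel", svtype="DUP"),
                 make_call(1000, 2000, tool="delly", svtype="DUP")]
        out = build_consensus(calls)
        assert sorted(v.svtype for v in out) == ["DEL", "DUP"]

    def test_mixed_samples_rejected(self, make_call):
        calls = [make_call(1, 100, sample="s1"), make_call(1, 100, sample="s2", tool="delly")]
        with pytest.raises(ValueError, match="one sample"):
            build_consensus(calls)

    def test_permutation_invariance(self, make_call):
        rng = random.Random(3)
        calls = []
        for k in range(30):
            base = 10_000 * (k + 1)
            calls.append(make_call(base, base + 1500, tool="cnvnator"))
            if k % 2:
                calls.append(make_call(base + 20, base + 1520, tool="delly"))
            if k % 3 == 0:
                calls.append(make_call(base + 50, base + 1450, tool="pindel"))
        ref = build_consensus(calls)
        for _ in range(5):
            shuffled = calls[:]
            rng.shuffle(shuffled)
            out = build_consensus(shuffled)
            assert [(v.start, v.end, v.tools) for v in out] == \
                [(v.start, v.end, v.tools) for v in ref]

    def test_span_contains_every_member(self, make_call):
        rng = np.random.default_rng(5)
        calls = []
        for k in range(60):
            s = int(rng.integers(1, 500_000))
            l = int(rng.integers(100, 5000))
            calls.append(make_call(s, s + l,
                                   tool=["cnvnator", "breakdancer", "pindel", "delly"][k % 4]))
        for v in build_consensus(calls):
            for m in v.source_calls:
                assert v.start <= m.start and m.end <= v.end


def brute_force_components(calls, config=ConsensusConfig()):
    """Independent oracle: boolean adjacency + transitive closure by
    repeated matrix products."""
    n = len(calls)
    adj = np.eye(n, dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        a, b = calls[i], calls[j]
        if (a.tool != b.tool and a.svtype == b.svtype and a.chrom == b.chrom
                and match_rule(a.tool, b.tool, a, b, config)):
            adj[i, j] = adj[j, i] = True
    closure = adj.copy()
    while True:
        nxt = closure @ closure
        if (nxt == closure).all():
            break
        closure = nxt
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = frozenset(np.flatnonzero(closure[i]).tolist())
        seen |= comp
        comps.append(comp)
    return comps


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_components_match_transitive_closure(self, make_call, seed):
        rng = np.random.default_rng(seed)
        tools = ("cnvnator", "breakdancer", "pindel", "delly")
        calls = []
        for _ in range(int(rng.integers(20, 80))):
            s = int(rng.integers(1, 100_000))
            l = int(rng.integers(60, 4000))
            calls.append(make_call(
                s, s + l, tool=tools[int(rng.integers(4))],
                svtype="DEL" if rng.random() < 0.8 else "DUP"))
        expected = {
            frozenset((calls[i].start, calls[i].end, calls[i].tool) for i in comp)
            for comp in brute_force_components(calls)
            if len({calls[i].tool for i in comp}) >= 2
        }
        got = {
            frozenset((m.start, m.end, m.tool) for m in v.source_calls)
            for v in build_consensus(calls)
        }
        assert got == expected


class TestCombinationCounts:
    def test_three_tool_variant_increments_three_rows(self, make_call):
        calls = [make_call(1000, 2000, tool=t)
                 for t in ("pindel", "delly", "cnvnator")]
        (v,) = build_consensus(calls)
        df = combination_counts([v])
        assert df["n_variants"].sum() == 3
        assert set(df.loc[df.n_variants == 1, "tool_a"] + "+"
                   + df.loc[df.n_variants == 1, "tool_b"]) == \
            {"cnvnator+delly", "cnvnator+pindel", "delly+pindel"}

    def test_disjoint_pairs_counted_separately(self, make_call):
        calls = [make_call(1000, 2000, tool="delly"),
                 make_call(1000, 2000, tool="breakdancer"),
                 make_call(50_000, 52_000, tool="delly"),
                 make_call(50_000, 52_000, tool="breakdancer")]
        out = build_consensus(calls)
        df = combination_counts(out, tools=("cnvnator", "breakdancer", "pindel", "delly"))
        row = df[(df.tool_a == "breakdancer") & (df.tool_b == "delly")]
        assert int(row.n_variants.iloc[0]) == 2
        assert df.n_variants.sum() == 2  # all other pairs zero-filled
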