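import pytest

from cnvcons import GenomicInterval, VariantCall


@pytest.fixture
def iv():
    def make(chrom="chr1", start=1, end=100):
        return GenomicInterval(chrom, start, end)
    return make


@pytest.fixture
def make_call():
    def make(start, end, chrom="chr1", svtype="DEL", tool="pindel",
             sample="s1", support=10, run="run1"):
        return VariantCall(
            interval=GenomicInterval(chrom, start, end),
            svtype=svtype, tool=tool, sample_id=sample,
            support_reads=support, run_id=run,
        )
    return make


@pytest.fixture(scope="session")
def demo_truth():
    """One shared demo-scale simulation for the slower integration tests."""
    from cnvcons import SimConfig, simulate_truth

    return simulate_truth(SimConfig.demo(seed=11))
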