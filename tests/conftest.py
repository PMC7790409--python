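import textwrap

import numpy as np
import pytest

from aidscope import default_config, simulate_cohort
from aidscope.core_io import TargetSpace

VCF_TEMPLATE = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=100000>
    ##FILTER=<ID=clustered_events,Description="x">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
    """)


@pytest.fixture
def make_vcf(tmp_path):
    """Write a small VCF from body lines; returns the path."""
    def _make(body_lines, name="test.vcf"):
        path = tmp_path / name
        body = "".join(line + "\n" for line in body_lines)
        path.write_text(VCF_TEMPLATE + body)
        return path
    return _make


@pytest.fixture
def make_targets():
    """TargetSpace over explicit sequences (single or multi interval)."""
    def _make(sequences, intervals=None):
        if intervals is None:
            intervals = [(c, 0, len(s)) for c, s in sequences.items()]
        return TargetSpace(intervals, sequences)
    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down two-genotype cohort shared by structural tests.

    Same clonal architecture and mutational process as the full presets,
    on a 150 kb genome so the whole suite stays fast.
    """
    cfg = default_config(seed=42, genome_length=150_000, n_genes=150,
                         n_driver_genes=40, n_lymphoma_genes=20,
                         cnv_length=3000)
    return simulate_cohort(cfg)
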