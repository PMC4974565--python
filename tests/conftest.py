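"""Shared fixtures: small synthetic constructs and simulated read sets."""

import numpy as np
import pytest

import dipseq as d


@pytest.fixture(scope="session")
def ref370():
    """Synthetic 370-codon LBD construct (MBP-sized)."""
    return d.make_demo_reference(n_codons=370, seed=101)


@pytest.fixture(scope="session")
def ref410():
    """Synthetic 410-codon fusion construct (TMBP-sized)."""
    return d.make_demo_reference(n_codons=410, seed=102, name="demoFusion")


@pytest.fixture(scope="session")
def cassette():
    """Synthetic frame-preserving cassette (cpGFP-sized, 5-bp duplication)."""
    return d.make_demo_cassette(seed=201)


@pytest.fixture(scope="session")
def short_cassette():
    """A cassette shorter than a read, to exercise both-ends-in-one-read."""
    return d.make_demo_cassette(length=100, duplication_len=5, seed=202)


@pytest.fixture(scope="session")
def naive_lib(ref370, cassette):
    return d.simulate_naive_library(ref370, cassette, n_variants=6000, seed=301)


@pytest.fixture(scope="session")
def simulated_reads(tmp_path_factory, ref370, cassette, naive_lib):
    """Error-free single-end reads from the naive library, with ground truth."""
    out = tmp_path_factory.mktemp("reads")
    paths, truth = d.generate_reads(
        naive_lib, ref370, cassette, depth=30000, out_prefix=out / "naive", seed=302
    )
    return paths, truth


@pytest.fixture(scope="session")
def called_observations(simulated_reads, ref370, cassette):
    paths, _truth = simulated_reads
    return d.call_reads(paths, ref370, cassette)
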