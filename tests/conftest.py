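import numpy as np
import pytest

import ribotrace as rt


@pytest.fixture(scope="session")
def nluc_design():
    return rt.build_reporter("elongation_NLuc")


@pytest.fixture(scope="session")
def repeat_design():
    return rt.build_reporter("elongation_GGGGCC70")


@pytest.fixture(scope="session")
def twocolor_design():
    return rt.build_reporter("frameshift_twocolor")


@pytest.fixture
def tiny_design():
    """30-codon design with an epitope at every codon: the completion
    times trace the full ribosome trajectory at codon resolution."""
    return rt.build_reporter({
        "name": "tiny_fullcov",
        "total_length": 30,
        "regions": [("cassette_ch1", 1, 30, "epitope_cassette")],
        "epitope_positions_ch1": list(range(1, 31)),
    })


def make_trace(signal, dt=10.0, rna=None, cell_id=0, rna_id=0):
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    return rt.IntensityTrace(
        cell_id=cell_id,
        rna_id=rna_id,
        time=np.arange(n) * dt,
        rna=np.full(n, 10.0) if rna is None else np.asarray(rna, dtype=float),
        ch1=signal,
        dt=dt,
    )
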