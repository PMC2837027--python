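import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from duplexnn import DuplexDataset, DuplexRecord, GeneratorConfig, generate_dataset

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_record(seq1, dg=-2.0, duplex_id="d1", temperature=25.0, **kw):
    """Perfect-match record from a single strand."""
    from duplexnn import revcomp

    return DuplexRecord(
        seq1=seq1,
        seq2=revcomp(seq1),
        duplex_id=duplex_id,
        struct1="(" * len(seq1),
        struct2=")" * len(seq1),
        dg_exp=dg,
        temperature=temperature,
        **kw,
    )


@pytest.fixture
def tiny_dataset():
    """Four hand-built perfect-match duplexes."""
    return DuplexDataset(
        [
            make_record("AAAA", dg=-1.7, duplex_id="a"),
            make_record("ACGT", dg=-3.1, duplex_id="b"),
            make_record("GGGGCC", dg=-7.9, duplex_id="c"),
            make_record("ATATAT", dg=-2.2, duplex_id="d"),
        ],
        source_label="tiny",
    )


@pytest.fixture
def synth_noise_free():
    """120 synthetic duplexes with exact (noise-free) model free energies."""
    return generate_dataset(GeneratorConfig(n_duplexes=120, noise_sd=0.0, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
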