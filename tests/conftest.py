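import numpy as np
import pytest

from mhclineage.alleles_io import AlleleName, AlleleSet


def make_alleles(seq_by_name: dict[str, str]) -> AlleleSet:
    names = [AlleleName.parse(n) for n in seq_by_name]
    return AlleleSet(names=names, sequences=list(seq_by_name.values()))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def trio_fasta(tmp_path):
    """Three 9-nt aligned records."""
    p = tmp_path / "trio.fasta"
    p.write_text(
        ">HLA-DRB1*03:01\nATGAAATTT\n"
        ">HLA-DRB1*11:01\nATGAAATTC\n"
        ">HLA-DRB1*08:02\nATGAAGTTT\n"
    )
    return p
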