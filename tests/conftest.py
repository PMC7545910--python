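import logging

import pandas as pd
import pytest

from bsamap.io import GenomeLayout


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.disable(logging.INFO)
    yield
    logging.disable(logging.NOTSET)


@pytest.fixture
def small_counts() -> pd.DataFrame:
    """Three SNPs on two chromosomes with easy-arithmetic counts."""
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "pos": [100, 900, 500],
            "ref": ["A", "C", "G"],
            "alt": ["T", "G", "A"],
            "refA": [2, 10, 5],
            "altA": [8, 0, 5],
            "refB": [5, 10, 5],
            "altB": [5, 10, 5],
        }
    )


@pytest.fixture
def tiny_genome() -> GenomeLayout:
    return GenomeLayout([("chr1", 1000), ("chr2", 1000)])
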