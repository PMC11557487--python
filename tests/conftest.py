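import numpy as np
import pandas as pd
import pytest

from bsamap.scan import VARIANT_COLUMNS


@pytest.fixture
def variant_table():
    """Hand-built six-record table exercising each site-filter rule."""
    rows = [
        # chrom, pos, ref, alt, qual, aa_mut, rd_mut, aa_wt, rd_wt, indel, miss_m, miss_w
        ("chr1", 100, "C", "T", 99, 2, 3, 1, 10, False, False, False),    # depth 3 < 5
        ("chr1", 200, "C", "T", 99, 3, 5, 2, 10, False, False, False),    # ok (min bound)
        ("chr1", 300, "G", "A", 99, 70, 150, 10, 150, False, False, False),  # ok
        ("chr1", 400, "G", "A", 99, 90, 201, 10, 100, False, False, False),  # depth > 200
        ("chr1", 500, "C", "CT", 99, 5, 10, 5, 10, True, False, False),   # indel
        ("chr1", 600, "C", "T", 99, 0, 0, 5, 10, False, True, False),     # missing
    ]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(20241030)
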