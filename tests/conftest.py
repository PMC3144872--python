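import numpy as np
import pytest

from clustrep.association import SnpRecord


def make_records(positions, pvals=None, chrom="1", prefix="rs"):
    """SnpRecords at given positions (default p=0.01, i.e. significant)."""
    if pvals is None:
        pvals = [0.01] * len(positions)
    return [
        SnpRecord(chromosome=chrom, position=int(p), snp_id=f"{prefix}{i}", p_value=float(pv))
        for i, (p, pv) in enumerate(zip(positions, pvals))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
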