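import numpy as np
import pytest

from scdrift.core_io import CellMethylome, CpGCall


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_cell(cell_id, sites, individual="ind1", age_group="young", age_weeks=6.0):
    """Build a cell from {(chrom, pos): (n_meth, n_unmeth)}."""
    calls = [
        CpGCall(chrom, pos, m, u) for (chrom, pos), (m, u) in sorted(sites.items())
    ]
    return CellMethylome(
        cell_id=cell_id,
        individual_id=individual,
        age_group=age_group,
        age_weeks=age_weeks,
        calls=calls,
        n_alignments=sum(m + u for m, u in sites.values()),
    )


@pytest.fixture
def two_cells():
    a = make_cell("a", {("chr1", p): (1, 0) for p in (11, 21, 31)})
    b = make_cell("b", {("chr1", p): (1, 0) for p in (11, 21, 31)})
    return [a, b]
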