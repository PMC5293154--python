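import numpy as np
import pandas as pd
import pytest

from subpolii.ms_quant import ProteinMatrix
from subpolii.netseq_core import OccupancyTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def toy_matrix():
    """3 proteins x 2 conditions x 3 replicates with a missingness pattern."""
    vals = pd.DataFrame(
        {
            "a1": [2.0, 8.0, 32.0],
            "a2": [4.0, 8.0, 16.0],
            "a3": [2.0, 16.0, 32.0],
            "b1": [np.nan, 8.0, 8.0],
            "b2": [np.nan, 8.0, np.nan],
            "b3": [np.nan, 4.0, 8.0],
        },
        index=["P1", "P2", "P3"],
    )
    cond = {s: s[0] for s in vals.columns}
    return ProteinMatrix(vals, cond, scale="raw")


def make_track(vectors: dict, total_reads=None) -> OccupancyTrack:
    """OccupancyTrack from {(chrom, strand): list-like}; missing strands zeroed."""
    chroms = {c: len(v) for (c, _s), v in vectors.items()}
    data = {}
    for c, n in chroms.items():
        for s in "+-":
            v = vectors.get((c, s))
            data[(c, s)] = np.asarray(v, dtype=float) if v is not None else np.zeros(n)
    track = OccupancyTrack(data=data)
    total = sum(v.sum() for v in data.values())
    track.total_reads = int(total) if total_reads is None else total_reads
    return track
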