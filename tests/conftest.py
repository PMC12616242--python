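import numpy as np
import pandas as pd
import pytest

from chromredist import (
    GenomeLayout,
    Interval,
    PeakSet,
    SyntheticConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    """One synthetic cohort under the default study conditions."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture
def toy_layout():
    return GenomeLayout([("chr1", 100_000), ("chr2", 50_000)])


def random_peakset(rng, layout, n, label="peaks", max_len=2000):
    """Random intervals on a toy layout (shared helper for oracle tests)."""
    ivs = []
    chroms = layout.names
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        L = layout.length_of(chrom)
        start = int(rng.integers(0, L - max_len))
        length = int(rng.integers(1, max_len))
        ivs.append(Interval(chrom, start, start + length))
    return PeakSet(ivs, label)


def random_bedgraph(rng, layout, n_rows=60, max_len=1500):
    """Sparse random coverage rows (possibly overlapping none of the genome)."""
    rows = []
    for chrom, L in layout:
        pos = 0
        for _ in range(n_rows):
            gap = int(rng.integers(0, 400))
            length = int(rng.integers(1, max_len))
            start = pos + gap
            end = start + length
            if end > L:
                break
            rows.append((chrom, start, end, float(rng.integers(0, 30))))
            pos = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def dense_coverage_oracle(df, layout):
    """Per-base expansion of a bedGraph frame (independent reference)."""
    arrays = {chrom: np.zeros(L) for chrom, L in layout}
    for r in df.itertuples():
        arrays[r.chrom][r.start : r.end] = r.value
    return arrays
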