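import numpy as np
import pandas as pd
import pytest

import rilmap as rm
from rilmap.matrix import GenotypeMatrix


def make_matrix(rows, lines=None, markers=None):
    """Build a GenotypeMatrix from a list of per-line call strings."""
    values = [list(r) for r in rows]
    n, m = len(values), len(values[0])
    lines = lines or [f"L{i+1}" for i in range(n)]
    markers = markers or [f"M{j+1}" for j in range(m)]
    return GenotypeMatrix.from_values(values, lines, markers)


@pytest.fixture(scope="session")
def noisefree_sim():
    """Two 80 cM chromosomes, 30 markers each, 92 F7 lines, no noise."""
    cfg = rm.cpr01_like_config(n_chromosomes=2, markers_per_chromosome=30,
                               seed=11)
    matrix, truth = rm.simulate_ril_population(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Same design with 20 % missing calls and 0.5 % genotyping error."""
    cfg = rm.cpr01_like_config(n_chromosomes=2, markers_per_chromosome=30,
                               missing_rate=0.2, error_rate=0.005, seed=13)
    matrix, truth = rm.simulate_ril_population(cfg)
    return cfg, matrix, truth


@pytest.fixture()
def collinear_marker_info():
    """MarkerInfo for a single-chromosome map whose physical order equals
    map order (20 markers on Ca1)."""
    markers = [f"m{j:02d}" for j in range(20)]
    return pd.DataFrame(
        {
            "scaffold": [f"s{j // 5}" for j in range(20)],
            "chrom": "Ca1",
            "bp": np.arange(20) * 100_000 + 1,
        },
        index=pd.Index(markers, name="marker"),
    )
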