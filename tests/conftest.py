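import numpy as np
import pandas as pd
import pytest

from wheatpheno import simulate as sim


@pytest.fixture(scope="session")
def small_map():
    return sim.make_genetic_map(n_chrom=3, markers_per_chrom=20, chrom_length_cm=100)


@pytest.fixture(scope="session")
def ril_population(small_map):
    return sim.simulate_ril_population(small_map, n_lines=300, n_selfing_generations=5, seed=11)


@pytest.fixture(scope="session")
def balanced_plots():
    """Balanced 2-rep single-year trial: 40 entries, known variance structure."""
    rng = np.random.default_rng(42)
    g = rng.normal(0.0, 2.0, size=40)
    rows = []
    for e in range(40):
        for rep in (1, 2):
            rows.append(
                {
                    "entry": f"E{e:02d}",
                    "year": 1,
                    "rep": rep,
                    "row": rep,
                    "col": e + 1,
                    "value": g[e] + rng.normal(0.0, 1.0),
                }
            )
    return pd.DataFrame(rows)
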