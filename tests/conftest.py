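import numpy as np
import pandas as pd
import pytest

from fvtqtl.growth import logistic_size_raw
from fvtqtl.simulate import SimConfig, simulate_map_and_genotypes


@pytest.fixture(scope="session")
def small_map_genos():
    """100 RILs on 3 chromosomes, 10 cM marker spacing."""
    cfg = SimConfig(n_ril=100, n_chrom=3, markers_per_chrom=11, seed=7)
    return simulate_map_and_genotypes(cfg)


@pytest.fixture()
def single_genotype_measurements():
    """8 plants of one genotype, 12 points each, true
    (r=0.08, Lmax=60, L0=3), noise SD 0.1 mm."""
    rng = np.random.default_rng(42)
    rows = []
    t = np.linspace(5, 110, 12)
    for j in range(8):
        y = logistic_size_raw(0.08, 60.0, 3.0, t) + rng.normal(0, 0.1, t.size)
        for tk, yk in zip(t, y):
            rows.append((f"P{j}", "G1", float(tk), float(yk)))
    return pd.DataFrame(rows, columns=["plant_id", "genotype", "t_dd", "value"])
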