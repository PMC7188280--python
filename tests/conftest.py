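"""Shared fixtures: small deterministic populations built in memory."""

import numpy as np
import pandas as pd
import pytest

from wheatsel.simulate import CHROMOSOMES, GenotypeMatrix, SimConfig, simulate_founders


def make_geno(dosages, line_ids=None, marker_ids=None) -> GenotypeMatrix:
    """GenotypeMatrix from a raw array with valid wheat-style marker IDs."""
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    if line_ids is None:
        line_ids = [f"L{i:03d}" for i in range(n)]
    if marker_ids is None:
        marker_ids = [f"S{CHROMOSOMES[j % 21]}_{(j + 1) * 1000}" for j in range(m)]
    return GenotypeMatrix(pd.DataFrame(dosages, index=line_ids, columns=marker_ids))


def random_inbred_geno(rng, n, m, p=0.4) -> GenotypeMatrix:
    return make_geno(2 * (rng.random((n, m)) < p).astype(int))


@pytest.fixture(scope="session")
def founders_small():
    """120 inbred lines x 300 markers, fixed seed."""
    cfg = SimConfig(n_lines=120, n_markers=300, n_qtl=20, h2_target=0.5, seed=7)
    return simulate_founders(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
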