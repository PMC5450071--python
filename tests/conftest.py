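"""Shared fixtures: small synthetic collections and random-matrix factories."""

import numpy as np
import pandas as pd
import pytest

from germpop.genotype_io import MISSING, GenotypeMatrix
from germpop.simulate import SimConfig, genome_map_for, simulate_collection


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, n=10, m=10, missing_rate=0.1) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    calls[rng.random((n, m)) < missing_rate] = MISSING
    return GenotypeMatrix(calls,
                          [f"A{i}" for i in range(n)],
                          [f"M{j}" for j in range(m)])


@pytest.fixture
def matrix_factory():
    return random_matrix


def trivial_markers(gm, chrom="chr01", spacing=10_000) -> pd.DataFrame:
    return pd.DataFrame({
        "marker_id": gm.marker_ids,
        "chrom": chrom,
        "pos": np.arange(1, gm.n_markers + 1) * spacing,
        "ref": "A",
        "alt": "C",
    })


@pytest.fixture
def markers_for():
    return trivial_markers


@pytest.fixture(scope="session")
def small_collection():
    """A modest two-pool collection reused across modules (~70 accessions)."""
    cfg = SimConfig(n_markers=800, n_pool1=30, n_pool2=40, n_admixed=4,
                    n_chrom=4, chrom_length_bp=2_000_000, seed=11,
                    calib_markers=800)
    gm, markers, samples, truth = simulate_collection(cfg)
    return dict(config=cfg, gm=gm, markers=markers, samples=samples,
                truth=truth, genome_map=genome_map_for(cfg))
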