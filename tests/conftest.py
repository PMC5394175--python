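import numpy as np
import pandas as pd
import pytest

from aimsel import GenotypeMatrix, SimConfig, simulate


TINY = dict(
    samples_per_group=[4, 4, 4, 4, 4],
    n_background=440,
    n_landrace_loci=24,
    n_altitude_loci=24,
    n_shared_loci=12,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """20 samples x 500 markers with missing calls and planted structure."""
    gm, truth = simulate(SimConfig(seed=7, **TINY))
    return gm, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The 50 x 2,100 benchmark cohort."""
    gm, truth = simulate(SimConfig(seed=7))
    return gm, truth


def toy_matrix(calls, landrace=None, altitude=None, marker_prefix="m"):
    """Hand-rolled GenotypeMatrix from a dosage array for unit tests."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    samples = pd.DataFrame(index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
    if landrace is not None:
        samples["landrace"] = list(landrace)
    if altitude is not None:
        samples["altitude_masl"] = list(altitude)
    snps = pd.DataFrame(
        {
            "chromosome": ["1"] * m,
            "position": np.arange(1, m + 1) * 100,
            "allele_a": ["A"] * m,
            "allele_b": ["G"] * m,
        },
        index=pd.Index([f"{marker_prefix}{j}" for j in range(m)], name="marker_id"),
    )
    return GenotypeMatrix(calls, samples, snps)
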