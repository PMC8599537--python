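import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methclock.simdata import SimConfig, SpeciesSpec, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """300 CpGs x 30 marmoset samples: quick but has real age signal."""
    cfg = SimConfig(
        n_cpgs=300,
        species_specs=(SpeciesSpec("marmoset", 22.8, (0.5, 15.5), 30),),
        n_age_cpgs=10,
        n_sex_cpgs=5,
        n_treatment_cpgs=5,
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The two-species default world (2,000 CpGs, 60 + 40 samples)."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture()
def toy_annotation():
    """100 annotated probes, 10 of them promoters."""
    n = 100
    ids = [f"cpg{i:03d}" for i in range(n)]
    classes = ["promoter"] * 10 + ["intron"] * 50 + ["intergenic"] * 40
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "pos": np.arange(1, n + 1) * 1000,
            "cpg_id": ids,
            "gene": [f"G{i}" for i in range(n)],
            "tss_distance": np.linspace(-3000, 3000, n).astype(int),
            "region_class": classes,
        }
    )
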