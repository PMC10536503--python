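import numpy as np
import pandas as pd
import pytest

from carriergwas import genio
from carriergwas.pedigree import build_pedigree
from carriergwas.simdata import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated cohort shared across read-only tests."""
    cfg = SimConfig(
        n_founders=40, n_generations=4, n_chromosomes=3, snps_per_chromosome=150,
        risk_locus=("1", 75, 0.3), seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_gm(small_dataset):
    return genio.recode_minor(small_dataset.genotypes)


@pytest.fixture()
def trio_pedigree():
    return build_pedigree(
        pd.DataFrame(
            [
                {"id": "sire", "sire": None, "dam": None, "sex": "M", "year": 2000},
                {"id": "dam", "sire": None, "dam": None, "sex": "F", "year": 2000},
                {"id": "child", "sire": "sire", "dam": "dam", "sex": "F", "year": 2002},
            ]
        )
    )


def make_gm(dosage, chrom="1", bp_start=1000, spacing=1000, samples=None):
    """Build a GenotypeMatrix from a dosage array for hand-constructed tests."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    samples = samples or [f"s{i}" for i in range(n)]
    bps = [bp_start + spacing * j for j in range(m)]
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "bp": bps,
            "id": [f"{chrom}:{b}" for b in bps],
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    return genio.GenotypeMatrix(list(samples), variants, dosage)


@pytest.fixture()
def gm_factory():
    return make_gm
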