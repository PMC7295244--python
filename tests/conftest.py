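import numpy as np
import pandas as pd
import pytest

from eigenmap.io import GenotypeMatrix, RunConfig
from eigenmap.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One default-condition synthetic cohort shared across read-only tests."""
    spec = CohortSpec(seed=11)
    geno, kinship, expr, modules, cov, truth = simulate_cohort(spec)
    return {
        "spec": spec,
        "geno": geno,
        "kinship": kinship,
        "expr": expr,
        "modules": modules,
        "cov": cov,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def desk_config():
    """Published thresholds with the submodule size floor at desk scale."""
    return RunConfig(min_module_size=20, seed=11)


def make_genotypes(dosages: np.ndarray, chrom=None, pos=None) -> GenotypeMatrix:
    """Wrap a raw dosage matrix in a GenotypeMatrix for unit tests."""
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "ref": "A",
            "alt": "G",
            "id": [f"v{j + 1}" for j in range(m)],
            "imputed": False,
        }
    )
    return GenotypeMatrix(
        dosages.astype(float), variants, [f"s{i + 1}" for i in range(n)]
    )
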