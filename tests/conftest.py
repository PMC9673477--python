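import numpy as np
import pytest

from gsbench.genotypes import GenotypeMatrix, generate_synthetic_genotypes


@pytest.fixture(scope="session")
def small_panel() -> GenotypeMatrix:
    """300 samples x 400 homozygous markers, MAF in (0.1, 0.5]."""
    return generate_synthetic_genotypes(300, 400, seed=101)


@pytest.fixture(scope="session")
def sim_panel() -> GenotypeMatrix:
    """1,000 samples x 1,500 markers; large enough for the built-in configs."""
    return generate_synthetic_genotypes(1000, 1500, seed=202)


def random_genotypes(n: int, m: int, seed: int, het: bool = True) -> GenotypeMatrix:
    """Unstructured toy matrix (allows heterozygotes, arbitrary MAF)."""
    rng = np.random.default_rng(seed)
    vals = rng.choice([0, 1, 2] if het else [0, 2], size=(n, m))
    return GenotypeMatrix([f"s{i}" for i in range(n)], [f"m{j}" for j in range(m)], vals)
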