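import numpy as np
import pytest

from cycleprofiler import load_templates


@pytest.fixture(scope="session")
def template():
    return load_templates()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_community(rng, n_genomes, n_functions, n_groups=3):
    """Random synthetic community: binary presence, positive coverages, groups."""
    import pandas as pd

    genomes = [f"g{i}" for i in range(n_genomes)]
    functions = [f"f{i}" for i in range(n_functions)]
    while True:
        s = rng.integers(0, 2, size=(n_genomes, n_functions))
        if s.sum() > 0:
            break
    presence = pd.DataFrame(s, index=genomes, columns=functions)
    coverage = pd.Series(rng.uniform(1, 50, size=n_genomes), index=genomes)
    groups = pd.Series([f"p{int(i)}" for i in rng.integers(0, n_groups, size=n_genomes)],
                       index=genomes)
    return presence, coverage, groups
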