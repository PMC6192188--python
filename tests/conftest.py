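import numpy as np
import pytest

from hapgeo import collapse_haplotypes, make_study_fixture, tabulate_by_population


@pytest.fixture(scope="session")
def cp_fixture():
    return make_study_fixture("cpDNA")


@pytest.fixture(scope="session")
def its_fixture():
    return make_study_fixture("ITS")


@pytest.fixture(scope="session")
def cp_collapsed(cp_fixture):
    col = collapse_haplotypes(cp_fixture.alignment)
    table = tabulate_by_population(col, cp_fixture.popmap)
    return col, table


@pytest.fixture(scope="session")
def its_collapsed(its_fixture):
    col = collapse_haplotypes(its_fixture.alignment, label_prefix="R")
    table = tabulate_by_population(col, its_fixture.popmap)
    return col, table


@pytest.fixture(scope="session")
def cp_label_map(cp_fixture, cp_collapsed):
    """Constructed haplotype label -> discovered label."""
    col, _ = cp_collapsed
    rep_to_disc = {seq: h for h, seq in col.representatives.items()}
    return {true: rep_to_disc[seq] for true, seq in cp_fixture.haplotype_sequences.items()}


@pytest.fixture(scope="session")
def its_label_map(its_fixture, its_collapsed):
    col, _ = its_collapsed
    rep_to_disc = {seq: h for h, seq in col.representatives.items()}
    return {true: rep_to_disc[seq] for true, seq in its_fixture.haplotype_sequences.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)


def random_haplotype_table(rng, n_pops=None, n_haps=None, max_n=20):
    """A random population x haplotype count table with n_k >= 2 everywhere."""
    import pandas as pd

    n_pops = n_pops or int(rng.integers(2, 6))
    n_haps = n_haps or int(rng.integers(2, 6))
    while True:
        counts = rng.multinomial(
            rng.integers(2, max_n + 1), rng.dirichlet(np.ones(n_haps)), size=n_pops
        )
        if (counts.sum(axis=1) >= 2).all() and (counts.sum(axis=0) >= 1).all():
            break
    return pd.DataFrame(
        counts, index=[f"P{i+1}" for i in range(n_pops)],
        columns=[f"H{j+1}" for j in range(n_haps)],
    )


def random_distance_matrix(rng, k, max_d=8):
    """A random integer metric built from random binary site patterns."""
    while True:
        sites = rng.integers(0, 2, size=(k, max_d))
        d = (sites[:, None, :] != sites[None, :, :]).sum(axis=2).astype(float)
        if np.all(d[~np.eye(k, dtype=bool)] > 0):
            return d
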