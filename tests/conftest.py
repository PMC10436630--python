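import numpy as np
import pandas as pd
import pytest

from hipca import HiPCA, SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Sparse 40-species cohort with two planted fault species."""
    spec = SyntheticSpec(
        D=40,
        d_true=4,
        n_healthy=300,
        n_unhealthy=150,
        zero_fraction=0.3,
        fault_species=[2, 7],
        fault_magnitude=6.0,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def dense_cohort():
    """Dense (no sparsification) cohort where the transform chain is
    exactly invertible."""
    spec = SyntheticSpec(
        D=40,
        d_true=4,
        n_healthy=400,
        n_unhealthy=200,
        zero_fraction=0.0,
        fault_species=[5],
        fault_magnitude=6.0,
        seed=21,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def fitted(dense_cohort):
    table, _ = dense_cohort
    return HiPCA.from_abundance(table).fit(pve=0.9, confidence=0.9)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def metaphlan_file(tmp_path):
    """Minimal MetaPhlAn2-style profile: kingdom, genus, species rows."""
    text = (
        "#clade_name\tS1\tS2\n"
        "k__Bacteria\t100.0\t100.0\n"
        "k__Bacteria|p__Firmicutes|g__Roseburia\t12.5\t3.0\n"
        "k__Bacteria|p__Firmicutes|g__Roseburia|s__Roseburia_hominis\t10.5\t2.5\n"
    )
    path = tmp_path / "profile.tsv"
    path.write_text(text)
    return path


@pytest.fixture()
def metadata_file(tmp_path):
    path = tmp_path / "meta.tsv"
    path.write_text(
        "sample_id\tlabel\tphenotype\n"
        "S1\thealthy\thealthy\n"
        "S2\tunhealthy\tIBD\n"
    )
    return path
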