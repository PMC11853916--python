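import numpy as np
import pandas as pd
import pytest

from perimark import (
    AbundanceTable,
    CohortLabels,
    PlantedCombo,
    SyntheticSpec,
    generate_cohort,
)


@pytest.fixture
def tiny_table():
    """Six samples x four taxa with an obvious PI-enriched first taxon."""
    data = pd.DataFrame(
        {
            "taxA": [100.0, 120.0, 90.0, 10.0, 12.0, 8.0],
            "taxB": [5.0, 6.0, 4.0, 5.5, 6.5, 4.5],
            "taxC": [0.0, 1.0, 0.0, 2.0, 0.0, 1.0],
            "taxD": [50.0, 40.0, 60.0, 45.0, 55.0, 50.0],
        },
        index=[f"s{i}" for i in range(6)],
    )
    return AbundanceTable(data)


@pytest.fixture
def tiny_labels():
    return CohortLabels(
        pd.Series(
            ["PI", "PI", "PI", "HI", "HI", "HI"],
            index=[f"s{i}" for i in range(6)],
        )
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Saliva-shaped cohort (20 HI / 20 PI) with a planted 3-taxon panel."""
    spec = SyntheticSpec.saliva_like(
        planted_combo=PlantedCombo((100, 650, 1200)), seed=0
    )
    table, labels = generate_cohort(spec)
    return spec, table, labels


@pytest.fixture(scope="session")
def null_cohort_small():
    """Signal-free 20/20 cohort with 300 taxa (for search null checks)."""
    spec = SyntheticSpec.saliva_like(
        n_bacteria=200, n_fungi=20, n_virus=80, seed=123
    )
    table, labels = generate_cohort(spec)
    return table, labels


def random_table(rng, n_samples, n_taxa, zero_frac=0.2):
    values = rng.lognormal(mean=2.0, sigma=1.0, size=(n_samples, n_taxa))
    values[rng.random((n_samples, n_taxa)) < zero_frac] = 0.0
    # keep every row non-degenerate
    values[:, 0] += 1.0
    data = pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)],
    )
    return AbundanceTable(data)
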