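import numpy as np
import pandas as pd
import pytest

import reflectchip as rc


@pytest.fixture(scope="session")
def default_chip_sim():
    """Default-condition ChIP simulation (1000 genes, 5% bound, 3 reps)."""
    return rc.simulate_chip_arrays(rc.ChipSimConfig(seed=11))


@pytest.fixture(scope="session")
def default_chip_calls(default_chip_sim):
    """Probe tables + fitted null models for every replicate."""
    tables, models = {}, {}
    for r, tab in enumerate(default_chip_sim.intensities, start=1):
        table, model = rc.call_probes(tab)
        tables[f"rep{r}"] = table
        models[f"rep{r}"] = model
    return tables, models


@pytest.fixture(scope="session")
def null_chip_table():
    """A single null-only replicate (no enriched probes), ~28k probes."""
    sim = rc.simulate_chip_arrays(rc.ChipSimConfig(
        n_genes=2000, frac_enriched=0.0, n_replicates=1, seed=1))
    table, model = rc.call_probes(sim.intensities[0])
    return table, model


@pytest.fixture(scope="session")
def planted_seq_sim():
    """TAATTA planted in 80% of 200 length-450 sequences."""
    return rc.simulate_promoter_sequences(rc.SeqSimConfig(
        n_sequences=200, plant_fraction=0.8,
        planted_matrix=rc.taatta_matrix(), seed=3))


@pytest.fixture(scope="session")
def default_expr_sim():
    return rc.simulate_expression(rc.ExprSimConfig(seed=2))
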