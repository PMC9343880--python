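"""Shared fixtures: a small synthetic cohort reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from medito.classify import informative_filter
from medito.quantify import editing_efficiency
from medito.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_editing_truth,
    simulate_site_panel,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A 6-gene, 30-site cohort of 38 genotypes — fast but non-trivial."""
    return SimulationConfig(
        n_upland=20,
        n_lowland=18,
        n_genes=6,
        sites_per_gene=5,
        mean_depth=300.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """panel, truth, counts, metadata and per-condition editing matrices."""
    panel = simulate_site_panel(small_config)
    truth = simulate_editing_truth(panel, small_config)
    counts, meta = simulate_counts(truth, small_config)
    matrices = editing_efficiency(counts, meta, min_call_depth=50)
    return {
        "config": small_config,
        "panel": panel,
        "truth": truth,
        "counts": counts,
        "meta": meta,
        "matrices": matrices,
    }


@pytest.fixture(scope="session")
def ecotype_labels(small_dataset) -> pd.Series:
    meta = small_dataset["meta"]
    return meta.drop_duplicates("genotype").set_index("genotype")["ecotype"]


def make_matrix(values, genotypes=None, sites=None, condition="CK", depth=500):
    """Build an EditingMatrix from a plain array (NaN = missing)."""
    from medito.core import EditingMatrix

    vals = np.asarray(values, dtype=float)
    genotypes = genotypes or [f"g{i}" for i in range(vals.shape[0])]
    sites = sites or [f"s{j}" for j in range(vals.shape[1])]
    eff = pd.DataFrame(vals, index=genotypes, columns=sites)
    dep = pd.DataFrame(
        np.where(np.isfinite(vals), depth, 0), index=genotypes, columns=sites
    )
    return EditingMatrix(eff, dep, condition=condition)
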