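import warnings

import numpy as np
import pandas as pd
import pytest

from coexnet import (
    AnalysisMatrix,
    CountTable,
    NullModelConfig,
    SampleFrame,
    benchmark_spec,
    generate,
)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Domain warnings (dropped samples, Unknown taxa, ...) are expected in
    many tests; individual tests opt back in with pytest.warns."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def tiny_table():
    return CountTable(
        "16S",
        ["otu1", "otu2", "otu3"],
        ["s1", "s2"],
        np.array([[5.0, 0.0], [1.0, 2.0], [4.0, 8.0]]),
    )


@pytest.fixture
def small_frame():
    rows = []
    for loc, hab in (("BC", "terra-firme"), ("BC", "varzea"),
                     ("JAU", "campina"), ("CXN", "igapo")):
        for p in (1, 2):
            plot = f"{loc}-{hab}-p{p}"
            for sub in ("litter", "soil"):
                rows.append({
                    "sample_id": f"{plot}-{sub}", "plot_id": plot,
                    "locality": loc, "habitat": hab, "substrate": sub,
                    "pH": 4.0 + p / 10, "C": 2.0 + p / 5,
                })
    return SampleFrame(pd.DataFrame(rows), ["pH", "C"])


def matrix_from_table(table: CountTable) -> AnalysisMatrix:
    return AnalysisMatrix(
        list(table.otu_ids),
        np.array(["otu"] * len(table.otu_ids), dtype=object),
        table.counts,
        list(table.sample_ids),
    )


@pytest.fixture(scope="session")
def planted_small():
    """A small planted community plus a fast config, shared across tests."""
    spec = benchmark_spec(seed=11, n_modules=4, module_size=6,
                          n_exclusion_pairs=2)
    spec.n_background_otus = 40
    data = generate(spec)
    cfg = NullModelConfig(n_monte_carlo=10, n_perm=10, n_graph_null=30, seed=5)
    return data, cfg
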