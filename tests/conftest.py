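import warnings

import numpy as np
import pandas as pd
import pytest

from heatomics.design import default_design
from heatomics.simulate import SimRecipe, simulate_omics


@pytest.fixture(scope="session")
def heat35_design():
    return default_design(treatments=("heat35",))


@pytest.fixture(scope="session")
def small_omics(heat35_design):
    """One moderately sized simulated heat35 arm shared across tests."""
    recipe = SimRecipe(seed=42, n_genes=400, n_proteins=150)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_omics(recipe, heat35_design)


@pytest.fixture()
def toy_counts_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    pd.DataFrame(
        {"s1": [5, 7], "s2": [11, 13]}, index=pd.Index(["gA", "gB"], name="gene_id")
    ).to_csv(path, sep="\t")
    lengths = tmp_path / "lengths.tsv"
    pd.DataFrame({"gene_id": ["gA", "gB"], "length_bp": [1000, 2000]}).to_csv(
        lengths, sep="\t", index=False
    )
    return path, lengths
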