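import numpy as np
import pandas as pd
import pytest

from phyloniche import SimulationConfig, TraitTable, simulate_phylogeny
from phyloniche.io import tree_from_string


@pytest.fixture(scope="session")
def two_clade_tree():
    """40-tip ultrametric tree with a forced basal split into two clades."""
    cfg = SimulationConfig(n_species=40, n_deep_clades=2, seed=11)
    return simulate_phylogeny(cfg)


@pytest.fixture
def toy_traits():
    """3 species, 2 binary + 1 quantitative trait across two dimensions."""
    data = pd.DataFrame(
        {
            "hab_rock": [1, 0, 1],
            "hab_tree": [0, 0, 1],
            "svl": [45.0, 80.0, 62.5],
        },
        index=pd.Index(["sp_a", "sp_b", "sp_c"], name="species"),
    )
    meta = pd.DataFrame(
        {
            "type": ["binary", "binary", "quantitative"],
            "dimension": ["habitat", "habitat", "ecomorphology"],
        },
        index=pd.Index(["hab_rock", "hab_tree", "svl"], name="trait"),
    )
    return TraitTable(data, meta)


@pytest.fixture
def star_tree_8():
    labels = ",".join(f"t{i}:1" for i in range(1, 9))
    return tree_from_string(f"({labels});")


def random_trait_table(rng: np.random.Generator, n_species: int = 8) -> TraitTable:
    """Small random mixed-type table for fuzzing round trips and Gower."""
    species = [f"sp{i:02d}" for i in range(n_species)]
    dims = ["habitat", "trophic", "ecomorphology"]
    data, meta_rows = {}, []
    for d, dim in enumerate(dims):
        for j in range(int(rng.integers(1, 4))):
            name = f"{dim}_t{j}"
            if rng.random() < 0.5:
                data[name] = rng.integers(0, 2, n_species)
                kind = "binary"
            else:
                data[name] = np.round(rng.normal(size=n_species) * 10, 3)
                kind = "quantitative"
            meta_rows.append({"trait": name, "type": kind, "dimension": dim})
    return TraitTable(
        pd.DataFrame(data, index=pd.Index(species, name="species")),
        pd.DataFrame(meta_rows).set_index("trait"),
    )
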