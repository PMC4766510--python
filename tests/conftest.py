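import numpy as np
import pandas as pd
import pytest

from gamediv.cluster import functional_contributions, linkage_cluster
from gamediv.contributions import phylo_contributions
from gamediv.gower import gower_distance
from gamediv.simulate import SimConfig, simulate_traits, simulate_tree
from gamediv.traits import TraitTable, standardize_traits
from gamediv.trees import read_newick


@pytest.fixture
def small_tree():
    """The worked 3-species tree: ED {1.5, 1.5, 2.0}, T = 5."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_traits():
    """The worked Gower fixture: d(A,B)=0.25, d(A,C)=1.0, d(B,C)=0.75."""
    frame = pd.DataFrame(
        {"num": [1.0, 3.0, 5.0], "cat": ["g", "g", "b"]}, index=["A", "B", "C"]
    )
    return TraitTable(frame, {"num": "numeric", "cat": "categorical"})


@pytest.fixture
def small_distance(small_traits):
    return gower_distance(small_traits)


@pytest.fixture(scope="session")
def study_devs():
    """Contribution deviations for a fixed study-scale assemblage,
    shared by the simulation-heavy model tests."""
    cfg = SimConfig(seed=0)
    rng = np.random.default_rng(7)
    tree = simulate_tree(cfg.n_species, cfg.tree_depth, rng)
    contribs = phylo_contributions(tree)
    traits = simulate_traits(tree, cfg.n_numeric_traits, cfg.n_categorical_traits, rng)
    dend = linkage_cluster(gower_distance(standardize_traits(traits)), "upgma")
    fd, fc = functional_contributions(dend)
    # panels cover only the priced subset of the assemblage
    priced = tree.tip_labels[: cfg.n_priced]
    return {
        "config": cfg,
        "tree": tree,
        "ED": contribs["ED"].deviation.loc[priced],
        "PC": contribs["PC"].deviation.loc[priced],
        "FD": fd.deviation.loc[priced],
        "FC": fc.deviation.loc[priced],
    }


def attach_contributions(panel: pd.DataFrame, devs: dict) -> pd.DataFrame:
    out = panel.copy()
    for metric in ("ED", "PC", "FD", "FC"):
        if metric in devs:
            out[metric] = out["species"].map(devs[metric])
    return out
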