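import numpy as np
import pandas as pd
import pytest

from htnbiome import CohortConfig, generate_cohort
from htnbiome.profiles import CohortMetadata, TaxonomyTree, TaxonProfile


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort reused by read-only tests."""
    cfg = CohortConfig(n_control=20, n_phtn=15, n_htn=25, n_taxa=8,
                       genes_per_taxon=50, n_noise_genes=40, n_metabolites=20,
                       n_coupled_metabolites=6, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def toy_tree():
    """kingdom Bacteria > phylum > genus G with species X, Y; genus G2 with Z."""
    nodes = {
        "root": ("root", "root", "root"),
        "k1": ("root", "kingdom", "Bacteria"),
        "p1": ("k1", "phylum", "Bacteroidetes"),
        "g1": ("p1", "genus", "G"),
        "g2": ("p1", "genus", "G2"),
        "sX": ("g1", "species", "X"),
        "sY": ("g1", "species", "Y"),
        "sZ": ("g2", "species", "Z"),
    }
    return TaxonomyTree(nodes=nodes, root="root")


@pytest.fixture()
def tiny_metadata():
    groups = ["C"] * 6 + ["P"] * 4 + ["H"] * 6
    idx = [f"s{i}" for i in range(len(groups))]
    return CohortMetadata(pd.DataFrame({"group": groups}, index=idx))


def profile_from_array(arr, taxa=None, samples=None, **kw):
    arr = np.asarray(arr, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return TaxonProfile(pd.DataFrame(arr, index=taxa, columns=samples), **kw)
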