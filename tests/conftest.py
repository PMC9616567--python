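import numpy as np
import pandas as pd
import pytest

from envsel.sfs import GenotypePosteriors, SFSPair
from envsel.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    return SimConfig(
        seed=5,
        n_genes=40,
        n_cytosines_per_gene=60,
        n_individuals_per_group=4,
        n_sites_per_class={"synonymous": 50_000, "nonsynonymous": 50_000},
        n_te_insertions=60,
    )


def make_posteriors(probs, site_classes=None, populations=None, ancestral="A"):
    """GenotypePosteriors from a (sites, individuals, 3) array."""
    probs = np.asarray(probs, dtype=float)
    n_sites, n_ind, _ = probs.shape
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_sites + 1),
            "ref": "A",
            "alt": "T",
            "site_class": site_classes if site_classes is not None else "synonymous",
            "ancestral": ancestral,
        }
    )
    individuals = pd.DataFrame(
        {
            "individual": [f"i{j}" for j in range(n_ind)],
            "population": populations if populations is not None else "pop1",
        }
    )
    return GenotypePosteriors(sites=sites, individuals=individuals, probs=probs)


@pytest.fixture
def toy_sfs():
    return SFSPair(
        n=10,
        folded=False,
        xi_s=np.array([30.0, 14, 9, 6, 5, 4, 3, 2, 2]),
        xi_n=np.array([40.0, 12, 6, 4, 2, 2, 1, 1, 1]),
        l_s=1000.0,
        l_n=2000.0,
        d_s=50.0,
        d_n=20.0,
    )
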