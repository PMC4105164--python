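import numpy as np
import pytest

from plastcomp.genome_io import Feature, PlastomeRecord
from plastcomp.synthetic_data import (
    AncestorConfig,
    EvolutionConfig,
    evolve_along_tree,
    make_ancestor,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_ancestor():
    """~15 kb annotated quadripartite genome with planted SSRs and repeats."""
    cfg = AncestorConfig(
        lsc_len=8000, ssc_len=2000, ir_len=2500, seed=11,
        n_ssr_mono=8, n_ssr_hexa=1, n_repeats=4,
    )
    return make_ancestor(cfg)


@pytest.fixture(scope="session")
def small_study(small_ancestor):
    """Five tips evolved from the small ancestor, with truth tables."""
    rec, truth = small_ancestor
    tree = "((A:0.004,B:0.004):0.002,(C:0.005,D:0.005):0.001,E:0.008);"
    tips, truth = evolve_along_tree(
        rec, truth, EvolutionConfig(tree=tree, seed=12)
    )
    return rec, tips, truth, tree


@pytest.fixture()
def toy_record():
    """100 bp hand-written record with one gene at [9, 40)."""
    seq = "ACGT" * 25
    return PlastomeRecord(
        id="toy", sequence=seq, circular=True,
        features=[
            Feature("geneA", "gene", [(9, 40, "+")]),
            Feature("geneA", "CDS", [(9, 40, "+")]),
        ],
    )
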