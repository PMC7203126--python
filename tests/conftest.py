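import pytest

from bgcprof import GeneCatalog, GeneRecord, StrainSpec, default_config
from bgcprof.synthdata import BgcSpec


@pytest.fixture
def tiny_config():
    """100 genes on 4 contigs with two planted 5-gene BGCs."""
    return default_config(
        n_genes=100,
        n_contigs=4,
        bgc_specs=(BgcSpec(0, 5, 5, 2), BgcSpec(1, 10, 5, 0)),
        n_burden_genes=10,
        seed=11,
    )


@pytest.fixture
def tiny_catalog(tiny_config):
    from bgcprof import generate_genome

    return generate_genome(tiny_config)


@pytest.fixture
def strain_pair(tiny_catalog):
    reference = StrainSpec("reference", frozenset(), n_replicates=4)
    deletion = StrainSpec(
        "deletion", frozenset(tiny_catalog.bgc_ids()), n_replicates=3
    )
    return reference, deletion


@pytest.fixture
def handmade_catalog():
    """Six genes on two contigs, built by hand for exact-value tests."""
    genes = [
        GeneRecord("gA", "c1", 1, 1000, "+", "BGC01", True, frozenset({"secondary metabolism"})),
        GeneRecord("gB", "c1", 1500, 2499, "+", "BGC01", False, frozenset({"secondary metabolism"})),
        GeneRecord("gC", "c1", 3000, 4999, "-", None, False, frozenset({"transport"})),
        GeneRecord("gD", "c2", 1, 2500, "+", None, False, frozenset({"metabolism"})),
        GeneRecord("gE", "c2", 3000, 3999, "-", None, False, frozenset({"metabolism", "transport"})),
        GeneRecord("gActin", "c2", 5000, 6000, "+", None, False, frozenset({"cytoskeleton"}), True),
    ]
    return GeneCatalog(genes)
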