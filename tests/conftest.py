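import pytest

from qsspn.fixtures import (GeneExpressionParams, build_birth_death,
                            build_gene_expression_fixture, build_toy_metabolism)


@pytest.fixture(scope="session")
def gene_doc():
    return build_gene_expression_fixture()


@pytest.fixture(scope="session")
def gene_model(gene_doc):
    return gene_doc.model


@pytest.fixture(scope="session")
def toy_metabolism():
    return build_toy_metabolism()


@pytest.fixture(scope="session")
def birth_death_doc():
    return build_birth_death()


def feedback_cycle_order_ok(trajectory) -> bool:
    """One full negative-feedback cycle in the narrated order.

    Checks event *indices* (not times: immediates share a timestamp):
    mRNA reaches max, then Protein reaches max, then the agonist turns on,
    then mRNA decays to 0 before Protein does, and transcription recurs
    (mRNA reaches max again).
    """
    def first_index(place, tokens, start=0):
        for i, (_t, p, n, _src) in enumerate(trajectory.events[start:], start):
            if p == place and n == tokens:
                return i
        return None

    i_mrna2 = first_index("mRNA", 2)
    if i_mrna2 is None:
        return False
    i_prot2 = first_index("Protein", 2, i_mrna2)
    if i_prot2 is None:
        return False
    i_agonist = first_index("agonist", 1, i_prot2)
    if i_agonist is None:
        return False
    i_mrna0 = first_index("mRNA", 0, i_agonist)
    if i_mrna0 is None:
        return False
    i_prot0 = first_index("Protein", 0, i_mrna0)
    if i_prot0 is None:
        return False
    return first_index("mRNA", 2, i_prot0) is not None
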