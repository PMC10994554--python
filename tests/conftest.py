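import pytest

from stepenrich import EntityNode, PathwayDB, build_pathway


def _p(gene):
    return EntityNode.protein(gene)


@pytest.fixture
def fig_pathway():
    """Three-step pathway: a two-subunit complex, a two-member set, a solo
    protein — the canonical worked example (4 entities over 5 genes)."""
    return build_pathway(
        "fig1",
        "Three-step example pathway",
        [
            EntityNode.complex([_p("P3A"), _p("P3B")]),
            EntityNode.set_of([_p("P1"), _p("P2")]),
            _p("P4"),
        ],
    )


@pytest.fixture
def fig_db(fig_pathway):
    return PathwayDB.from_pathways([fig_pathway])


@pytest.fixture
def multi_db(fig_pathway):
    """A small multi-pathway database with overlapping and disjoint pathways."""
    other = build_pathway(
        "glyco",
        "Hexokinase toy pathway",
        [
            EntityNode.set_of([_p("GCK"), _p("HK1"), _p("HK2"), _p("HK3")]),
            _p("GPI"),
            _p("PFKM"),
        ],
    )
    shared = build_pathway(
        "shared",
        "Shares P4 with fig1",
        [_p("P4"), _p("Q1"), EntityNode.complex([_p("Q2"), _p("Q3")])],
    )
    return PathwayDB.from_pathways([fig_pathway, other, shared])
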