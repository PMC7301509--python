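import pytest

from meshsem import (
    FixtureSpec,
    FrequencyTable,
    MeSHDataset,
    MeSHTerm,
    MH,
    SCR,
    TreeNumber,
    build_ic_table,
    generate_fixture,
)


def build_manual(terms, n_total=1000, scrs=(), scr_broader=None, nonmesh=None):
    """Hand-built dataset from (ui, name, [tree numbers], count) rows.

    The parent/child table is derived from tree-number truncation so both
    hierarchy encodings agree, as in generated fixtures.
    """
    mhs = [
        MeSHTerm(
            ui=ui,
            name=name,
            record_kind=MH,
            tree_numbers=frozenset(TreeNumber(t) for t in tns),
            semantic_types=frozenset({"dsyn"}),
            cuis=frozenset({f"CU{ui}"}),
            pub_count=count,
        )
        for ui, name, tns, count in terms
    ]
    owner = {tn.text: t.ui for t in mhs for tn in t.tree_numbers}
    parent_child = set()
    for t in mhs:
        for tn in t.tree_numbers:
            parent = tn.parent()
            if parent is not None:
                parent_child.add((owner[parent.text], t.ui))
    scr_terms = [
        MeSHTerm(
            ui=ui, name=name, record_kind=SCR,
            semantic_types=frozenset({"dsyn"}), cuis=frozenset({f"CU{ui}"}),
        )
        for ui, name in scrs
    ]
    return MeSHDataset(
        main_headings=mhs,
        scrs=scr_terms,
        scr_broader={k: frozenset(v) for k, v in (scr_broader or {}).items()},
        parent_child=parent_child,
        n_total=n_total,
        nonmesh_concepts=nonmesh or {},
    )


@pytest.fixture(scope="session")
def ds_small():
    """Default-spec fixture: 2 categories, depth 4, branching 2 (30 MHs)."""
    return generate_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def ic_small(ds_small):
    return build_ic_table(ds_small, FrequencyTable.from_dataset(ds_small))


@pytest.fixture(scope="session")
def ds_large():
    """~240-MH fixture with multiple parents for oracle sweeps."""
    return generate_fixture(
        FixtureSpec(seed=3, n_categories=2, depth=5, branching=3,
                    multi_parent_rate=0.2, n_scrs=6)
    )


@pytest.fixture(scope="session")
def ic_large(ds_large):
    return build_ic_table(ds_large, FrequencyTable.from_dataset(ds_large))


@pytest.fixture(scope="session")
def ds_chain():
    """Exact-arithmetic dataset: root roll-up 500, leaves 100 and 200, N=1000.

    IC values are 0.30103 (root), 1.0 and 0.69897 — the inputs of the
    frozen Lin/JC/Schlicker expectations.
    """
    return build_manual(
        [
            ("D000100", "root alpha", ["C01"], 200),
            ("D000101", "leaf beta", ["C01.100"], 100),
            ("D000102", "leaf gamma", ["C01.200"], 200),
        ],
        n_total=1000,
    )


@pytest.fixture(scope="session")
def ds_two_categories():
    """The printed neurodegeneration/psychosis tree-number pair, with full
    prefix chains so every ancestor address is owned."""
    return build_manual(
        [
            ("D000200", "nervous system diseases", ["C10"], 500),
            ("D000201", "neurodegenerative diseases", ["C10.574"], 200),
            ("D000202", "tauopathies", ["C10.574.945"], 50),
            ("D000210", "mental disorders", ["F03"], 400),
            ("D000211", "psychotic disorders", ["F03.700"], 150),
            ("D000212", "schizophrenia", ["F03.700.750"], 80),
        ],
        n_total=2000,
    )
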