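"""Independent reference implementations used only by the tests.

These deliberately take a different route from the package: hierarchy
navigation goes through the parent/child table with networkx instead of
tree-number prefix arithmetic, and the similarity formulas are evaluated
directly from exhaustive ancestor enumerations.
"""

import math

import networkx as nx


def child_to_parent_graph(ds) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(t.ui for t in ds.main_headings)
    for parent, child in ds.parent_child:
        g.add_edge(child, parent)
    return g


def parent_to_child_graph(ds) -> nx.DiGraph:
    return child_to_parent_graph(ds).reverse()


def inclusive_ancestors_oracle(ds, ui) -> set:
    g = child_to_parent_graph(ds)
    return nx.descendants(g, ui) | {ui}


def descendant_closure_oracle(ds, ui) -> set:
    g = parent_to_child_graph(ds)
    return nx.descendants(g, ui) | {ui}


def ic_oracle(ds, ui, ft) -> float:
    freq = sum(ft.counts.get(u, 0) for u in descendant_closure_oracle(ds, ui))
    return -math.log10(max(freq, 1) / ft.n_total)


def categories_disjoint_oracle(ds, ui1, ui2) -> bool:
    c1 = {tn.category for tn in ds.get_term(ui1).tree_numbers}
    c2 = {tn.category for tn in ds.get_term(ui2).tree_numbers}
    return not (c1 & c2)


def mica_ic_oracle(ds, ic_table, ui1, ui2) -> float:
    if categories_disjoint_oracle(ds, ui1, ui2):
        return 0.0
    common = inclusive_ancestors_oracle(ds, ui1) & inclusive_ancestors_oracle(ds, ui2)
    if not common:
        return 0.0
    return max(ic_table.ic.get(u, 0.0) for u in common)


def lin_oracle(ds, ic_table, ui1, ui2) -> float:
    if categories_disjoint_oracle(ds, ui1, ui2):
        return 0.0
    m = mica_ic_oracle(ds, ic_table, ui1, ui2)
    denom = ic_table.ic[ui1] + ic_table.ic[ui2]
    if denom == 0.0:
        return 1.0 if ui1 == ui2 else 0.0
    return 2.0 * m / denom


def jc_oracle(ds, ic_table, ui1, ui2) -> float:
    if categories_disjoint_oracle(ds, ui1, ui2):
        return 0.0
    m = mica_ic_oracle(ds, ic_table, ui1, ui2)
    return 1.0 - min(1.0, ic_table.ic[ui1] + ic_table.ic[ui2] - 2.0 * m)


def rel_oracle(ds, ic_table, ui1, ui2) -> float:
    m = mica_ic_oracle(ds, ic_table, ui1, ui2)
    return lin_oracle(ds, ic_table, ui1, ui2) * (1.0 - 10.0 ** (-m))


def wang_s_oracle(ds, ui, omega) -> dict:
    """Semantic contributions via shortest parent-link paths (BFS)."""
    g = child_to_parent_graph(ds)
    dist = nx.single_source_shortest_path_length(g, ui)
    return {u: omega ** n for u, n in dist.items()}


def wang_oracle(ds, ui1, ui2, omega) -> float:
    if categories_disjoint_oracle(ds, ui1, ui2):
        return 0.0
    s1 = wang_s_oracle(ds, ui1, omega)
    s2 = wang_s_oracle(ds, ui2, omega)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    return sum(s1[t] + s2[t] for t in common) / (sum(s1.values()) + sum(s2.values()))
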