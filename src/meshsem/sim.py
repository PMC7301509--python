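"""Semantic similarity between MeSH terms.

Four information-content measures and one graph measure are provided.
With ``m = IC(MICA(d1, d2))``, the IC of the most informative common
ancestor under the inclusive convention (every term is its own ancestor):

    res(d1, d2) = m
    lin(d1, d2) = 2 m / (IC(d1) + IC(d2))
    jc (d1, d2) = 1 - min(1, IC(d1) + IC(d2) - 2 m)
    rel(d1, d2) = lin(d1, d2) * (1 - 10^(-m))

The graph measure assigns every inclusive ancestor ``a`` of ``d`` a
semantic contribution S_d(a) = omega^(n_a), where n_a is the minimum edge
count from ``d`` to ``a`` over all tree-number paths, and compares two
terms by the contributions of their shared ancestors:

    wang(d1, d2) = sum_{t in A(d1) ∩ A(d2)} (S_d1(t) + S_d2(t)) / (SV_d1 + SV_d2)

Two rules from the MeSH setting apply everywhere: terms whose category
sets (first letters of tree numbers) are disjoint have similarity exactly
0 under every measure, and when multiple tree numbers yield multiple
values only the maximal one is retained.  SCR endpoints are replaced by
their broader main headings before any measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable

from .dataset import MeSHDataset
from .errors import MeshSemError
from .ic import ICTable
from .tree import TreeNumber

METHODS = ("res", "lin", "jc", "rel", "wang")

DEFAULT_OMEGA = 0.6


@dataclass(frozen=True)
class MICAResult:
    """Most informative common ancestor of two main headings.

    ``mica_ui`` is ``None`` (and ``mica_ic`` 0) when the two terms share no
    category or no common ancestor.
    """

    mica_ui: str | None
    mica_ic: float


@dataclass(frozen=True)
class SimilarityRequest:
    """A similarity query between two MeSH ids (MH or SCR)."""

    ui1: str
    ui2: str
    method: str = "lin"
    omega: float = DEFAULT_OMEGA

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")


def inclusive_ancestors(
    ds: MeSHDataset, ui: str, tree_numbers: Iterable[TreeNumber] | None = None
) -> frozenset[str]:
    """Ancestor MH ids of ``ui`` including ``ui`` itself.

    ``tree_numbers`` restricts the ancestor set to the chains of the given
    addresses (used by the per-tree-number maximal-similarity rule).
    """
    term = ds.get_term(ui)
    tns = term.tree_numbers if tree_numbers is None else frozenset(tree_numbers)
    out = {ui}
    for tn in tns:
        for anc in tn.ancestors():
            out.add(ds.owner_of(anc))
    return frozenset(out)


def _categories_disjoint(ds: MeSHDataset, ui1: str, ui2: str) -> bool:
    return not (ds.get_term(ui1).categories & ds.get_term(ui2).categories)


def mica(ds: MeSHDataset, ic_table: ICTable, ui1: str, ui2: str) -> MICAResult:
    """Most informative common ancestor of two main headings.

    Cross-category pairs have no MICA by definition; otherwise the common
    inclusive ancestor with maximal IC is returned, ties broken by the
    lexicographically smaller id.
    """
    if _categories_disjoint(ds, ui1, ui2):
        return MICAResult(None, 0.0)
    common = inclusive_ancestors(ds, ui1) & inclusive_ancestors(ds, ui2)
    if not common:
        return MICAResult(None, 0.0)
    best = min(common, key=lambda u: (-ic_table.ic.get(u, 0.0), u))
    return MICAResult(best, ic_table.ic.get(best, 0.0))


def sim_resnik(ds: MeSHDataset, ic_table: ICTable, ui1: str, ui2: str) -> float:
    """IC of the MICA; 0 across categories; unbounded above."""
    return mica(ds, ic_table, ui1, ui2).mica_ic


def sim_lin(ds: MeSHDataset, ic_table: ICTable, ui1: str, ui2: str) -> float:
    if _categories_disjoint(ds, ui1, ui2):
        return 0.0
    m = mica(ds, ic_table, ui1, ui2).mica_ic
    denom = ic_table.ic.get(ui1, 0.0) + ic_table.ic.get(ui2, 0.0)
    if denom == 0.0:
        # two ICs of zero: identical terms are perfectly similar, distinct
        # uninformative terms carry no shared information
        return 1.0 if ui1 == ui2 else 0.0
    return 2.0 * m / denom


def sim_jc(ds: MeSHDataset, ic_table: ICTable, ui1: str, ui2: str) -> float:
    """Jiang-Conrath distance folded into [0, 1]; 0 across categories."""
    if _categories_disjoint(ds, ui1, ui2):
        return 0.0
    m = mica(ds, ic_table, ui1, ui2).mica_ic
    dist = ic_table.ic.get(ui1, 0.0) + ic_table.ic.get(ui2, 0.0) - 2.0 * m
    return 1.0 - min(1.0, dist)


def sim_rel(ds: MeSHDataset, ic_table: ICTable, ui1: str, ui2: str) -> float:
    """Schlicker relevance: Lin damped by (1 - P(MICA))."""
    if _categories_disjoint(ds, ui1, ui2):
        return 0.0
    m = mica(ds, ic_table, ui1, ui2).mica_ic
    return sim_lin(ds, ic_table, ui1, ui2) * (1.0 - 10.0 ** (-m))


def wang_s_values(
    ds: MeSHDataset,
    ui: str,
    omega: float = DEFAULT_OMEGA,
    tree_numbers: Iterable[TreeNumber] | None = None,
) -> dict[str, float]:
    """Semantic contribution S_d(a) = omega^(n_a) for every inclusive ancestor.

    ``n_a`` is the minimum number of edges from ``d`` to ``a`` over all
    tree-number chains (0 for the term itself, so S_d(d) = 1 for any
    omega).  ``tree_numbers`` restricts the chains considered.
    """
    term = ds.get_term(ui)
    tns = term.tree_numbers if tree_numbers is None else frozenset(tree_numbers)
    dist: dict[str, int] = {ui: 0}
    for tn in tns:
        for n_edges, anc in enumerate(tn.ancestors(), start=1):
            owner = ds.owner_of(anc)
            if n_edges < dist.get(owner, n_edges + 1):
                dist[owner] = n_edges
    return {u: omega ** n for u, n in dist.items()}


def sim_wang(
    ds: MeSHDataset,
    ui1: str,
    ui2: str,
    omega: float = DEFAULT_OMEGA,
    tree_numbers1: Iterable[TreeNumber] | None = None,
    tree_numbers2: Iterable[TreeNumber] | None = None,
) -> float:
    if _categories_disjoint(ds, ui1, ui2):
        return 0.0
    s1 = wang_s_values(ds, ui1, omega, tree_numbers1)
    s2 = wang_s_values(ds, ui2, omega, tree_numbers2)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    num = sum(s1[t] + s2[t] for t in common)
    denom = sum(s1.values()) + sum(s2.values())
    return num / denom


_IC_METHODS = {"res": sim_resnik, "lin": sim_lin, "jc": sim_jc, "rel": sim_rel}


def _mh_pair_similarity(
    ds: MeSHDataset, ic_table: ICTable | None, ui1: str, ui2: str,
    method: str, omega: float,
) -> float:
    """One main-heading pair under the maximal-similarity rule.

    An identical pair scores exactly 1 under every measure (the identity
    boundary of the measurement model; the raw Resnik and Schlicker
    formulas alone would not reach 1).
    """
    if ui1 == ui2:
        return 1.0
    if _categories_disjoint(ds, ui1, ui2):
        return 0.0
    if method == "wang":
        # Wang scores depend on the whole ancestor chain, so the maximal-
        # similarity rule enumerates tree-number pairs explicitly.
        best = 0.0
        for tn1, tn2 in product(
            sorted(ds.get_term(ui1).tree_numbers),
            sorted(ds.get_term(ui2).tree_numbers),
        ):
            best = max(
                best, sim_wang(ds, ui1, ui2, omega, (tn1,), (tn2,))
            )
        return best
    if ic_table is None:
        raise MeshSemError(f"method {method!r} requires an IC table")
    # For the IC measures the per-tree-number maximum coincides with the
    # global MICA: every common ancestor lies on some chain pair and all
    # four formulas are monotone in IC(MICA).
    return _IC_METHODS[method](ds, ic_table, ui1, ui2)


def similarity(
    ds: MeSHDataset,
    ic_table: ICTable | None,
    request: SimilarityRequest | None = None,
    *,
    ui1: str | None = None,
    ui2: str | None = None,
    method: str = "lin",
    omega: float = DEFAULT_OMEGA,
) -> float:
    """Similarity between two MeSH ids, each an MH or an SCR.

    SCR endpoints are replaced by their broader main headings and the
    maximum over all resulting MH pairs is returned, making the operation
    symmetric and well defined for rare-disease records that carry no tree
    number of their own.
    """
    if request is None:
        if ui1 is None or ui2 is None:
            raise TypeError("similarity() needs a SimilarityRequest or ui1/ui2")
        request = SimilarityRequest(ui1=ui1, ui2=ui2, method=method, omega=omega)

    def endpoints(ui: str) -> frozenset[str]:
        term = ds.get_term(ui)
        return frozenset({ui}) if term.is_mh else ds.scr_broader_mhs(ui)

    best = 0.0
    for a, b in product(sorted(endpoints(request.ui1)), sorted(endpoints(request.ui2))):
        best = max(
            best,
            _mh_pair_similarity(ds, ic_table, a, b, request.method, request.omega),
        )
    return best
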