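"""Deterministic synthetic MeSH-like vocabularies.

The generator builds, per category, a rooted tree of main headings of a
given depth and branching factor, then optionally rewires some nodes to a
second (strictly shallower, same-category) parent, turning the tree into a
DAG.  Tree numbers are derived from the DAG exactly as MeSH derives them:
every node carries one dotted address per path from its category root, each
address extending one parent address by the node's own 3-digit component.
The parent/child table and the tree numbers therefore encode the same
hierarchy by construction.

SCRs are attached to one or two broader MHs, a few non-MeSH-synonymous
UMLS concepts embed an MH name (exercising the recognizer's recursive
route), and per-term publication counts follow a capped Zipf law (many
rarely indexed terms, a few heavily indexed ones).  The total publication
count N defaults to the sum of all per-term counts, which keeps every
term's occurrence probability below 1 — hence strictly positive
information content — whenever more than one category carries counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import MeSHDataset, MeSHTerm, MH, SCR
from .errors import InfeasibleSpecError
from .tree import TreeNumber

_CATEGORY_LETTERS = "CFADBEGHIJKLMN"

_ADJECTIVES = (
    "acute", "chronic", "familial", "juvenile", "congenital", "idiopathic",
    "recurrent", "primary", "secondary", "atypical", "benign", "diffuse",
    "spastic", "systemic", "focal", "progressive",
)
_NOUNS = (
    "neuropathy", "dermatitis", "anemia", "carcinoma", "dysplasia",
    "fibrosis", "myopathy", "arthritis", "encephalitis", "nephropathy",
    "sclerosis", "palsy", "psychosis", "amaurosis", "ataxia", "dystonia",
)

#: semantic types drawn for fixture terms; all belong to the default
#: disease-related recognizer filter so fixtures survive default filtering.
_SEMANTIC_TYPE_POOL = ("dsyn", "neop", "fndg", "sosy", "patf", "mobd", "anab", "acab")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic vocabulary.

    ``depth`` counts levels including the category root, so one category
    with ``depth=3, branching=2`` holds 1+2+4 = 7 main headings.
    ``multi_parent_rate`` is the probability that a non-root node gains one
    extra parent; ``n_total`` overrides the default total publication count
    (sum of per-term counts).
    """

    seed: int = 0
    n_categories: int = 2
    depth: int = 4
    branching: int = 2
    n_scrs: int = 4
    n_nonmesh: int = 2
    multi_parent_rate: float = 0.1
    extra_cui_rate: float = 0.3
    count_exponent: float = 2.0
    count_cap: int = 10_000
    n_total: int | None = None

    def validate(self) -> None:
        if self.n_categories < 1 or self.n_categories > len(_CATEGORY_LETTERS):
            raise InfeasibleSpecError(
                f"n_categories must be in [1, {len(_CATEGORY_LETTERS)}]"
            )
        if self.depth < 1:
            raise InfeasibleSpecError("depth must be >= 1")
        if self.branching < 1 and self.depth > 1:
            raise InfeasibleSpecError("branching 0 is infeasible with depth > 1")
        for rate in (self.multi_parent_rate, self.extra_cui_rate):
            if not 0.0 <= rate <= 1.0:
                raise InfeasibleSpecError("rates must lie in [0, 1]")
        if min(self.n_scrs, self.n_nonmesh, self.count_cap) < 0:
            raise InfeasibleSpecError("counts must be non-negative")
        if self.count_exponent <= 1.0:
            raise InfeasibleSpecError("count_exponent must exceed 1")


def _draw_count(rng: np.random.Generator, spec: FixtureSpec) -> int:
    return int(min(spec.count_cap, rng.zipf(spec.count_exponent)))


def _name(rng: np.random.Generator, idx: int, suffix: str = "") -> str:
    adj = _ADJECTIVES[int(rng.integers(len(_ADJECTIVES)))]
    noun = _NOUNS[int(rng.integers(len(_NOUNS)))]
    return f"{adj} {noun}{suffix} {idx:03d}"


def _draw_semantic_types(rng: np.random.Generator) -> frozenset[str]:
    k = 1 + int(rng.random() < 0.5)
    picks = rng.choice(len(_SEMANTIC_TYPE_POOL), size=k, replace=False)
    return frozenset(_SEMANTIC_TYPE_POOL[int(i)] for i in picks)


def generate_fixture(spec: FixtureSpec) -> MeSHDataset:
    """Build a synthetic dataset; byte-identical tables for equal specs."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # --- main-heading DAG -------------------------------------------------
    # node records: index (1-based, also the 3-digit component), category,
    # level, parents (node indices)
    nodes: list[dict] = []

    def add_node(category: str, level: int, parents: list[int]) -> int:
        idx = len(nodes) + 1
        if idx > 999:
            raise InfeasibleSpecError("fixture exceeds 999 main headings")
        nodes.append({"idx": idx, "category": category, "level": level,
                      "parents": list(parents)})
        return idx

    for c in range(spec.n_categories):
        letter = _CATEGORY_LETTERS[c]
        root = add_node(letter, 1, [])
        frontier = [root]
        for level in range(2, spec.depth + 1):
            frontier = [
                add_node(letter, level, [p])
                for p in frontier
                for _ in range(spec.branching)
            ]

    # extra parents: strictly shallower, same category, not already a parent
    for node in nodes:
        if node["level"] < 2 or rng.random() >= spec.multi_parent_rate:
            continue
        candidates = [
            m["idx"] for m in nodes
            if m["category"] == node["category"]
            and m["level"] < node["level"]
            and m["idx"] not in node["parents"]
        ]
        if candidates:
            node["parents"].append(int(rng.choice(candidates)))

    # tree numbers by DAG closure: one address per path from the root
    tns: dict[int, set[str]] = {}
    roots_seen: dict[str, int] = {}
    for node in nodes:  # creation order is topological in level
        if not node["parents"]:
            roots_seen[node["category"]] = roots_seen.get(node["category"], 0) + 1
            tns[node["idx"]] = {f"{node['category']}{roots_seen[node['category']]:02d}"}
        else:
            tns[node["idx"]] = {
                f"{t}.{node['idx']:03d}"
                for p in node["parents"]
                for t in tns[p]
            }

    def mh_ui(idx: int) -> str:
        return f"D{idx:06d}"

    main_headings = []
    for node in nodes:
        idx = node["idx"]
        cuis = {f"C{1_000_000 + idx:07d}"}
        if idx == 1 or rng.random() < spec.extra_cui_rate:
            cuis.add(f"C{2_000_000 + idx:07d}")  # many-to-one CUI -> MH
        main_headings.append(
            MeSHTerm(
                ui=mh_ui(idx),
                name=_name(rng, idx),
                record_kind=MH,
                tree_numbers=frozenset(TreeNumber(t) for t in tns[idx]),
                semantic_types=_draw_semantic_types(rng),
                cuis=frozenset(cuis),
                pub_count=_draw_count(rng, spec),
            )
        )
    parent_child = [
        (mh_ui(p), mh_ui(node["idx"])) for node in nodes for p in node["parents"]
    ]

    # --- SCRs -------------------------------------------------------------
    scrs, scr_broader = [], {}
    n_mh = len(nodes)
    for i in range(1, spec.n_scrs + 1):
        ui = f"C{500_000 + i:06d}"
        # first SCR gets exactly one broader MH, second exactly two (when
        # possible); the rest draw 1-2 at random
        if i == 1 or n_mh < 2:
            k = 1
        elif i == 2:
            k = 2
        else:
            k = 1 + int(rng.random() < 0.3)
        picks = rng.choice(n_mh, size=k, replace=False)
        scr_broader[ui] = frozenset(mh_ui(int(p) + 1) for p in picks)
        scrs.append(
            MeSHTerm(
                ui=ui,
                name=_name(rng, i, suffix=" variant"),
                record_kind=SCR,
                semantic_types=_draw_semantic_types(rng),
                cuis=frozenset({f"C{3_000_000 + i:07d}"}),
                pub_count=None,
            )
        )

    # --- non-MeSH-synonymous concepts ------------------------------------
    nonmesh: dict[str, str] = {}
    for i in range(1, spec.n_nonmesh + 1):
        host = main_headings[int(rng.integers(n_mh))]
        nonmesh[f"C{4_000_000 + i:07d}"] = f"hereditary {host.name}"

    n_total = spec.n_total
    if n_total is None:
        n_total = sum(t.pub_count for t in main_headings)

    return MeSHDataset(
        main_headings=main_headings,
        scrs=scrs,
        scr_broader=scr_broader,
        parent_child=parent_child,
        n_total=n_total,
        nonmesh_concepts=nonmesh,
    )
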