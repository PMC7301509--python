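"""In-memory data model for the five-table MeSH dataset.

The model holds MeSH main headings (MHs, the principal descriptor component,
each carrying one or more tree numbers) and supplementary concept records
(SCRs, tree-number-less records for specific substances and rare diseases,
linked to MHs through narrower/broader relations), together with the
many-to-one mapping from UMLS concept ids (CUIs) to MeSH ids and the
parent/child relation between MHs.  Qualifier records, MeSH concepts and
entry terms are deliberately out of the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .errors import (
    DatasetIntegrityError,
    NotAMainHeadingError,
    NotAnSCRError,
    NoMeshMappingError,
    UnknownTermError,
)
from .tree import TreeNumber

MH = "MH"
SCR = "SCR"


@dataclass(frozen=True)
class MeSHTerm:
    """One MeSH main heading or supplementary concept record.

    ``tree_numbers`` is non-empty exactly for MHs; ``categories`` of an MH is
    the set of first letters of its tree numbers (an SCR inherits categories
    from its broader MHs, which requires the dataset — see
    :meth:`MeSHDataset.categories_of`).  ``pub_count`` is the number of
    publications indexed directly by this term, ``None`` when unknown.
    """

    ui: str
    name: str
    record_kind: str  # MH or SCR
    tree_numbers: frozenset[TreeNumber] = frozenset()
    semantic_types: frozenset[str] = frozenset()
    cuis: frozenset[str] = frozenset()
    pub_count: int | None = None

    def __post_init__(self) -> None:
        if self.record_kind not in (MH, SCR):
            raise ValueError(f"record_kind must be {MH!r} or {SCR!r}, got {self.record_kind!r}")
        if self.record_kind == MH and not self.tree_numbers:
            raise DatasetIntegrityError(f"main heading {self.ui} has no tree numbers")
        if self.record_kind == SCR and self.tree_numbers:
            raise DatasetIntegrityError(f"SCR {self.ui} must not carry tree numbers")
        if not self.cuis:
            raise DatasetIntegrityError(f"term {self.ui} maps to no UMLS concept")
        if self.pub_count is not None and self.pub_count < 0:
            raise DatasetIntegrityError(f"term {self.ui} has negative publication count")

    @property
    def is_mh(self) -> bool:
        return self.record_kind == MH

    @property
    def categories(self) -> frozenset[str]:
        """Category letters of an MH; empty for an SCR (use the dataset)."""
        return frozenset(tn.category for tn in self.tree_numbers)


class MeSHDataset:
    """The five tables plus lookup indexes.

    Construction validates the structural invariants: every SCR resolves to
    at least one existing broader MH, every CUI maps to exactly one stored
    term, and every tree number is owned by exactly one MH.
    """

    def __init__(
        self,
        main_headings: Iterable[MeSHTerm],
        scrs: Iterable[MeSHTerm] = (),
        scr_broader: dict[str, frozenset[str]] | None = None,
        parent_child: Iterable[tuple[str, str]] = (),
        n_total: int = 0,
        nonmesh_concepts: dict[str, str] | None = None,
    ):
        self._terms: dict[str, MeSHTerm] = {}
        for t in main_headings:
            if not t.is_mh:
                raise DatasetIntegrityError(f"{t.ui} passed as MH but is {t.record_kind}")
            self._add(t)
        for t in scrs:
            if t.is_mh:
                raise DatasetIntegrityError(f"{t.ui} passed as SCR but is {t.record_kind}")
            self._add(t)

        self.scr_broader: dict[str, frozenset[str]] = {
            k: frozenset(v) for k, v in (scr_broader or {}).items()
        }
        self.parent_child: frozenset[tuple[str, str]] = frozenset(parent_child)
        self.n_total = int(n_total)
        #: non-MeSH-synonymous UMLS concepts (cui -> preferred name); used by
        #: the recognizer's recursive route, not one of the five core tables.
        self.nonmesh_concepts: dict[str, str] = dict(nonmesh_concepts or {})

        self._build_indexes()
        self._validate()

    # ------------------------------------------------------------------ setup

    def _add(self, term: MeSHTerm) -> None:
        if term.ui in self._terms:
            raise DatasetIntegrityError(f"duplicate MeSH id {term.ui}")
        self._terms[term.ui] = term

    def _build_indexes(self) -> None:
        self.concept_map: dict[str, str] = {}
        self._tn_owner: dict[str, str] = {}
        self._name_index: dict[str, str] = {}
        for term in self._terms.values():
            for cui in term.cuis:
                prev = self.concept_map.get(cui)
                if prev is not None and prev != term.ui:
                    raise DatasetIntegrityError(
                        f"CUI {cui} maps to both {prev} and {term.ui}"
                    )
                self.concept_map[cui] = term.ui
            for tn in term.tree_numbers:
                prev = self._tn_owner.get(tn.text)
                if prev is not None and prev != term.ui:
                    raise DatasetIntegrityError(
                        f"tree number {tn.text} owned by both {prev} and {term.ui}"
                    )
                self._tn_owner[tn.text] = term.ui
            # names: case-insensitive, last writer loses to keep determinism
            key = term.name.casefold()
            if key not in self._name_index or term.ui < self._name_index[key]:
                self._name_index[key] = term.ui

    def _validate(self) -> None:
        for scr_ui, broader in self.scr_broader.items():
            scr = self._terms.get(scr_ui)
            if scr is None or scr.is_mh:
                raise DatasetIntegrityError(f"broader relation names non-SCR id {scr_ui}")
            if not broader:
                raise DatasetIntegrityError(f"SCR {scr_ui} has an empty broader set")
            for mh_ui in broader:
                mh = self._terms.get(mh_ui)
                if mh is None or not mh.is_mh:
                    raise DatasetIntegrityError(
                        f"SCR {scr_ui} broader link targets non-MH id {mh_ui}"
                    )
        for scr_ui, scr in self._terms.items():
            if not scr.is_mh and scr_ui not in self.scr_broader:
                raise DatasetIntegrityError(f"SCR {scr_ui} has no broader main heading")
        for parent, child in self.parent_child:
            for ui in (parent, child):
                t = self._terms.get(ui)
                if t is None or not t.is_mh:
                    raise DatasetIntegrityError(
                        f"parent/child pair ({parent}, {child}) names non-MH id {ui}"
                    )
        for cui in self.nonmesh_concepts:
            if cui in self.concept_map:
                raise DatasetIntegrityError(
                    f"CUI {cui} listed as non-MeSH but mapped to {self.concept_map[cui]}"
                )

    # ------------------------------------------------------------- inspection

    @property
    def main_headings(self) -> list[MeSHTerm]:
        return [t for t in self._terms.values() if t.is_mh]

    @property
    def scrs(self) -> list[MeSHTerm]:
        return [t for t in self._terms.values() if not t.is_mh]

    def terms(self) -> Iterator[MeSHTerm]:
        return iter(self._terms.values())

    def __contains__(self, ui: str) -> bool:
        return ui in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    # -------------------------------------------------------------- operations

    def get_term(self, ui: str) -> MeSHTerm:
        """Look up a term by MeSH unique id (case-sensitive)."""
        try:
            return self._terms[ui]
        except KeyError:
            raise UnknownTermError(ui) from None

    def term_by_name(self, name: str) -> MeSHTerm:
        """Look up a term by preferred name (case-insensitive)."""
        ui = self._name_index.get(name.casefold())
        if ui is None:
            raise UnknownTermError(name)
        return self._terms[ui]

    def umls_to_mesh(self, cui: str) -> MeSHTerm:
        """Resolve a UMLS concept id to its MeSH term.

        Several CUIs may map to one MH; each MeSH-synonymous SCR CUI maps
        one-to-one.  Raises :class:`NoMeshMappingError` for concepts with no
        MeSH mapping (callers may fall back to the recognizer's recursive
        route).
        """
        ui = self.concept_map.get(cui)
        if ui is None:
            raise NoMeshMappingError(cui)
        return self._terms[ui]

    def scr_broader_mhs(self, scr_ui: str) -> frozenset[str]:
        """Broader main headings of an SCR (always non-empty)."""
        term = self.get_term(scr_ui)
        if term.is_mh:
            raise NotAnSCRError(f"{scr_ui} is a main heading, not an SCR")
        broader = self.scr_broader.get(scr_ui, frozenset())
        if not broader:  # _validate makes this unreachable for loaded datasets
            raise DatasetIntegrityError(f"SCR {scr_ui} has no broader main heading")
        return broader

    def owner_of(self, tn: TreeNumber | str) -> str:
        """The MH ui owning a tree number address."""
        text = tn.text if isinstance(tn, TreeNumber) else tn
        ui = self._tn_owner.get(text)
        if ui is None:
            raise DatasetIntegrityError(f"no main heading owns tree number {text}")
        return ui

    def ancestor_terms(self, ui: str) -> frozenset[str]:
        """MH ids owning any proper prefix of any tree number of ``ui``.

        Excludes ``ui`` itself even when distinct tree numbers of the term
        are prefixes of each other.
        """
        term = self.get_term(ui)
        if not term.is_mh:
            raise NotAMainHeadingError(f"{ui} is an SCR; ancestors are defined for MHs")
        out: set[str] = set()
        for tn in term.tree_numbers:
            for anc in tn.ancestors():
                out.add(self.owner_of(anc))
        out.discard(ui)
        return frozenset(out)

    def descendant_terms(self, ui: str, include_self: bool = True) -> frozenset[str]:
        """MH ids owning a proper dotted extension of any tree number of ``ui``."""
        term = self.get_term(ui)
        if not term.is_mh:
            raise NotAMainHeadingError(f"{ui} is an SCR; descendants are defined for MHs")
        prefixes = [tn.text + "." for tn in term.tree_numbers]
        out = {
            owner
            for text, owner in self._tn_owner.items()
            if any(text.startswith(p) for p in prefixes)
        }
        if include_self:
            out.add(ui)
        else:
            out.discard(ui)
        return frozenset(out)

    def categories_of(self, ui: str) -> frozenset[str]:
        """Category letters of a term.

        For an MH these are the first characters of its tree numbers; an SCR
        has no tree number, so it inherits the union of its broader MHs'
        categories.
        """
        term = self.get_term(ui)
        if term.is_mh:
            return term.categories
        cats: set[str] = set()
        for mh_ui in self.scr_broader_mhs(ui):
            cats.update(self._terms[mh_ui].categories)
        return frozenset(cats)
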