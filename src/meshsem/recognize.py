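"""Dictionary-based recognition of MeSH terms in free biomedical text.

Phrases are normalized (case folding, apostrophe/backtick stripping,
punctuation removal, whitespace collapse) and scanned greedily left to
right for the longest window of tokens matching a stored preferred name.
Matches resolve to main headings (route ``direct``) or supplementary
concept records (route ``scr``); SCR hits can additionally be expanded to
their broader main headings (route ``scr_expanded``).  Names of
non-MeSH-synonymous UMLS concepts known to the dataset are re-submitted as
free text up to a recursion depth limit (route ``recursive``).

An adapter for MetaMap fielded (MMI) output is included: the external NLP
engine itself is not required — only its documented pipe-delimited machine
output format is parsed and resolved against the dataset.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Iterator

from .dataset import MeSHDataset, MeSHTerm, SCR
from .errors import NoMeshMappingError

logger = logging.getLogger(__name__)

#: Disease-related UMLS semantic-type codes used as the default filter for
#: recognition (the 33 types covering disorders, findings, anatomy and
#: physiologic function relevant to phenotype curation).
DISEASE_SEMANTIC_TYPES = frozenset(
    "inpo dsyn phpr anab orgf clna hlca genf orga neop emod inbe lbtr anst "
    "npop celc cell bpoc acty mobd celf evnt sosy patf tisu moft fndg bdsu "
    "ortf menp acab comd sbst cgab".split()
)

ROUTE_DIRECT = "direct"
ROUTE_SCR = "scr"
ROUTE_SCR_EXPANDED = "scr_expanded"
ROUTE_RECURSIVE = "recursive"

_APOSTROPHES = "'’‘ʼ`´"
_POSSESSIVE_RE = re.compile(rf"(\w)[{_APOSTROPHES}]s(?=\W|$)")
_APOSTROPHE_RE = re.compile(f"[{_APOSTROPHES}]")
_PUNCT_RE = re.compile(r"[^\w\s]|_")
_WS_RE = re.compile(r"\s+")
_TOKEN_RE = re.compile(r"\S+")


@dataclass(frozen=True)
class MeSHAnnotation:
    """One recognized span of text resolved to a MeSH term."""

    source_text: str
    span: tuple[int, int]  # 0-based, half-open character offsets
    cui: str | None
    mesh_ui: str
    mesh_name: str
    record_kind: str
    route: str
    score: float = 1.0


@dataclass(frozen=True)
class RecognizerConfig:
    """Recognition options.

    The default semantic-type filter is the disease-related list; an empty
    filter accepts every type.  ``recursion_depth_limit`` bounds how many
    times a non-MeSH concept name may be re-submitted as free text.
    """

    semantic_type_filter: frozenset[str] = DISEASE_SEMANTIC_TYPES
    expand_scr: bool = False
    recursion_depth_limit: int = 2
    strip_possessives: bool = True

    def __post_init__(self) -> None:
        if self.recursion_depth_limit < 0:
            raise ValueError("recursion_depth_limit must be >= 0")


def normalize_phrase(text: str, strip_possessives: bool = True) -> str:
    """Normalize free text for dictionary lookup.

    Lowercases, removes ASCII and typographic apostrophes/backticks
    (optionally dropping a possessive "s" left behind), replaces remaining
    punctuation with spaces and collapses whitespace.  Idempotent.

    >>> normalize_phrase("Graves` disease")
    'graves disease'
    """
    t = text.casefold()
    if strip_possessives:
        t = _POSSESSIVE_RE.sub(r"\1", t)
    t = _APOSTROPHE_RE.sub("", t)
    t = _PUNCT_RE.sub(" ", t)
    return _WS_RE.sub(" ", t).strip()


# ---------------------------------------------------------------- name index


class _NameIndex:
    """Normalized preferred names of MeSH terms (and optionally non-MeSH
    concepts) with deterministic tie-breaks: MH before SCR before non-MeSH,
    then smaller id."""

    def __init__(self, ds: MeSHDataset, cfg: RecognizerConfig, with_nonmesh: bool):
        self.entries: dict[str, list[tuple[int, str]]] = {}
        self.max_words = 1
        for term in ds.terms():
            rank = 0 if term.is_mh else 1
            self._add(normalize_phrase(term.name, cfg.strip_possessives), rank, term.ui)
        if with_nonmesh:
            for cui, name in ds.nonmesh_concepts.items():
                self._add(normalize_phrase(name, cfg.strip_possessives), 2, cui)

    def _add(self, key: str, rank: int, ident: str) -> None:
        if not key:
            return
        self.entries.setdefault(key, []).append((rank, ident))
        self.entries[key].sort()
        self.max_words = max(self.max_words, key.count(" ") + 1)


def _index_for(ds: MeSHDataset, cfg: RecognizerConfig, with_nonmesh: bool) -> _NameIndex:
    cache = getattr(ds, "_meshsem_name_index_cache", None)
    if cache is None:
        cache = {}
        ds._meshsem_name_index_cache = cache  # type: ignore[attr-defined]
    key = (cfg.strip_possessives, with_nonmesh)
    if key not in cache:
        cache[key] = _NameIndex(ds, cfg, with_nonmesh)
    return cache[key]


def _type_passes(cfg: RecognizerConfig, types: frozenset[str]) -> bool:
    return not cfg.semantic_type_filter or bool(types & cfg.semantic_type_filter)


def _tokenize(text: str, strip_possessives: bool) -> list[tuple[str, int, int]]:
    """(normalized token, start, end) triples; tokens that normalize to
    nothing (pure punctuation) are dropped."""
    out = []
    for m in _TOKEN_RE.finditer(text):
        norm = normalize_phrase(m.group(), strip_possessives)
        if norm:
            out.append((norm, m.start(), m.end()))
    return out


def _scan(
    ds: MeSHDataset,
    text: str,
    cfg: RecognizerConfig,
    index: _NameIndex,
    skip_nonmesh: frozenset[str] = frozenset(),
) -> Iterator[tuple[tuple[int, int], tuple[int, str]]]:
    """Greedy leftmost-longest scan; yields (span, (rank, identifier)).

    ``skip_nonmesh`` holds normalized non-MeSH concept names already being
    resolved; rejecting them breaks recursion cycles and lets shorter
    windows (e.g. an embedded MH name) match instead.
    """
    tokens = _tokenize(text, cfg.strip_possessives)
    i = 0
    while i < len(tokens):
        hit = None
        for j in range(min(len(tokens), i + index.max_words), i, -1):
            key = " ".join(t[0] for t in tokens[i:j])
            for rank, ident in index.entries.get(key, ()):
                if rank == 2:
                    if key in skip_nonmesh:
                        logger.warning(
                            "recursion cycle at %r; falling back to shorter matches",
                            key,
                        )
                        continue
                    hit = ((tokens[i][1], tokens[j - 1][2]), (rank, ident))
                    break
                if _type_passes(cfg, ds.get_term(ident).semantic_types):
                    hit = ((tokens[i][1], tokens[j - 1][2]), (rank, ident))
                    break
            if hit:
                break
        if hit:
            yield hit
            # advance past the matched tokens
            end = hit[0][1]
            while i < len(tokens) and tokens[i][1] < end:
                i += 1
        else:
            i += 1


def _annotation(
    text: str, span: tuple[int, int], term: MeSHTerm, route: str,
    cui: str | None = None, score: float = 1.0,
) -> MeSHAnnotation:
    return MeSHAnnotation(
        source_text=text,
        span=span,
        cui=cui if cui is not None else min(term.cuis),
        mesh_ui=term.ui,
        mesh_name=term.name,
        record_kind=term.record_kind,
        route=route,
        score=score,
    )


def match_concepts(
    ds: MeSHDataset, text: str, cfg: RecognizerConfig | None = None
) -> list[MeSHAnnotation]:
    """Non-overlapping longest matches of stored preferred names in ``text``.

    Annotations are returned in ascending span order with route ``direct``
    (main heading) or ``scr``.
    """
    cfg = cfg or RecognizerConfig()
    index = _index_for(ds, cfg, with_nonmesh=False)
    out = []
    for span, (_rank, ui) in _scan(ds, text, cfg, index):
        term = ds.get_term(ui)
        route = ROUTE_DIRECT if term.is_mh else ROUTE_SCR
        out.append(_annotation(text, span, term, route))
    return out


def _resolve_name_recursively(
    ds: MeSHDataset, name: str, cfg: RecognizerConfig,
    depth: int, visited: set[str],
    source_text: str, span: tuple[int, int], cui: str, score: float,
) -> list[MeSHAnnotation]:
    """Re-submit a non-MeSH concept name as free text (route ``recursive``)."""
    if depth > cfg.recursion_depth_limit:
        return []
    visited = visited | {normalize_phrase(name, cfg.strip_possessives)}
    index = _index_for(ds, cfg, with_nonmesh=True)
    out: list[MeSHAnnotation] = []
    for _span, (rank, ident) in _scan(ds, name, cfg, index, frozenset(visited)):
        if rank < 2:
            term = ds.get_term(ident)
            out.append(_annotation(source_text, span, term, ROUTE_RECURSIVE,
                                   cui=cui, score=score))
            if term.record_kind == SCR and cfg.expand_scr:
                out.extend(_expand_scr(ds, source_text, span, term, score))
        else:
            out.extend(
                _resolve_name_recursively(
                    ds, ds.nonmesh_concepts[ident], cfg, depth + 1, visited,
                    source_text, span, cui, score,
                )
            )
    return out


def _expand_scr(
    ds: MeSHDataset, text: str, span: tuple[int, int], scr: MeSHTerm, score: float,
) -> list[MeSHAnnotation]:
    return [
        _annotation(text, span, ds.get_term(mh_ui), ROUTE_SCR_EXPANDED,
                    cui=min(scr.cuis), score=score)
        for mh_ui in sorted(ds.scr_broader_mhs(scr.ui))
    ]


def parse_text(
    ds: MeSHDataset, text: str, cfg: RecognizerConfig | None = None
) -> list[MeSHAnnotation]:
    """Full recognition pipeline over one free-text phrase.

    Extends :func:`match_concepts` with SCR expansion (when enabled) and
    the recursive route for non-MeSH-synonymous concepts whose names occur
    in the text.
    """
    cfg = cfg or RecognizerConfig()
    with_nonmesh = cfg.recursion_depth_limit > 0 and bool(ds.nonmesh_concepts)
    index = _index_for(ds, cfg, with_nonmesh=with_nonmesh)
    out: list[MeSHAnnotation] = []
    for span, (rank, ident) in _scan(ds, text, cfg, index):
        if rank < 2:
            term = ds.get_term(ident)
            route = ROUTE_DIRECT if term.is_mh else ROUTE_SCR
            out.append(_annotation(text, span, term, route))
            if term.record_kind == SCR and cfg.expand_scr:
                out.extend(_expand_scr(ds, text, span, term, 1.0))
        else:
            out.extend(
                _resolve_name_recursively(
                    ds, ds.nonmesh_concepts[ident], cfg, depth=1, visited=set(),
                    source_text=text, span=span, cui=ident, score=1.0,
                )
            )
    return out


# ----------------------------------------------------------------- MMI input


def parse_mmi_output(
    ds: MeSHDataset, stream: Iterable[str], cfg: RecognizerConfig | None = None
) -> list[MeSHAnnotation]:
    """Resolve MetaMap fielded (MMI) output lines against the dataset.

    Each ``MMI`` record carries ``id|MMI|score|preferred name|CUI|semantic
    types|trigger|location|positional info``.  Scores are rescaled from
    MetaMap's 0-1000 range to [0, 1].  CUIs mapped in the dataset resolve
    directly; unmapped CUIs route their preferred name through the
    recursive path.  Non-MMI records (e.g. ``AA`` abbreviation lines) are
    ignored; malformed lines are skipped with a log message.
    """
    cfg = cfg or RecognizerConfig()
    out: list[MeSHAnnotation] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("|")
        if len(fields) < 5:
            logger.warning("MMI line %d: too few fields; skipped", lineno)
            continue
        if fields[1] != "MMI":
            continue
        try:
            score = max(0.0, min(1.0, float(fields[2]) / 1000.0))
        except ValueError:
            logger.warning("MMI line %d: bad score %r; skipped", lineno, fields[2])
            continue
        name, cui = fields[3], fields[4]
        types = frozenset(
            t.strip() for t in fields[5].strip("[]").split(",") if t.strip()
        ) if len(fields) > 5 else frozenset()
        if types and not _type_passes(cfg, types):
            continue
        span = (0, len(name))
        try:
            term = ds.umls_to_mesh(cui)
        except NoMeshMappingError:
            out.extend(
                _resolve_name_recursively(
                    ds, name, cfg, depth=1, visited=set(),
                    source_text=name, span=span, cui=cui, score=score,
                )
            )
            continue
        route = ROUTE_DIRECT if term.is_mh else ROUTE_SCR
        out.append(_annotation(name, span, term, route, cui=cui, score=score))
        if term.record_kind == SCR and cfg.expand_scr:
            out.extend(_expand_scr(ds, name, span, term, score))
    return out
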