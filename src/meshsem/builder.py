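"""Building a dataset from UMLS-style pipe-delimited (RRF) files.

Full UMLS releases ship 18+-column tables; this builder consumes a
configured, documented subset sufficient to reconstruct the five-table
model:

``concepts`` file (one row per CUI↔term link)
    ``cui|ui|kind|name|tree_numbers|count`` where ``kind`` is ``MH``,
    ``SCR`` or ``NONMESH`` (``ui`` empty for NONMESH rows) and
    ``tree_numbers`` is comma-joined (the pipe is the field separator).
``relations`` file
    ``ui1|rel|ui2`` with ``rel`` = ``PAR`` (ui1 is parent of ui2) or
    ``RB`` (SCR ui1 has broader MH ui2).
``semantic_types`` file
    ``cui|type_code``.

A trailing pipe (as in real RRF) is tolerated.  In strict mode a row with
the wrong field count aborts the build with its line number; in lenient
mode it is skipped with a log message.  Dangling references are collected
and reported together, and a build fails if any SCR ends up with no
broader main heading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

from .dataset import MeSHDataset, MeSHTerm, MH, SCR
from .errors import BuildError
from .io import save_dataset
from .tree import TreeNumber

logger = logging.getLogger(__name__)

CONCEPT_COLUMNS = ("cui", "ui", "kind", "name", "tree_numbers", "count")
RELATION_COLUMNS = ("ui1", "rel", "ui2")
STY_COLUMNS = ("cui", "type_code")

PARENT_REL = "PAR"
BROADER_REL = "RB"
NONMESH_KIND = "NONMESH"


@dataclass(frozen=True)
class RRFRow:
    """One parsed pipe-delimited row."""

    values: tuple[str, ...]
    line_number: int

    def __getitem__(self, key: int) -> str:
        return self.values[key]


def parse_rrf(
    path: str | Path, column_map: Sequence[str], strict: bool = True
) -> Iterator[RRFRow]:
    """Lazily parse a pipe-delimited file with a fixed column count.

    A single trailing ``|`` per line is tolerated (standard RRF style).
    Rows with any other field count raise :class:`BuildError` naming the
    line (strict mode) or are skipped with a log message (lenient mode).
    """
    n_cols = len(column_map)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("|")
            # RRF lines end with a separator; writers emitting an empty
            # final field must still close with "|"
            if len(fields) > 1 and fields[-1] == "":
                fields = fields[:-1]
            if len(fields) != n_cols:
                msg = (
                    f"{path}: line {lineno}: expected {n_cols} fields, "
                    f"got {len(fields)}"
                )
                if strict:
                    raise BuildError(msg)
                logger.warning("%s; skipped", msg)
                continue
            yield RRFRow(values=tuple(fields), line_number=lineno)


def build_dataset(
    concept_file: str | Path,
    rel_file: str | Path,
    sty_file: str | Path,
    out_dir: str | Path | None = None,
    strict: bool = True,
    n_total: int | None = None,
) -> MeSHDataset:
    """Assemble a dataset from the three source files.

    Writes the five tables to ``out_dir`` when given and returns the loaded
    dataset.  ``n_total`` defaults to the sum of all per-term counts.
    """
    names: dict[str, str] = {}
    kinds: dict[str, str] = {}
    tns: dict[str, set[str]] = {}
    cuis: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    nonmesh: dict[str, str] = {}

    for row in parse_rrf(concept_file, CONCEPT_COLUMNS, strict):
        cui, ui, kind, name, tn_field, count = row.values
        if kind == NONMESH_KIND:
            nonmesh[cui] = name
            continue
        if kind not in (MH, SCR):
            raise BuildError(
                f"{concept_file}: line {row.line_number}: unknown record kind {kind!r}"
            )
        prev = kinds.get(ui)
        if prev is not None and prev != kind:
            raise BuildError(f"{concept_file}: id {ui} listed as both {prev} and {kind}")
        kinds[ui] = kind
        names[ui] = name
        cuis.setdefault(ui, set()).add(cui)
        if tn_field:
            tns.setdefault(ui, set()).update(t for t in tn_field.split(",") if t)
        if count:
            counts[ui] = max(counts.get(ui, 0), int(count))

    sty: dict[str, set[str]] = {}
    dangling: list[str] = []
    for row in parse_rrf(sty_file, STY_COLUMNS, strict):
        cui, code = row.values
        sty.setdefault(cui, set()).add(code)

    parent_child: list[tuple[str, str]] = []
    scr_broader: dict[str, set[str]] = {}
    for row in parse_rrf(rel_file, RELATION_COLUMNS, strict):
        ui1, rel, ui2 = row.values
        missing = [u for u in (ui1, ui2) if u not in kinds]
        if missing:
            dangling.extend(f"line {row.line_number}: {u}" for u in missing)
            continue
        if rel == PARENT_REL:
            parent_child.append((ui1, ui2))
        elif rel == BROADER_REL:
            scr_broader.setdefault(ui1, set()).add(ui2)
        else:
            raise BuildError(
                f"{rel_file}: line {row.line_number}: unknown relation {rel!r}"
            )

    if dangling:
        raise BuildError(
            f"{rel_file}: relations reference unknown ids: " + "; ".join(dangling)
        )
    orphans = [ui for ui, k in kinds.items() if k == SCR and not scr_broader.get(ui)]
    if orphans:
        raise BuildError(f"SCRs with no broader main heading: {sorted(orphans)}")

    def term_types(ui: str) -> frozenset[str]:
        out: set[str] = set()
        for c in cuis[ui]:
            out.update(sty.get(c, ()))
        return frozenset(out)

    mhs = [
        MeSHTerm(
            ui=ui,
            name=names[ui],
            record_kind=MH,
            tree_numbers=frozenset(TreeNumber(t) for t in tns.get(ui, ())),
            semantic_types=term_types(ui),
            cuis=frozenset(cuis[ui]),
            pub_count=counts.get(ui),
        )
        for ui, kind in kinds.items() if kind == MH
    ]
    scrs = [
        MeSHTerm(
            ui=ui,
            name=names[ui],
            record_kind=SCR,
            semantic_types=term_types(ui),
            cuis=frozenset(cuis[ui]),
            pub_count=counts.get(ui),
        )
        for ui, kind in kinds.items() if kind == SCR
    ]
    if n_total is None:
        n_total = sum(counts.values()) or 1

    ds = MeSHDataset(
        main_headings=mhs,
        scrs=scrs,
        scr_broader={k: frozenset(v) for k, v in scr_broader.items()},
        parent_child=parent_child,
        n_total=n_total,
        nonmesh_concepts=nonmesh,
    )
    if out_dir is not None:
        save_dataset(ds, out_dir)
    return ds


def export_rrf(ds: MeSHDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset back out as the three-file RRF source form.

    Inverse of :func:`build_dataset` up to table ordering; used to produce
    RRF inputs from synthetic fixtures.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "concepts": out / "concepts.rrf",
        "relations": out / "relations.rrf",
        "semantic_types": out / "semantic_types.rrf",
    }
    with open(paths["concepts"], "w", encoding="utf-8") as fh:
        for term in sorted(ds.terms(), key=lambda t: t.ui):
            tn_field = ",".join(sorted(tn.text for tn in term.tree_numbers))
            count = "" if term.pub_count is None else str(term.pub_count)
            for cui in sorted(term.cuis):
                fh.write(
                    f"{cui}|{term.ui}|{term.record_kind}|{term.name}|{tn_field}|{count}|\n"
                )
        for cui, name in sorted(ds.nonmesh_concepts.items()):
            fh.write(f"{cui}||{NONMESH_KIND}|{name}|||\n")
    with open(paths["relations"], "w", encoding="utf-8") as fh:
        for parent, child in sorted(ds.parent_child):
            fh.write(f"{parent}|{PARENT_REL}|{child}|\n")
        for scr_ui in sorted(ds.scr_broader):
            for mh_ui in sorted(ds.scr_broader[scr_ui]):
                fh.write(f"{scr_ui}|{BROADER_REL}|{mh_ui}|\n")
    with open(paths["semantic_types"], "w", encoding="utf-8") as fh:
        for term in sorted(ds.terms(), key=lambda t: t.ui):
            cui = min(term.cuis)
            for code in sorted(term.semantic_types):
                fh.write(f"{cui}|{code}|\n")
    return paths
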