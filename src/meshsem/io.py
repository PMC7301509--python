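"""Plain-text serialization of the five-table dataset.

The on-disk form is a directory of TSV tables plus a JSON manifest:

``MainHeadingDetailData.tsv``
    ui, name, tree_numbers, category, semantic_types, cuis, pub_count
``SupplementMainHeading.tsv``
    cui, mh_ui (all UMLS concepts related to MHs)
``RNDetailData.tsv``
    ui, name, semantic_types, cuis, pub_count (SCR basic records)
``RNandRBRel.tsv``
    scr_ui, mh_ui (narrower/broader links from SCRs to MHs)
``ParentChildRel.tsv``
    parent_ui, child_ui
``NonMeshConcepts.tsv`` (optional)
    cui, name — non-MeSH-synonymous UMLS concepts for the recursive route

Multi-valued fields are "|"-joined and sorted, rows are sorted on the first
column, so serialization is byte-deterministic.  ``manifest.json`` records
the schema version, total publication count N and per-table row counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .dataset import MeSHDataset, MeSHTerm, MH, SCR
from .errors import DatasetIntegrityError
from .tree import TreeNumber

SCHEMA_VERSION = "1.0"

MAIN_HEADING_TABLE = "MainHeadingDetailData"
SUPPLEMENT_TABLE = "SupplementMainHeading"
SCR_TABLE = "RNDetailData"
SCR_BROADER_TABLE = "RNandRBRel"
PARENT_CHILD_TABLE = "ParentChildRel"
NONMESH_TABLE = "NonMeshConcepts"

_COLUMNS = {
    MAIN_HEADING_TABLE: [
        "ui", "name", "tree_numbers", "category", "semantic_types", "cuis", "pub_count",
    ],
    SUPPLEMENT_TABLE: ["cui", "mh_ui"],
    SCR_TABLE: ["ui", "name", "semantic_types", "cuis", "pub_count"],
    SCR_BROADER_TABLE: ["scr_ui", "mh_ui"],
    PARENT_CHILD_TABLE: ["parent_ui", "child_ui"],
    NONMESH_TABLE: ["cui", "name"],
}


def _join(values) -> str:
    return "|".join(sorted(str(v) for v in values))


def _term_count(term: MeSHTerm) -> str:
    return "" if term.pub_count is None else str(term.pub_count)


def dataset_to_tables(ds: MeSHDataset) -> dict[str, pd.DataFrame]:
    """Render a dataset as the five (plus optional sixth) canonical tables."""
    mh_rows = [
        {
            "ui": t.ui,
            "name": t.name,
            "tree_numbers": _join(tn.text for tn in t.tree_numbers),
            "category": _join(t.categories),
            "semantic_types": _join(t.semantic_types),
            "cuis": _join(t.cuis),
            "pub_count": _term_count(t),
        }
        for t in sorted(ds.main_headings, key=lambda t: t.ui)
    ]
    supp_rows = [
        {"cui": cui, "mh_ui": t.ui}
        for t in sorted(ds.main_headings, key=lambda t: t.ui)
        for cui in sorted(t.cuis)
    ]
    scr_rows = [
        {
            "ui": t.ui,
            "name": t.name,
            "semantic_types": _join(t.semantic_types),
            "cuis": _join(t.cuis),
            "pub_count": _term_count(t),
        }
        for t in sorted(ds.scrs, key=lambda t: t.ui)
    ]
    broader_rows = [
        {"scr_ui": scr_ui, "mh_ui": mh_ui}
        for scr_ui in sorted(ds.scr_broader)
        for mh_ui in sorted(ds.scr_broader[scr_ui])
    ]
    pc_rows = [
        {"parent_ui": p, "child_ui": c} for p, c in sorted(ds.parent_child)
    ]
    tables = {
        MAIN_HEADING_TABLE: pd.DataFrame(mh_rows, columns=_COLUMNS[MAIN_HEADING_TABLE]),
        SUPPLEMENT_TABLE: pd.DataFrame(supp_rows, columns=_COLUMNS[SUPPLEMENT_TABLE]),
        SCR_TABLE: pd.DataFrame(scr_rows, columns=_COLUMNS[SCR_TABLE]),
        SCR_BROADER_TABLE: pd.DataFrame(broader_rows, columns=_COLUMNS[SCR_BROADER_TABLE]),
        PARENT_CHILD_TABLE: pd.DataFrame(pc_rows, columns=_COLUMNS[PARENT_CHILD_TABLE]),
    }
    if ds.nonmesh_concepts:
        tables[NONMESH_TABLE] = pd.DataFrame(
            [{"cui": c, "name": n} for c, n in sorted(ds.nonmesh_concepts.items())],
            columns=_COLUMNS[NONMESH_TABLE],
        )
    return tables


def save_dataset(ds: MeSHDataset, out_dir: str | Path) -> Path:
    """Write the dataset directory; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = dataset_to_tables(ds)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "n_total": ds.n_total,
        "tables": {name: {"columns": _COLUMNS[name], "rows": len(df)}
                   for name, df in tables.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _read_table(path: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = _COLUMNS[name]
    if list(df.columns) != expected:
        raise DatasetIntegrityError(
            f"table {name} has columns {list(df.columns)}, expected {expected}"
        )
    return df


def _split(cell: str) -> frozenset[str]:
    return frozenset(p for p in cell.split("|") if p)


def _parse_count(cell: str) -> int | None:
    return None if cell == "" else int(cell)


def load_dataset(in_dir: str | Path) -> MeSHDataset:
    """Load a dataset directory written by :func:`save_dataset`."""
    d = Path(in_dir)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise DatasetIntegrityError(f"no manifest.json in {d}")
    manifest = json.loads(manifest_path.read_text())

    mh_df = _read_table(d / f"{MAIN_HEADING_TABLE}.tsv", MAIN_HEADING_TABLE)
    scr_df = _read_table(d / f"{SCR_TABLE}.tsv", SCR_TABLE)
    broader_df = _read_table(d / f"{SCR_BROADER_TABLE}.tsv", SCR_BROADER_TABLE)
    pc_df = _read_table(d / f"{PARENT_CHILD_TABLE}.tsv", PARENT_CHILD_TABLE)

    mhs = [
        MeSHTerm(
            ui=r.ui,
            name=r.name,
            record_kind=MH,
            tree_numbers=frozenset(TreeNumber(t) for t in _split(r.tree_numbers)),
            semantic_types=_split(r.semantic_types),
            cuis=_split(r.cuis),
            pub_count=_parse_count(r.pub_count),
        )
        for r in mh_df.itertuples()
    ]
    scrs = [
        MeSHTerm(
            ui=r.ui,
            name=r.name,
            record_kind=SCR,
            semantic_types=_split(r.semantic_types),
            cuis=_split(r.cuis),
            pub_count=_parse_count(r.pub_count),
        )
        for r in scr_df.itertuples()
    ]
    scr_broader: dict[str, set[str]] = {}
    for r in broader_df.itertuples():
        scr_broader.setdefault(r.scr_ui, set()).add(r.mh_ui)
    parent_child = [(r.parent_ui, r.child_ui) for r in pc_df.itertuples()]

    nonmesh: dict[str, str] = {}
    nonmesh_path = d / f"{NONMESH_TABLE}.tsv"
    if nonmesh_path.exists():
        for r in _read_table(nonmesh_path, NONMESH_TABLE).itertuples():
            nonmesh[r.cui] = r.name

    return MeSHDataset(
        main_headings=mhs,
        scrs=scrs,
        scr_broader={k: frozenset(v) for k, v in scr_broader.items()},
        parent_child=parent_child,
        n_total=int(manifest.get("n_total", 0)),
        nonmesh_concepts=nonmesh,
    )
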