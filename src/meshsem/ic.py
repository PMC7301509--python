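"""Information content of MeSH terms from publication counts.

A term's occurrence probability is the number of publications indexed by
the term or any of its descendants, divided by the total number N of
publications indexed by the vocabulary; its information content is the
negative base-10 logarithm of that probability:

    P(d)  = freq(D(d)) / N          D(d) = descendants of d (d included)
    IC(d) = -log10(P(d))

Rolling counts up over the inclusive descendant closure makes IC
anti-monotone along the hierarchy: a parent is never more informative than
its child.  Base 10 is used so that 10^(-IC(d)) recovers P(d), the form the
Schlicker relevance measure multiplies into the Lin score.  A zero roll-up
is replaced by a pseudo-count of 1 (a never-indexed term is maximally, not
infinitely, informative).
"""

from __future__ import annotations

import csv
import json
import logging
import math
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

from .dataset import MeSHDataset
from .errors import TransportError

logger = logging.getLogger(__name__)

LOG_BASE = 10

ESEARCH_URL = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"


@dataclass(frozen=True)
class FrequencyTable:
    """Per-term publication counts plus the vocabulary-wide total N."""

    counts: dict[str, int]
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("total publication count N must be positive")
        bad = [ui for ui, c in self.counts.items() if c < 0]
        if bad:
            raise ValueError(f"negative publication counts for {bad}")

    @classmethod
    def from_dataset(cls, ds: MeSHDataset) -> "FrequencyTable":
        """Counts embedded in the dataset itself (fixture or built data)."""
        counts = {
            t.ui: t.pub_count for t in ds.main_headings if t.pub_count is not None
        }
        return cls(counts=counts, n_total=ds.n_total)

    @classmethod
    def from_tsv(cls, path: str | Path, n_total: int | None = None) -> "FrequencyTable":
        """Read a ``mesh_ui, name, count`` TSV.

        N is taken from the ``n_total`` argument or from a leading comment
        line of the form ``# N_total=<int>``.
        """
        counts: dict[str, int] = {}
        with open(path, newline="") as fh:
            header_seen = False
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if "N_total=" in line and n_total is None:
                        n_total = int(line.split("N_total=", 1)[1].strip())
                    continue
                fields = line.split("\t")
                if not header_seen:
                    header_seen = True
                    if fields[0] == "mesh_ui":
                        continue
                counts[fields[0]] = int(fields[2] if len(fields) > 2 else fields[1])
        if n_total is None:
            raise ValueError(f"{path}: no N_total header and none supplied")
        return cls(counts=counts, n_total=n_total)

    def to_tsv(self, path: str | Path, ds: MeSHDataset | None = None) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(f"# N_total={self.n_total}\n")
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["mesh_ui", "name", "count"])
            for ui in sorted(self.counts):
                name = ds.get_term(ui).name if ds is not None and ui in ds else ""
                w.writerow([ui, name, self.counts[ui]])


@dataclass(frozen=True)
class ICTable:
    """Information-content values (base-10) for every main heading."""

    ic: dict[str, float]
    n_total: int
    log_base: int = LOG_BASE

    def __getitem__(self, ui: str) -> float:
        return self.ic[ui]

    def __contains__(self, ui: str) -> bool:
        return ui in self.ic


def descendant_closure(ds: MeSHDataset, ui: str, include_self: bool = True) -> frozenset[str]:
    """MHs whose tree numbers properly extend any tree number of ``ui``.

    ``ui`` itself is included by default: the roll-up convention where a
    term counts its own publications keeps leaf probabilities well defined.
    """
    return ds.descendant_terms(ui, include_self=include_self)


def rollup_frequency(
    ds: MeSHDataset, ui: str, ft: FrequencyTable, include_self: bool = True
) -> int:
    """Sum of publication counts over the descendant closure (missing = 0)."""
    return sum(
        ft.counts.get(d, 0) for d in descendant_closure(ds, ui, include_self)
    )


def information_content(
    ds: MeSHDataset, ui: str, ft: FrequencyTable, include_self: bool = True
) -> float:
    """IC(d) = -log10(freq(D(d)) / N), with pseudo-count 1 for zero roll-ups."""
    freq = rollup_frequency(ds, ui, ft, include_self)
    if freq == 0:
        freq = 1
    return -math.log10(freq / ft.n_total)


def build_ic_table(
    ds: MeSHDataset, ft: FrequencyTable, include_self: bool = True
) -> ICTable:
    """IC for every main heading in the dataset."""
    ic = {
        t.ui: information_content(ds, t.ui, ft, include_self)
        for t in sorted(ds.main_headings, key=lambda t: t.ui)
    }
    return ICTable(ic=ic, n_total=ft.n_total)


# --------------------------------------------------------------- count fetch

Fetcher = Callable[[str], int]


def _eutils_fetcher(endpoint: str = ESEARCH_URL, timeout: float = 10.0) -> Fetcher:
    """Count fetcher querying the MeSH field of PubMed via esearch."""

    def fetch(name: str) -> int:
        query = urllib.parse.urlencode(
            {"db": "pubmed", "term": f'"{name}"[MeSH Terms]',
             "rettype": "count", "retmode": "json"}
        )
        with urllib.request.urlopen(f"{endpoint}?{query}", timeout=timeout) as resp:
            payload = json.loads(resp.read().decode("utf-8"))
        return int(payload["esearchresult"]["count"])

    return fetch


def fetch_publication_counts(
    terms: Iterable[tuple[str, str]],
    fetcher: Fetcher | None = None,
    cache_path: str | Path | None = None,
    retries: int = 2,
    delay: float = 0.0,
) -> dict[str, int]:
    """Publication count per (ui, name) pair, with an on-disk JSON cache.

    ``fetcher`` maps a term name to a count; when omitted, a live NCBI
    esearch fetcher is used (tests always inject a recorded fetcher).
    A transport failure after ``retries`` attempts raises
    :class:`TransportError` carrying the counts gathered so far.
    """
    if fetcher is None:
        fetcher = _eutils_fetcher()
    cache: dict[str, int] = {}
    if cache_path is not None and Path(cache_path).exists():
        cache = {k: int(v) for k, v in json.loads(Path(cache_path).read_text()).items()}

    out: dict[str, int] = {}
    for ui, name in terms:
        if ui in cache:
            out[ui] = cache[ui]
            continue
        last_err: Exception | None = None
        for attempt in range(retries + 1):
            try:
                count = int(fetcher(name))
                if count < 0:
                    raise ValueError(f"negative count {count} for {name!r}")
                out[ui] = cache[ui] = count
                last_err = None
                break
            except Exception as err:  # noqa: BLE001 - any transport failure retries
                last_err = err
                if delay:
                    time.sleep(delay)
        if last_err is not None:
            if cache_path is not None:
                Path(cache_path).write_text(json.dumps(cache, sort_keys=True))
            raise TransportError(
                f"failed to fetch count for {name!r}: {last_err}", partial=out
            )
    if cache_path is not None:
        Path(cache_path).write_text(json.dumps(cache, sort_keys=True))
    return out
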