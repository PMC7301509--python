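"""Dotted tree-number addresses for the MeSH hierarchy.

A tree number such as ``"C10.574.945"`` encodes one position of a main
heading in the MeSH forest.  Truncating trailing components yields the
positions of its ancestors, and the first character of the string is the
MeSH category letter (``C`` diseases, ``F`` psychiatry and psychology, ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property

from .errors import MalformedTreeNumberError

_COMPONENT_RE = re.compile(r"^[A-Za-z0-9]+$")


@dataclass(frozen=True, order=True)
class TreeNumber:
    """A validated dotted hierarchical address.

    Parameters
    ----------
    text:
        The dotted string, e.g. ``"C10.574.945"``.  The first component must
        start with a single uppercase category letter; components are
        non-empty alphanumeric strings separated by ``"."``.
    """

    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise MalformedTreeNumberError("empty tree number")
        parts = self.text.split(".")
        if any(not _COMPONENT_RE.match(p) for p in parts):
            raise MalformedTreeNumberError(
                f"malformed tree number {self.text!r}: empty or non-alphanumeric component"
            )
        if not self.text[0].isupper() or not self.text[0].isalpha():
            raise MalformedTreeNumberError(
                f"malformed tree number {self.text!r}: must start with an uppercase category letter"
            )

    @cached_property
    def components(self) -> tuple[str, ...]:
        return tuple(self.text.split("."))

    @property
    def category(self) -> str:
        """Single-letter MeSH category, the first character of the address."""
        return self.text[0]

    @property
    def depth(self) -> int:
        """Number of components; top-level nodes have depth 1."""
        return len(self.components)

    def ancestors(self) -> list["TreeNumber"]:
        """All proper dotted prefixes, nearest ancestor first.

        ``TreeNumber("C10.574.945").ancestors()`` is
        ``[TreeNumber("C10.574"), TreeNumber("C10")]``; a top-level address
        has no ancestors.  The address itself is never included.
        """
        parts = self.components
        return [
            TreeNumber(".".join(parts[:k])) for k in range(len(parts) - 1, 0, -1)
        ]

    def parent(self) -> "TreeNumber | None":
        """The immediate ancestor, or ``None`` for a top-level address."""
        anc = self.ancestors()
        return anc[0] if anc else None

    def is_proper_prefix_of(self, other: "TreeNumber") -> bool:
        """True iff ``self`` is an ancestor address of ``other``."""
        return other.text.startswith(self.text + ".")

    def __str__(self) -> str:
        return self.text


def ancestors_of_tree_number(tn: TreeNumber | str) -> list[TreeNumber]:
    """Proper prefixes of a tree number, nearest-first (see :meth:`TreeNumber.ancestors`)."""
    if isinstance(tn, str):
        tn = TreeNumber(tn)
    return tn.ancestors()
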