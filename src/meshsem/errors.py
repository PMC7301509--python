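"""Exception hierarchy for the meshsem package."""


class MeshSemError(Exception):
    """Base class for all meshsem errors."""


class MalformedTreeNumberError(MeshSemError, ValueError):
    """A tree number string violates the dotted-address grammar."""


class UnknownTermError(MeshSemError, KeyError):
    """A MeSH unique id is not present in the dataset."""

    def __init__(self, ui: str):
        super().__init__(ui)
        self.ui = ui

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return f"unknown MeSH id: {self.ui!r}"


class NoMeshMappingError(MeshSemError, KeyError):
    """A UMLS concept id has no MeSH-synonymous mapping in the dataset."""

    def __init__(self, cui: str):
        super().__init__(cui)
        self.cui = cui

    def __str__(self) -> str:
        return f"UMLS concept {self.cui!r} is not MeSH-synonymous in this dataset"


class NotAnSCRError(MeshSemError, TypeError):
    """An operation restricted to supplementary concept records got a main heading."""


class NotAMainHeadingError(MeshSemError, TypeError):
    """An operation defined on main headings got an SCR."""


class DatasetIntegrityError(MeshSemError):
    """The five-table dataset violates one of its structural invariants."""


class BuildError(MeshSemError):
    """Raw source files could not be assembled into a consistent dataset."""


class InfeasibleSpecError(MeshSemError, ValueError):
    """A fixture specification cannot produce a valid dataset."""


class TransportError(MeshSemError):
    """A publication-count fetch failed; carries any partial results."""

    def __init__(self, message: str, partial: dict | None = None):
        super().__init__(message)
        self.partial = dict(partial or {})
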