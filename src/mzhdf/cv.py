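"""PSI-MS controlled-vocabulary support.

The PSI-MS CV assigns a stable accession (``MS:<7 digits>``) and a name to
every concept in mass spectrometry — ``MS:1000628`` is "basepeak
chromatogram", a kind of ``MS:1000810`` "mass chromatogram".  Every dataset
this package writes to HDF5 is tagged with the accession and name of the CV
term that best describes it; where PSI has not issued a specific term the
annotation falls back on the more general parent term "binary data array"
(``MS:1000513``), flagged as such.

The vocabulary is distributed as an OBO v1.2 flat file.  :func:`parse_obo`
builds a :class:`TermCatalog` from one; a small excerpt of the real ontology
ships with the package so everything works offline
(:func:`load_bundled_catalog`).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Mapping

import obonet

__all__ = [
    "CVTerm",
    "TermCatalog",
    "RoleAnnotation",
    "OboParseError",
    "UnknownAccessionError",
    "CycleError",
    "UnknownRoleError",
    "CatalogMismatchError",
    "parse_obo",
    "load_bundled_catalog",
    "ROLE_TABLE",
]

_MS_ACCESSION_RE = re.compile(r"^MS:\d{7}$")


class OboParseError(ValueError):
    """A [Term] stanza violated the minimal OBO contract (e.g. id without name)."""


class UnknownAccessionError(KeyError):
    """Lookup of an accession not present in the catalog."""

    def __init__(self, accession: str):
        super().__init__(accession)
        self.accession = accession

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return f"unknown CV accession: {self.accession}"


class CycleError(ValueError):
    """The is_a graph contains a cycle (names one member term)."""


class UnknownRoleError(KeyError):
    """A dataset role with no entry in the role→accession table."""


class CatalogMismatchError(ValueError):
    """The catalog's name for an accession disagrees with the built-in role table,
    indicating CV version drift."""


@dataclass(frozen=True)
class CVTerm:
    """One controlled-vocabulary term."""

    accession: str
    name: str
    parents: frozenset[str] = frozenset()
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise OboParseError(f"term {self.accession} has an empty name")
        if self.accession in self.parents:
            raise OboParseError(f"term {self.accession} lists itself as a parent")


@dataclass
class TermCatalog:
    """Accession-indexed collection of CV terms plus the OBO data-version."""

    terms: dict[str, CVTerm] = field(default_factory=dict)
    source_version: str = ""

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermCatalog):
            return NotImplemented
        return self.terms == other.terms and self.source_version == other.source_version

    def resolve(self, accession: str) -> CVTerm:
        """Return the term for *accession*; raise :class:`UnknownAccessionError` otherwise."""
        try:
            return self.terms[accession]
        except KeyError:
            raise UnknownAccessionError(accession) from None

    def dangling_parents(self) -> set[str]:
        """Parent accessions referenced by some term but absent from the catalog."""
        referenced: set[str] = set()
        for term in self.terms.values():
            referenced.update(term.parents)
        return referenced - set(self.terms)

    def has_ancestor(self, accession: str, ancestor: str) -> bool:
        """True iff *ancestor* is reachable from *accession* via transitive ``is_a``.

        A term is not its own ancestor.  Raises :class:`CycleError` if the walk
        revisits a term on the current path.
        """
        self.resolve(accession)
        self.resolve(ancestor)
        seen: set[str] = set()
        stack = [(accession, frozenset({accession}))]
        while stack:
            current, path = stack.pop()
            term = self.terms.get(current)
            if term is None:  # dangling parent: reachability just stops there
                continue
            for parent in term.parents:
                if parent in path:
                    raise CycleError(f"is_a cycle involving {parent}")
                if parent == ancestor:
                    return True
                if parent not in seen:
                    seen.add(parent)
                    stack.append((parent, path | {parent}))
        return False

    def to_obo(self) -> str:
        """Serialize the catalog back to minimal OBO v1.2 text (lossless for the
        fields the catalog models: id, name, is_a, is_obsolete)."""
        out = io.StringIO()
        out.write("format-version: 1.2\n")
        if self.source_version:
            out.write(f"data-version: {self.source_version}\n")
        out.write("ontology: ms\n")
        for accession in sorted(self.terms):
            term = self.terms[accession]
            out.write(f"\n[Term]\nid: {term.accession}\nname: {term.name}\n")
            for parent in sorted(term.parents):
                out.write(f"is_a: {parent}\n")
            if term.obsolete:
                out.write("is_obsolete: true\n")
        return out.getvalue()


def parse_obo(stream: IO[str] | str) -> TermCatalog:
    """Parse OBO v1.2 text into a :class:`TermCatalog`.

    *stream* may be a file-like object of text, a path, or OBO text itself
    (anything containing a newline is treated as text).  Non-MS namespaces are
    retained.  Empty input yields an empty catalog.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream) if "\n" in stream or not stream else open(stream)
    graph = obonet.read_obo(stream, ignore_obsolete=False)
    terms: dict[str, CVTerm] = {}
    for accession, data in graph.nodes(data=True):
        name = data.get("name")
        if not name:
            raise OboParseError(f"[Term] stanza {accession} has no name")
        parents = frozenset(data.get("is_a", ()))
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        terms[accession] = CVTerm(accession, name, parents, obsolete)
    version = graph.graph.get("data-version", "") or ""
    return TermCatalog(terms=terms, source_version=version)


def load_bundled_catalog() -> TermCatalog:
    """Load the PSI-MS excerpt that ships with the package."""
    text = (
        resources.files("mzhdf.data").joinpath("psi-ms.excerpt.obo").read_text("utf-8")
    )
    return parse_obo(text)


@dataclass(frozen=True)
class RoleAnnotation:
    """CV annotation attached to one dataset role in the store."""

    role: str
    accession: str
    name: str
    is_fallback: bool = False


# Dataset role -> (accession, name, is_fallback). Versioned with the package;
# any disagreement with the consulted OBO is an integrity error, resolved in
# favour of the OBO. Roles with no specific PSI-MS term (per-centroid noise,
# scan bookkeeping integers) fall back on "binary data array" (MS:1000513).
ROLE_TABLE: Mapping[str, tuple[str, str, bool]] = {
    "mz": ("MS:1000514", "m/z array", False),
    "intensity": ("MS:1000515", "intensity array", False),
    "charge": ("MS:1000516", "charge array", False),
    "noise": ("MS:1000513", "binary data array", True),
    "signal_to_noise": ("MS:1000517", "signal to noise array", False),
    "bpc": ("MS:1000628", "basepeak chromatogram", False),
    "tic": ("MS:1000235", "total ion current chromatogram", False),
    "time": ("MS:1000595", "time array", False),
    "ms_level": ("MS:1000511", "ms level", False),
    "rt": ("MS:1000016", "scan start time", False),
    "filter_string": ("MS:1000512", "filter string", False),
    "precursor_mz": ("MS:1000744", "selected ion m/z", False),
    "precursor_charge": ("MS:1000041", "charge state", False),
    "scan_number": ("MS:1000513", "binary data array", True),
    "parent_scan": ("MS:1000513", "binary data array", True),
    "is_centroid": ("MS:1000513", "binary data array", True),
}


def annotation_for_role(catalog: TermCatalog, role: str) -> RoleAnnotation:
    """Annotation for a store dataset role, verified against *catalog*.

    Raises :class:`UnknownRoleError` for roles outside the table and
    :class:`CatalogMismatchError` when the catalog's term name disagrees with
    the table (CV version drift).
    """
    try:
        accession, name, is_fallback = ROLE_TABLE[role]
    except KeyError:
        raise UnknownRoleError(role) from None
    term = catalog.resolve(accession)
    if term.name != name:
        raise CatalogMismatchError(
            f"role {role!r}: catalog names {accession} {term.name!r}, "
            f"package expects {name!r}"
        )
    return RoleAnnotation(role=role, accession=accession, name=name, is_fallback=is_fallback)


def annotations_for_roles(
    catalog: TermCatalog, roles: Iterable[str]
) -> dict[str, RoleAnnotation]:
    return {role: annotation_for_role(catalog, role) for role in roles}
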