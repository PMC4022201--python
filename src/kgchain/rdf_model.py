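"""Triple data model and N-Triples / TSV I/O.

The in-memory representation uses bare labels (``Herb_0``, ``treatment``)
because that is how instance graphs are discussed in the literature this
package implements; on disk, bare labels are expanded to IRIs under a fixed
namespace so that the files are valid N-Triples. IRIs outside that namespace
survive a round trip unchanged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import rdflib
from rdflib.term import Literal as RDFLiteral
from rdflib.term import URIRef

#: Namespace under which bare labels are minted as IRIs when serialized.
NAMESPACE = "urn:kgchain:"


@dataclass(frozen=True, order=True)
class Resource:
    """A node of the instance graph: an IRI-backed entity or a literal value.

    ``identifier`` is the bare label (namespace stripped) for in-memory
    comparison; ``is_literal`` marks RDF literals, which may appear as triple
    objects but can never extend a chain path.
    """

    identifier: str
    is_literal: bool = False

    def __post_init__(self) -> None:
        if not self.identifier or self.identifier != self.identifier.strip():
            raise ValueError(
                f"resource identifier must be non-empty with no surrounding "
                f"whitespace: {self.identifier!r}"
            )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.identifier


@dataclass(frozen=True, order=True)
class Triple:
    """One (subject, predicate, object) assertion of the instance graph."""

    subject: Resource
    predicate: str
    object: Resource

    def __post_init__(self) -> None:
        if not self.predicate or self.predicate != self.predicate.strip():
            raise ValueError(f"predicate must be non-empty: {self.predicate!r}")

    def __iter__(self) -> Iterator:
        return iter((self.subject, self.predicate, self.object))


def triple(s: str, p: str, o: str, *, literal_object: bool = False) -> Triple:
    """Shorthand constructor from bare labels."""
    return Triple(Resource(s), p, Resource(o, is_literal=literal_object))


class TripleGraph:
    """A finite set of triples with set semantics.

    Duplicates collapse on construction and iteration order is sorted, so no
    downstream result can depend on input ordering.
    """

    __slots__ = ("_triples",)

    def __init__(self, triples: Iterable[Triple] = ()) -> None:
        self._triples = frozenset(triples)

    @property
    def triples(self) -> frozenset[Triple]:
        return self._triples

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(sorted(self._triples))

    def __contains__(self, t: Triple) -> bool:
        return t in self._triples

    def __eq__(self, other: object) -> bool:
        if isinstance(other, TripleGraph):
            return self._triples == other._triples
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._triples)

    def __or__(self, other: "TripleGraph") -> "TripleGraph":
        return TripleGraph(self._triples | other._triples)

    def __repr__(self) -> str:
        return f"TripleGraph({len(self._triples)} triples)"

    def predicates(self) -> frozenset[str]:
        return frozenset(t.predicate for t in self._triples)

    def with_predicate(self, predicate: str) -> "TripleGraph":
        return TripleGraph(t for t in self._triples if t.predicate == predicate)


class NTriplesParseError(ValueError):
    """A malformed N-Triples statement, reported with its line number."""

    def __init__(self, path: object, line_number: int, line: str) -> None:
        self.line_number = line_number
        super().__init__(
            f"{path}: malformed N-Triples statement at line {line_number}: {line!r}"
        )


def _to_resource(term: object) -> Resource:
    if isinstance(term, RDFLiteral):
        return Resource(str(term), is_literal=True)
    text = str(term)
    if text.startswith(NAMESPACE):
        text = text[len(NAMESPACE):]
    return Resource(text)


def _to_term(resource: Resource) -> URIRef | RDFLiteral:
    if resource.is_literal:
        return RDFLiteral(resource.identifier)
    if ":" in resource.identifier and not resource.identifier.startswith(NAMESPACE):
        # already an IRI (has a scheme); keep verbatim
        return URIRef(resource.identifier)
    return URIRef(NAMESPACE + resource.identifier)


def _predicate_label(term: object) -> str:
    text = str(term)
    if text.startswith(NAMESPACE):
        return text[len(NAMESPACE):]
    return text


def _parse_statement(line: str) -> Triple:
    g = rdflib.Graph()
    g.parse(data=line, format="nt")
    (s, p, o), = g
    return Triple(_to_resource(s), _predicate_label(p), _to_resource(o))


def read_ntriples(path: str | Path) -> TripleGraph:
    """Read an N-Triples file into a deduplicated :class:`TripleGraph`.

    Comment lines (``#``) and blank lines are skipped; a malformed statement
    raises :class:`NTriplesParseError` naming the offending line.
    """
    triples: list[Triple] = []
    with open(path, encoding="utf-8") as handle:
        for number, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                triples.append(_parse_statement(line))
            except Exception as exc:
                raise NTriplesParseError(path, number, line) from exc
    return TripleGraph(triples)


def write_ntriples(graph: TripleGraph, path: str | Path) -> None:
    """Serialize a graph to N-Triples, one statement per line, sorted."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(dumps_ntriples(graph))


def dumps_ntriples(graph: TripleGraph) -> str:
    """N-Triples text of ``graph`` in deterministic sorted order."""
    buffer = io.StringIO()
    for t in graph:  # TripleGraph iterates sorted
        s = _to_term(t.subject).n3()
        p = _to_term(Resource(t.predicate)).n3()
        o = _to_term(t.object).n3()
        buffer.write(f"{s} {p} {o} .\n")
    return buffer.getvalue()


def read_tsv(path: str | Path) -> TripleGraph:
    """Read a three-column subject/predicate/object TSV edge list.

    ``#`` starts a comment line; blank lines are skipped.
    """
    triples: list[Triple] = []
    with open(path, encoding="utf-8") as handle:
        for number, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: expected 3 tab-separated columns at line "
                    f"{number}, got {len(parts)}"
                )
            triples.append(triple(parts[0].strip(), parts[1].strip(), parts[2].strip()))
    return TripleGraph(triples)


def write_tsv(graph: TripleGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for t in graph:
            handle.write(f"{t.subject.identifier}\t{t.predicate}\t{t.object.identifier}\n")


def fixture_g0() -> TripleGraph:
    """The eight-triple herb-to-gene instance graph used as the worked example.

    Two herbs treat the same disease; the path continues disease → drug →
    target → protein → Entrez record → gene symbol. One extra assertion
    (``geneSequence``) lies outside every reasoning chain and must be ignored
    by all algorithms.
    """
    return TripleGraph(
        [
            triple("Herb_0", "treatment", "Disease_0"),
            triple("Disease_0", "possibleDrug", "Drug_0"),
            triple("Drug_0", "hasTarget", "Target_0"),
            triple("Target_0", "hasAccession", "Protein_0"),
            triple("Protein_0", "classifiedWith", "EntrezID_0"),
            triple("EntrezID_0", "symbol", "Gene_0"),
            triple("Herb_1", "treatment", "Disease_0"),
            triple("Target_0", "geneSequence", "Sequence_0"),
        ]
    )
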