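"""Ontology handling: OBO parsing, ancestor closure and term remapping.

Phenotype ontologies such as the Human Phenotype Ontology arrange terms in
a directed acyclic graph via ``is_a`` relations.  All semantic-similarity
computation in this package reduces to ancestor queries on that DAG, so the
central object here is :class:`OntologyDAG`, a thin validated wrapper around
a :mod:`networkx` digraph with edges pointing child -> parent.

Conventions
-----------
* Ancestor closure is **reflexive**: a term is its own ancestor.  This is
  the standard Resnik convention and makes ``sim(s, s) = IC(s)``.
* Only ``is_a`` edges define the graph; other OBO relationship types
  (``part_of`` etc.) are ignored.
* Multi-rooted ontologies are allowed and no virtual super-root is
  inserted; two terms from different rooted components then simply have no
  common ancestor.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "OntologyTerm",
    "OntologyDAG",
    "OntologyError",
    "UnknownTermError",
    "RemapError",
    "parse_obo",
]


class OntologyError(ValueError):
    """Structural problem in an ontology file (cycle, dangling parent...)."""


class UnknownTermError(KeyError):
    """A term id that is not present (or is obsolete) in the ontology."""

    def __init__(self, term_id: str, extra: str = ""):
        self.term_id = term_id
        msg = f"unknown term id {term_id!r}"
        if extra:
            msg += f" ({extra})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return self.args[0]


class RemapError(OntologyError):
    """No supported ancestor exists for a term being remapped."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term (one ``[Term]`` stanza)."""

    term_id: str
    name: str
    parent_ids: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False


class OntologyDAG:
    """Validated is-a DAG over ontology terms with reflexive ancestor closure.

    Parameters
    ----------
    terms
        Iterable of non-obsolete :class:`OntologyTerm`.  Every parent id
        must itself appear among the terms.
    obsolete_ids
        Optional ids of obsolete terms, kept only so annotation errors can
        distinguish "obsolete" from "never existed".
    alt_ids
        Mapping of secondary (``alt_id``) accessions to their primary id.
    """

    def __init__(
        self,
        terms: Iterable[OntologyTerm],
        obsolete_ids: Iterable[str] = (),
        alt_ids: Mapping[str, str] | None = None,
    ):
        self.terms: dict[str, OntologyTerm] = {}
        for term in terms:
            if term.term_id in self.terms:
                raise OntologyError(f"duplicate term id {term.term_id!r}")
            if term.obsolete:
                raise OntologyError(
                    f"obsolete term {term.term_id!r} may not enter the DAG"
                )
            self.terms[term.term_id] = term
        self.obsolete_ids = frozenset(obsolete_ids)
        self.alt_ids = dict(alt_ids or {})

        graph = nx.DiGraph()  # edges: child -> parent
        graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parent_ids:
                if parent not in self.terms:
                    raise OntologyError(
                        f"term {term.term_id!r} names unknown parent {parent!r}"
                    )
                graph.add_edge(term.term_id, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = " -> ".join(u for u, _ in nx.find_cycle(graph))
            raise OntologyError(f"ontology contains an is-a cycle: {cycle}")
        self._graph = graph
        self.root_ids = frozenset(
            t for t in self.terms if graph.out_degree(t) == 0
        )
        # reflexive ancestor closure, memoised per instance
        self._ancestors = lru_cache(maxsize=None)(self._compute_ancestors)

    # -- queries ---------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    def resolve(self, term_id: str) -> str:
        """Resolve an alt_id to its primary id; primary ids pass through."""
        primary = self.alt_ids.get(term_id, term_id)
        self._require(primary)
        return primary

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            extra = "obsolete" if term_id in self.obsolete_ids else ""
            raise UnknownTermError(term_id, extra)

    def _compute_ancestors(self, term_id: str) -> frozenset[str]:
        return frozenset(nx.descendants(self._graph, term_id)) | {term_id}

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive transitive ancestor closure of ``term_id``."""
        self._require(term_id)
        return self._ancestors(term_id)

    def common_ancestors(self, s: str, t: str) -> frozenset[str]:
        """All shared ancestors of ``s`` and ``t`` (reflexive closure)."""
        return self.ancestors(s) & self.ancestors(t)

    def remap_to_supported(self, term_id: str, supported: Iterable[str]) -> str:
        """Map a term onto the nearest supported ancestor.

        Returns ``term_id`` itself when supported; otherwise the ancestor at
        minimum is-a edge distance that lies in ``supported``.  Ties at equal
        distance break to the lexicographically smallest id so the mapping
        is deterministic.
        """
        supported = set(supported)
        self._require(term_id)
        if term_id in supported:
            return term_id
        # breadth-first over parent edges; first depth with any hit wins
        frontier = [term_id]
        seen = {term_id}
        while frontier:
            nxt: list[str] = []
            for node in frontier:
                for parent in self._graph.successors(node):
                    if parent not in seen:
                        seen.add(parent)
                        nxt.append(parent)
            hits = sorted(set(nxt) & supported)
            if hits:
                return hits[0]
            frontier = nxt
        raise RemapError(
            f"term {term_id!r} has no ancestor in the supported set"
        )


_OBSOLETE_RE = re.compile(r"^is_obsolete:\s*true", re.MULTILINE)


def _scan_obsolete_ids(path: Path) -> set[str]:
    """Ids of obsolete [Term] stanzas (obonet drops them silently)."""
    obsolete: set[str] = set()
    stanza_id: str | None = None
    in_term = False
    stanza_lines: list[str] = []

    def flush() -> None:
        if in_term and stanza_id and _OBSOLETE_RE.search("\n".join(stanza_lines)):
            obsolete.add(stanza_id)

    for line in path.read_text().splitlines():
        if line.startswith("["):
            flush()
            in_term = line.strip() == "[Term]"
            stanza_id = None
            stanza_lines = []
        elif in_term:
            stanza_lines.append(line)
            if line.startswith("id:") and stanza_id is None:
                stanza_id = line.split(":", 1)[1].strip()
    flush()
    return obsolete


def parse_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO flat file (1.2/1.4 dialect) into an :class:`OntologyDAG`.

    Non-obsolete ``[Term]`` stanzas become nodes; ``is_a`` lines become
    child -> parent edges; ``alt_id`` accessions resolve to their primary
    term.  Obsolete terms are excluded from the DAG (and hence from
    annotation) but remembered for diagnostics.

    Raises
    ------
    OntologyError
        On an is-a cycle or a parent id with no ``[Term]`` stanza.
    FileNotFoundError
        When ``path`` does not exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    multigraph = obonet.read_obo(path, ignore_obsolete=True)

    terms: list[OntologyTerm] = []
    alt_ids: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        if "name" not in data:
            children = sorted(
                c for c, p, k in multigraph.in_edges(node, keys=True) if k == "is_a"
            )
            raise OntologyError(
                f"parent id {node!r} (referenced by {', '.join(children)}) "
                "has no [Term] stanza"
            )
        parents = frozenset(
            p for _, p, key in multigraph.out_edges(node, keys=True) if key == "is_a"
        )
        terms.append(OntologyTerm(node, data["name"], parents))
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    return OntologyDAG(terms, _scan_obsolete_ids(path), alt_ids)
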