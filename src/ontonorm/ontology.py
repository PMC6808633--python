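"""Ontology model and OBO 1.2 flat-file I/O.

The normalization pipeline only needs the subsumption skeleton of an
ontology: concept identifiers, their human-readable labels and synonyms,
and the directed acyclic graph of *is-a* edges.  Everything downstream
(ancestry vectors, decay weighting, Wang similarity) is defined on the
reflexive-transitive closure of the parent relation, so this module also
provides the two closure queries, :func:`ancestors` and
:func:`min_edge_distance`.

Edge-distance convention: ``d(c, c) = 0`` and ``d(c, direct parent) = 1``,
i.e. *d* counts parent edges on the shortest directed path.  On a DAG an
ancestor may be reachable by several paths; the minimum is used, which is
deterministic and reduces to the unique path length on trees.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Ontology",
    "OboParseError",
    "OntologyValidationError",
    "read_obo",
    "write_obo",
    "ancestors",
    "min_edge_distance",
]


class OboParseError(ValueError):
    """Raised for a malformed OBO stanza; the message names the line."""


class OntologyValidationError(ValueError):
    """Raised when the parsed structure violates an Ontology invariant."""


@dataclass(frozen=True)
class Ontology:
    """A validated is-a DAG over opaque concept identifiers.

    Attributes
    ----------
    concepts
        All concept identifiers, e.g. ``"OBT:000001"``.
    labels
        Concept -> preferred name.
    synonyms
        Concept -> list of synonym strings (possibly empty).
    parents
        Concept -> set of direct is-a parents.
    extra_edges
        Non-subsumption relationships (e.g. ``sameAs``) kept only for the
        graph-embedding builder; never used by ancestry or similarity.
    """

    concepts: frozenset[str]
    labels: Mapping[str, str]
    synonyms: Mapping[str, list[str]]
    parents: Mapping[str, frozenset[str]]
    extra_edges: frozenset[tuple[str, str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for c, ps in self.parents.items():
            missing = ps - self.concepts
            if missing:
                raise OntologyValidationError(
                    f"concept {c!r} references unknown parents: {sorted(missing)}"
                )
        cycle = _find_cycle(self.parents)
        if cycle:
            raise OntologyValidationError(
                "is_a relation contains a cycle: " + " -> ".join(cycle)
            )
        if not self.concepts:
            raise OntologyValidationError("ontology has no concepts")

    @property
    def roots(self) -> frozenset[str]:
        """Concepts with no parents; non-empty for any valid DAG."""
        return frozenset(c for c in self.concepts if not self.parents.get(c))

    @property
    def order(self) -> list[str]:
        """Fixed lexicographic concept order used for vector dimensions."""
        return sorted(self.concepts)

    def children(self, c: str) -> set[str]:
        return {x for x in self.concepts if c in self.parents.get(x, ())}

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, c: object) -> bool:
        return c in self.concepts


def _find_cycle(parents: Mapping[str, Iterable[str]]) -> list[str] | None:
    """Iterative three-color DFS; returns one directed cycle if present."""
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {c: WHITE for c in parents}
    for start in parents:
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, Iterable[str]]] = [(start, iter(parents.get(start, ())))]
        color[start] = GRAY
        path = [start]
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color.get(nxt, WHITE) == GRAY:
                    i = path.index(nxt)
                    return path[i:] + [nxt]
                if color.get(nxt, WHITE) == WHITE:
                    color[nxt] = GRAY
                    path.append(nxt)
                    stack.append((nxt, iter(parents.get(nxt, ()))))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                path.pop()
                stack.pop()
    return None


# OBO synonym lines look like:  synonym: "some text" EXACT []
_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')


def read_obo(path) -> Ontology:
    """Parse an OBO 1.2 flat file into an :class:`Ontology`.

    Only ``[Term]`` stanzas are read; ``id``, ``name``, ``synonym``,
    ``is_a``, ``relationship`` and ``is_obsolete`` tags are interpreted,
    everything else is ignored.  Obsolete terms are skipped entirely.

    Raises
    ------
    OboParseError
        On a malformed stanza, naming the offending line number.
    OntologyValidationError
        If the is_a edges contain a cycle or reference unknown concepts.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    stanzas: list[dict] = []
    current: dict | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            current = {"_type": line, "_line": lineno} if line == "[Term]" else None
            if line == "[Term]":
                stanzas.append(current)
            continue
        if current is None:
            continue  # header or non-Term stanza
        if ":" not in line:
            raise OboParseError(f"line {lineno}: expected 'tag: value', got {raw!r}")
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.split("!")[0].strip()  # strip trailing comments
        if tag == "id":
            current["id"] = value
        elif tag == "name":
            current["name"] = value
        elif tag == "is_a":
            current.setdefault("is_a", []).append(value)
        elif tag == "synonym":
            m = _SYNONYM_RE.match(value)
            if not m:
                raise OboParseError(
                    f"line {lineno}: synonym value must start with a quoted string: {raw!r}"
                )
            current.setdefault("synonyms", []).append(m.group("text"))
        elif tag == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(
                    f"line {lineno}: relationship needs 'type target': {raw!r}"
                )
            current.setdefault("relationships", []).append((parts[0], parts[1]))
        elif tag == "is_obsolete":
            current["obsolete"] = value.lower() == "true"

    concepts: set[str] = set()
    labels: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    parents: dict[str, set[str]] = {}
    extra: set[tuple[str, str, str]] = set()
    for st in stanzas:
        if st.get("obsolete"):
            continue
        if "id" not in st:
            raise OboParseError(f"line {st['_line']}: [Term] stanza without an id")
        cid = st["id"]
        concepts.add(cid)
        labels[cid] = st.get("name", cid)
        synonyms[cid] = list(st.get("synonyms", []))
        parents[cid] = set(st.get("is_a", []))
        for rel, target in st.get("relationships", []):
            extra.add((cid, rel, target))

    # relationship targets to obsolete/unknown terms are dropped silently
    extra = {(s, r, t) for (s, r, t) in extra if t in concepts}
    return Ontology(
        concepts=frozenset(concepts),
        labels=labels,
        synonyms=synonyms,
        parents={c: frozenset(p) for c, p in parents.items()},
        extra_edges=frozenset(extra),
    )


def write_obo(onto: Ontology, path) -> None:
    """Write the same OBO dialect :func:`read_obo` reads (round-trip safe)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for c in onto.order:
            fh.write("\n[Term]\n")
            fh.write(f"id: {c}\n")
            fh.write(f"name: {onto.labels.get(c, c)}\n")
            for syn in onto.synonyms.get(c, []):
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for p in sorted(onto.parents.get(c, ())):
                fh.write(f"is_a: {p}\n")
            for s, rel, t in sorted(onto.extra_edges):
                if s == c:
                    fh.write(f"relationship: {rel} {t}\n")


def ancestors(onto: Ontology, c: str) -> frozenset[str]:
    """Reflexive-transitive closure of the parent relation from ``c``."""
    if c not in onto.concepts:
        raise KeyError(f"unknown concept: {c!r}")
    seen = {c}
    frontier = deque([c])
    while frontier:
        node = frontier.popleft()
        for p in onto.parents.get(node, ()):
            if p not in seen:
                seen.add(p)
                frontier.append(p)
    return frozenset(seen)


def min_edge_distance(onto: Ontology, c: str, a: str) -> int:
    """Minimum number of parent edges on a directed path from ``c`` to ``a``.

    ``d(c, c) == 0`` and ``d(c, direct parent) == 1``.  Raises
    :class:`ValueError` if ``a`` is not an ancestor of ``c``.
    """
    if c not in onto.concepts:
        raise KeyError(f"unknown concept: {c!r}")
    if a not in onto.concepts:
        raise KeyError(f"unknown concept: {a!r}")
    dists = ancestor_distances(onto, c)
    if a not in dists:
        raise ValueError(f"{a!r} is not an ancestor of {c!r}")
    return dists[a]


def ancestor_distances(onto: Ontology, c: str) -> dict[str, int]:
    """BFS upward from ``c``: ancestor -> minimum edge distance."""
    dists = {c: 0}
    frontier = deque([c])
    while frontier:
        node = frontier.popleft()
        for p in onto.parents.get(node, ()):
            if p not in dists:
                dists[p] = dists[node] + 1
                frontier.append(p)
    return dists
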