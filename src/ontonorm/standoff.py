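"""BioNLP-ST standoff annotation I/O (.a1 entities, .a2 normalizations).

Offsets follow the standoff convention: 0-based, half-open, newlines count
as one character.  Discontinuous mentions carry several ``start end``
fragments separated by ``;``.

.a1 line:   ``T1<TAB>Habitat 10 15<TAB>soils``
.a2 line:   ``N1<TAB>OntoBiotope Annotation:T1 Referent:OBT:000001``
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .projection import Prediction

__all__ = [
    "Mention",
    "Normalization",
    "StandoffParseError",
    "read_standoff",
    "write_a1",
    "write_a2",
    "write_predictions",
]


class StandoffParseError(ValueError):
    """Malformed standoff line; message names the file and line number."""


@dataclass(frozen=True)
class Mention:
    """An entity mention with its character span(s) in the source text."""

    entity_id: str  # e.g. "T1"
    type: str  # e.g. "Habitat"
    spans: tuple[tuple[int, int], ...]  # 0-based half-open fragments
    surface: str
    doc_id: str = ""

    def __post_init__(self) -> None:
        if not self.spans:
            raise ValueError(f"mention {self.entity_id} has no spans")
        for s, e in self.spans:
            if not 0 <= s < e:
                raise ValueError(
                    f"mention {self.entity_id}: invalid span ({s}, {e})"
                )


@dataclass(frozen=True)
class Normalization:
    """Binding of a mention to an ontology concept."""

    norm_id: str  # e.g. "N1"
    entity_id: str  # the Tn it annotates
    resource: str  # e.g. "OntoBiotope"
    referent: str  # concept identifier


def _parse_a1_line(line: str, path, lineno: int) -> Mention:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 3 or not parts[0].startswith("T"):
        raise StandoffParseError(f"{path}:{lineno}: malformed .a1 line: {line!r}")
    tid, typespans, surface = parts
    fields = typespans.split(" ", 1)
    if len(fields) != 2:
        raise StandoffParseError(f"{path}:{lineno}: missing offsets: {line!r}")
    mtype, span_str = fields
    spans = []
    for frag in span_str.split(";"):
        try:
            s, e = (int(x) for x in frag.split())
        except ValueError as exc:
            raise StandoffParseError(
                f"{path}:{lineno}: bad span fragment {frag!r}"
            ) from exc
        spans.append((s, e))
    return Mention(entity_id=tid, type=mtype, spans=tuple(spans), surface=surface)


def _parse_a2_line(line: str, path, lineno: int) -> Normalization:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 2 or not parts[0].startswith("N"):
        raise StandoffParseError(f"{path}:{lineno}: malformed .a2 line: {line!r}")
    nid, rest = parts
    fields = rest.split()
    if len(fields) != 3:
        raise StandoffParseError(f"{path}:{lineno}: expected 3 fields: {line!r}")
    resource = fields[0]
    try:
        ann = next(f for f in fields if f.startswith("Annotation:"))
        ref = next(f for f in fields if f.startswith("Referent:"))
    except StopIteration as exc:
        raise StandoffParseError(
            f"{path}:{lineno}: missing Annotation:/Referent: field: {line!r}"
        ) from exc
    return Normalization(
        norm_id=nid,
        entity_id=ann.split(":", 1)[1],
        resource=resource,
        referent=ref.split(":", 1)[1],
    )


def read_standoff(
    a1_path, a2_path=None
) -> tuple[list[Mention], list[Normalization]]:
    """Parse .a1 (and optionally .a2) files.

    A Referent pointing to an entity id absent from the .a1 file raises
    :class:`StandoffParseError`.
    """
    mentions: list[Mention] = []
    with open(a1_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                mentions.append(_parse_a1_line(line, a1_path, lineno))
    normalizations: list[Normalization] = []
    if a2_path is not None:
        known = {m.entity_id for m in mentions}
        with open(a2_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                norm = _parse_a2_line(line, a2_path, lineno)
                if norm.entity_id not in known:
                    raise StandoffParseError(
                        f"{a2_path}:{lineno}: Referent to unknown entity "
                        f"{norm.entity_id!r}"
                    )
                normalizations.append(norm)
    return mentions, normalizations


def write_a1(mentions: list[Mention], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            spans = ";".join(f"{s} {e}" for s, e in m.spans)
            fh.write(f"{m.entity_id}\t{m.type} {spans}\t{m.surface}\n")


def write_a2(norms: list[Normalization], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in norms:
            fh.write(
                f"{n.norm_id}\t{n.resource} Annotation:{n.entity_id} "
                f"Referent:{n.referent}\n"
            )


def write_predictions(
    preds: list[Prediction], resource_name: str, path
) -> list[str]:
    """Write top-1 predictions as .a2 normalization lines.

    Each prediction's ``mention`` field must be the entity id ("Tn") it
    normalizes.  Mentions with status ``no_vector`` produce no line; their
    entity ids are returned as the skip list for the caller to log.
    """
    skipped: list[str] = []
    norms: list[Normalization] = []
    for pred in preds:
        if pred.status != "ok" or not pred.ranking:
            skipped.append(pred.mention)
            continue
        norms.append(
            Normalization(
                norm_id=f"N{len(norms) + 1}",
                entity_id=pred.mention,
                resource=resource_name,
                referent=pred.ranking[0][0],
            )
        )
    write_a2(norms, path)
    return skipped
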