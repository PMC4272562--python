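"""Read and write the recommended ``metadata.rdf`` annotations.

The archive convention annotates the archive itself (subject ``"."``) and,
optionally, individual entries (subject = entry location) with:

* Dublin Core terms — ``description``, ``creator``, ``created``,
  ``modified`` — with dates encoded under the W3C date-time profile
  (W3CDTF, a constrained ISO 8601: ``YYYY[-MM[-DD[Thh:mm[:ss[.s]]TZD]]]``);
* the W3C vCard ontology for people — ``hasName`` (``given-name``,
  ``family-name``), ``hasEmail``, ``organization-name``.

The serialization is RDF/XML with *relative* subject URIs, so the metadata
stays meaningful wherever the archive travels.  Unrecognized triples found
on a known subject are carried through reads and writes opaquely so that
third-party annotations survive a round trip.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Collection, Iterable, Sequence

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF

from .errors import InvariantViolationError, RdfParseError, TimestampError
from .report import Finding, Severity

DCTERMS = Namespace("http://purl.org/dc/terms/")
VCARD = Namespace("http://www.w3.org/2006/vcard/ns#")

# Internal base used to turn the archive's relative subjects into absolute
# URIs while a graph is in memory; never appears in serialized output.
_BASE = "http://omex-archive.invalid/"

_W3CDTF_RE = re.compile(
    r"^(?P<y>\d{4})"
    r"(?:-(?P<mo>\d{2})"
    r"(?:-(?P<d>\d{2})"
    r"(?:T(?P<h>\d{2}):(?P<mi>\d{2})"
    r"(?::(?P<s>\d{2})(?P<frac>\.\d+)?)?"
    r"(?P<tz>Z|[+-]\d{2}:\d{2})?"
    r")?)?)?$"
)


@dataclass(frozen=True)
class W3CDTF:
    """A timestamp under the W3C date-time profile.

    Keeps the lexical form exactly as read (so round trips preserve the
    original literal) alongside the resolved instant used for comparisons.
    """

    raw: str
    instant: datetime

    @classmethod
    def parse(cls, text: str) -> "W3CDTF":
        m = _W3CDTF_RE.match(text.strip())
        if not m:
            raise TimestampError(f"not a W3CDTF date: {text!r}")
        g = m.groupdict()
        try:
            dt = datetime(
                int(g["y"]),
                int(g["mo"] or 1),
                int(g["d"] or 1),
                int(g["h"] or 0),
                int(g["mi"] or 0),
                int(g["s"] or 0),
                int(round(float(g["frac"] or 0) * 1e6)),
            )
        except ValueError as exc:
            raise TimestampError(f"invalid date components in {text!r}") from exc
        tz = g["tz"]
        if tz == "Z":
            dt = dt.replace(tzinfo=timezone.utc)
        elif tz:
            sign = 1 if tz[0] == "+" else -1
            offset = timedelta(hours=int(tz[1:3]), minutes=int(tz[4:6]))
            dt = dt.replace(tzinfo=timezone(sign * offset))
        else:
            if g["h"] is not None:
                warnings.warn(
                    f"timestamp {text!r} has no timezone; interpreting as UTC",
                    stacklevel=2,
                )
            dt = dt.replace(tzinfo=timezone.utc)
        return cls(text.strip(), dt)

    @classmethod
    def from_datetime(cls, dt: datetime) -> "W3CDTF":
        if dt.tzinfo is None:
            dt = dt.replace(tzinfo=timezone.utc)
        raw = dt.isoformat()
        if raw.endswith("+00:00"):
            raw = raw[:-6] + "Z"
        return cls(raw, dt)

    @classmethod
    def coerce(cls, value: "W3CDTF | datetime | str") -> "W3CDTF":
        if isinstance(value, W3CDTF):
            return value
        if isinstance(value, datetime):
            return cls.from_datetime(value)
        return cls.parse(value)

    def __str__(self) -> str:
        return self.raw


@dataclass(frozen=True)
class VCardPerson:
    """A person annotation; at least one name component must be non-empty."""

    family_name: str = ""
    given_name: str = ""
    email: str | None = None
    organization_name: str | None = None

    def __post_init__(self):
        if not (self.family_name or self.given_name):
            raise InvariantViolationError(
                "a vCard person needs a family name or a given name"
            )


@dataclass
class MetadataRecord:
    """Annotations attached to the archive (``about="."``) or to one entry.

    ``extra`` holds RDF triples read from a document that use vocabulary this
    module does not model; they are re-emitted verbatim on write.
    """

    about: str = "."
    description: str | None = None
    creators: list[VCardPerson] = field(default_factory=list)
    created: W3CDTF | None = None
    modified: list[W3CDTF] = field(default_factory=list)
    extra: list[tuple] = field(default_factory=list)

    def check(self) -> None:
        if self.created is not None:
            for mod in self.modified:
                if mod.instant < self.created.instant:
                    raise InvariantViolationError(
                        f"record {self.about!r}: modified date {mod} precedes "
                        f"creation date {self.created}"
                    )

    def is_empty(self) -> bool:
        return (
            self.description is None
            and not self.creators
            and self.created is None
            and not self.modified
            and not self.extra
        )


def _subject_to_about(subject: URIRef) -> str:
    s = str(subject)
    if s == _BASE or s == _BASE.rstrip("/"):
        return "."
    if s.startswith(_BASE):
        return s[len(_BASE):]
    return s


def _about_to_subject(about: str) -> URIRef:
    if about == ".":
        return URIRef(_BASE)
    if re.match(r"^[A-Za-z][A-Za-z0-9+.\-]*://", about):
        return URIRef(about)
    return URIRef(_BASE + about)


def _parse_timestamp_objects(graph: Graph, subject, pred, consumed) -> list[W3CDTF]:
    """Dates appear either as direct literals or nested under a dcterms:W3CDTF node."""
    out = []
    for obj in graph.objects(subject, pred):
        consumed.add((subject, pred, obj))
        if isinstance(obj, Literal):
            out.append(W3CDTF.parse(str(obj)))
            continue
        lit = None
        for t in graph.triples((obj, None, None)):
            consumed.add(t)
            if t[1] == DCTERMS.W3CDTF:
                lit = str(t[2])
        if lit is None:
            raise TimestampError(
                f"date node under {pred} carries no dcterms:W3CDTF literal"
            )
        out.append(W3CDTF.parse(lit))
    return out


def _parse_creator(graph: Graph, node, consumed) -> VCardPerson | None:
    family = given = ""
    email = org = None
    for t in graph.triples((node, None, None)):
        consumed.add(t)
        pred, obj = t[1], t[2]
        if pred == VCARD.hasName:
            for t2 in graph.triples((obj, None, None)):
                consumed.add(t2)
                if t2[1] == VCARD["family-name"]:
                    family = str(t2[2])
                elif t2[1] == VCARD["given-name"]:
                    given = str(t2[2])
        elif pred == VCARD["family-name"]:
            family = str(obj)
        elif pred == VCARD["given-name"]:
            given = str(obj)
        elif pred == VCARD.hasEmail:
            email = str(obj)
            if email.startswith("mailto:"):
                email = email[len("mailto:"):]
        elif pred == VCARD["organization-name"]:
            org = str(obj)
    if not (family or given):
        return None
    return VCardPerson(family, given, email, org)


def read_metadata(data: bytes) -> list[MetadataRecord]:
    """Parse an RDF metadata document into one record per subject.

    RDF/XML is the recommended serialization and is tried first; Turtle is
    accepted as a fallback when the payload is plainly not XML.

    Raises
    ------
    RdfParseError, TimestampError
    """
    graph = Graph()
    try:
        graph.parse(data=data, format="xml", publicID=_BASE)
    except Exception as xml_exc:
        try:
            graph.parse(data=data, format="turtle", publicID=_BASE)
        except Exception:
            raise RdfParseError(f"cannot parse metadata as RDF: {xml_exc}") from xml_exc

    consumed: set[tuple] = set()
    # Subjects that are themselves structural objects (creator nodes, name
    # nodes) are not archive subjects, even when they are IRIs.
    structural_objects = {
        o for _, p, o in graph if p in (DCTERMS.creator, VCARD.hasName)
    }
    subjects = []
    for s in graph.subjects(unique=True):
        if isinstance(s, URIRef) and s not in structural_objects:
            subjects.append(s)
    subjects.sort()

    records = []
    for subject in subjects:
        rec = MetadataRecord(about=_subject_to_about(subject))
        desc_triples = list(graph.triples((subject, DCTERMS.description, None)))
        if desc_triples:
            rec.description = str(desc_triples[0][2])
            consumed.update(desc_triples)
        for creator_node in graph.objects(subject, DCTERMS.creator):
            consumed.add((subject, DCTERMS.creator, creator_node))
            person = _parse_creator(graph, creator_node, consumed)
            if person is not None:
                rec.creators.append(person)
        created = _parse_timestamp_objects(graph, subject, DCTERMS.created, consumed)
        if created:
            rec.created = created[0]
            if len(created) > 1:
                warnings.warn(
                    f"multiple creation dates on {rec.about!r}; keeping the first",
                    stacklevel=2,
                )
        rec.modified = _parse_timestamp_objects(graph, subject, DCTERMS.modified, consumed)
        records.append(rec)

    # Preserve anything we did not model, attached to its owning record.
    by_subject = {_about_to_subject(r.about): r for r in records}
    leftovers = [t for t in graph if t not in consumed]
    orphans = 0
    for t in leftovers:
        owner = by_subject.get(t[0])
        if owner is not None:
            owner.extra.append(t)
            owner.extra.extend(_bnode_closure(graph, t[2], consumed))
        else:
            orphans += 1
    if orphans:
        warnings.warn(
            f"dropping {orphans} metadata triple(s) with no recognizable subject",
            stacklevel=2,
        )
    return [r for r in records if not r.is_empty() or r.about == "."]


def _bnode_closure(graph: Graph, node, consumed) -> list[tuple]:
    out = []
    if isinstance(node, BNode):
        for t in graph.triples((node, None, None)):
            if t not in consumed:
                consumed.add(t)
                out.append(t)
                out.extend(_bnode_closure(graph, t[2], consumed))
    return out


def write_metadata(
    records: Sequence[MetadataRecord],
    locations: Collection[str] | None = None,
) -> bytes:
    """Serialize records as RDF/XML with relative subject URIs.

    When *locations* is given (normally the manifest's locations), every
    record's ``about`` must be ``"."`` or one of them.  Output is
    deterministic: a given record list always serializes to the same bytes
    (the serializer is hand-rolled on lxml because generic RDF writers do
    not guarantee stable blank-node layout).

    Raises
    ------
    InvariantViolationError
        On an unknown ``about`` location or a modified date preceding the
        creation date.
    """
    triples: list[tuple] = []
    counter = iter(range(10**9))

    def bnode() -> BNode:
        return BNode(f"n{next(counter)}")

    for rec in records:
        rec.check()
        if locations is not None and rec.about != "." and rec.about not in locations:
            raise InvariantViolationError(
                f"metadata subject {rec.about!r} is not a manifest location"
            )
        subject = _about_to_subject(rec.about)
        if rec.description is not None:
            triples.append((subject, DCTERMS.description, Literal(rec.description)))
        for person in rec.creators:
            cnode = bnode()
            triples.append((subject, DCTERMS.creator, cnode))
            name = bnode()
            triples.append((cnode, VCARD.hasName, name))
            if person.family_name:
                triples.append((name, VCARD["family-name"], Literal(person.family_name)))
            if person.given_name:
                triples.append((name, VCARD["given-name"], Literal(person.given_name)))
            if person.email:
                triples.append((cnode, VCARD.hasEmail, URIRef("mailto:" + person.email)))
            if person.organization_name:
                triples.append(
                    (cnode, VCARD["organization-name"], Literal(person.organization_name))
                )
        if rec.created is not None:
            node = bnode()
            triples.append((subject, DCTERMS.created, node))
            triples.append((node, DCTERMS.W3CDTF, Literal(rec.created.raw)))
        for mod in rec.modified:
            node = bnode()
            triples.append((subject, DCTERMS.modified, node))
            triples.append((node, DCTERMS.W3CDTF, Literal(mod.raw)))
        triples.extend(rec.extra)
    return _serialize_rdfxml(triples)


_RDF_NS = str(RDF)


def _split_qname(uri: str) -> tuple[str, str]:
    for i in range(len(uri) - 1, -1, -1):
        if uri[i] in "#/":
            ns, local = uri[: i + 1], uri[i + 1:]
            if local and re.match(r"^[A-Za-z_][\w.\-]*$", local):
                return ns, local
            break
    raise InvariantViolationError(f"cannot derive an XML qualified name from {uri!r}")


def _serialize_rdfxml(triples: Sequence[tuple]) -> bytes:
    """Deterministic RDF/XML emitter for an ordered triple list.

    Blank nodes referenced exactly once are nested inline; any other blank
    node is linked through ``rdf:nodeID``.  Namespace prefixes are assigned
    in first-use order (``dcterms`` and ``vCard`` are fixed).
    """
    from lxml import etree

    nsmap: dict[str, str] = {"rdf": _RDF_NS}
    prefixes = {_RDF_NS: "rdf", str(DCTERMS): "dcterms", str(VCARD): "vCard"}

    def qtag(pred: URIRef) -> str:
        ns, local = _split_qname(str(pred))
        if ns not in prefixes:
            prefixes[ns] = f"ns{len(prefixes)}"
        nsmap[prefixes[ns]] = ns
        return f"{{{ns}}}{local}"

    by_subject: dict = {}
    object_refs: dict = {}
    order: list = []
    for s, p, o in triples:
        qtag(p)  # register namespaces up-front so the root declares them all
        if s not in by_subject:
            by_subject[s] = []
            order.append(s)
        by_subject[s].append((p, o))
        if isinstance(o, BNode):
            object_refs[o] = object_refs.get(o, 0) + 1

    def relativize(uri: str) -> str:
        if uri == _BASE or uri == _BASE.rstrip("/"):
            return "."
        if uri.startswith(_BASE):
            return uri[len(_BASE):]
        return uri

    def fill(parent, subject, inline_done: set) -> None:
        for p, o in by_subject.get(subject, ()):
            el = etree.SubElement(parent, qtag(p))
            if isinstance(o, Literal):
                el.text = str(o)
                if o.language:
                    el.set("{http://www.w3.org/XML/1998/namespace}lang", o.language)
                elif o.datatype:
                    el.set(f"{{{_RDF_NS}}}datatype", str(o.datatype))
            elif isinstance(o, BNode):
                if object_refs.get(o) == 1 and o not in inline_done:
                    inline_done.add(o)
                    desc = etree.SubElement(el, f"{{{_RDF_NS}}}Description")
                    fill(desc, o, inline_done)
                else:
                    el.set(f"{{{_RDF_NS}}}nodeID", str(o))
            else:
                el.set(f"{{{_RDF_NS}}}resource", relativize(str(o)))

    root = etree.Element(f"{{{_RDF_NS}}}RDF", nsmap=nsmap)
    inline_done: set = set()
    for subject in order:
        if isinstance(subject, BNode) and (
            subject in inline_done or object_refs.get(subject) == 1
        ):
            continue  # rendered (or will be) inline at its point of use
        desc = etree.SubElement(root, f"{{{_RDF_NS}}}Description")
        if isinstance(subject, BNode):
            desc.set(f"{{{_RDF_NS}}}nodeID", str(subject))
        else:
            desc.set(f"{{{_RDF_NS}}}about", relativize(str(subject)))
        fill(desc, subject, inline_done)
    # nsmap on the constructed root is fixed at creation; rebuild with the
    # final prefix table so late-registered namespaces are declared too.
    final = etree.Element(f"{{{_RDF_NS}}}RDF", nsmap=nsmap)
    for child in root:
        final.append(child)
    return etree.tostring(
        final, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


MISSING_CREATED = "MISSING_CREATED"
MISSING_MODIFIED = "MISSING_MODIFIED"
MISSING_CREATOR = "MISSING_CREATOR"


def check_minimal_metadata(records: Iterable[MetadataRecord]) -> list[Finding]:
    """Check the minimum recommended archive annotations.

    The archive record (``about="."``) should state when the archive was
    created, when it was last updated, and who created it.  Returns one
    finding per missing item (0-3); an empty list means the minimum is met.
    """
    archive = next((r for r in records if r.about == "."), None)
    findings = []
    if archive is None or archive.created is None:
        findings.append(
            Finding(Severity.WARNING, MISSING_CREATED, ".", "no archive creation date")
        )
    if archive is None or not archive.modified:
        findings.append(
            Finding(Severity.WARNING, MISSING_MODIFIED, ".", "no date of last update")
        )
    if archive is None or not archive.creators:
        findings.append(
            Finding(Severity.WARNING, MISSING_CREATOR, ".", "no archive creator")
        )
    return findings
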