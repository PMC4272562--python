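"""Domain model of a COMBINE Archive.

A COMBINE Archive is a ZIP container whose content is described by a flat
manifest.  Each manifest entry names a file by a *relative* location inside
the archive, declares its format with an absolute URI, and may carry a
boolean ``master`` flag marking the document a tool should open first.

Format URIs come in three flavours:

* COMBINE specification identifiers under the Identifiers.org prefix
  (``http://identifiers.org/combine.specifications/...``), used for the
  community's own standards (SBML, SED-ML, CellML, SBOL, ...);
* Internet media types expressed as URIs under
  ``http://purl.org/NET/mediatypes/`` (e.g. ``.../application/pdf``);
* unregistered media types, which use the ``type/x.name`` convention
  (e.g. ``.../application/x.copasi``).

This module is pure logic: no I/O, no XML.  Everything here is shared by the
manifest, metadata, container and validation layers.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import (
    AbsolutePathError,
    DuplicateLocationError,
    InvariantViolationError,
    MalformedURIError,
    PathEscapeError,
)

#: Identifiers.org prefix naming formats specified by COMBINE.
COMBINE_SPEC_PREFIX = "http://identifiers.org/combine.specifications/"

#: URI prefix turning an Internet media type into a resolvable URI.
MEDIATYPE_PREFIX = "http://purl.org/NET/mediatypes/"

#: Format URI of the OMEX container specification (used for the "." self-entry).
OMEX_FORMAT = COMBINE_SPEC_PREFIX + "omex"

#: Format URI of the OMEX manifest document.
OMEX_MANIFEST_FORMAT = COMBINE_SPEC_PREFIX + "omex-manifest"

#: Format URI of the OMEX metadata document.
OMEX_METADATA_FORMAT = COMBINE_SPEC_PREFIX + "omex-metadata"

#: Fixed name of the mandatory manifest at the archive root.
MANIFEST_LOCATION = "manifest.xml"

#: Conventional name of the metadata file at the archive root.
METADATA_LOCATION = "metadata.rdf"

# IANA top-level media types recognized when deciding whether a media-type URI
# follows the unregistered `type/x.name` convention.  Pinned here rather than
# fetched: registration status of subtypes is deliberately not checked.
IANA_TOP_LEVEL_TYPES = frozenset(
    {
        "application",
        "audio",
        "example",
        "font",
        "haptics",
        "image",
        "message",
        "model",
        "multipart",
        "text",
        "video",
    }
)

_ABSOLUTE_URI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:\S+$")
_UNREGISTERED_NAME_RE = re.compile(r"^([a-z0-9\-]+)/x\.[A-Za-z0-9][A-Za-z0-9!#$&^_.+\-]*$")
_SCHEME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:")


class FormatCategory(str, enum.Enum):
    """Classification of a format URI."""

    COMBINE_SPEC = "combine_spec"
    MEDIA_TYPE = "media_type"
    UNREGISTERED_MEDIA_TYPE = "unregistered_media_type"


@dataclass(frozen=True)
class FormatURI:
    """A classified format identifier.

    Parameters
    ----------
    uri:
        Syntactically valid absolute URI naming the format.
    category:
        One of :class:`FormatCategory`; derived from the URI by
        :func:`classify_format`.
    """

    uri: str
    category: FormatCategory

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.uri

    @property
    def media_type(self) -> str | None:
        """The bare ``type/subtype`` name for media-type URIs, else ``None``."""
        if self.uri.startswith(MEDIATYPE_PREFIX):
            return self.uri[len(MEDIATYPE_PREFIX):]
        return None

    def is_combine_spec(self, name: str) -> bool:
        """True if this is the COMBINE spec *name* (any level/version suffix)."""
        prefix = COMBINE_SPEC_PREFIX + name
        rest = self.uri[len(prefix):] if self.uri.startswith(prefix) else None
        return rest is not None and (rest == "" or rest[0] == ".")


def classify_format(uri: str) -> FormatURI:
    """Classify a format URI into one of the three recognized categories.

    Raises
    ------
    MalformedURIError
        If *uri* is empty or not an absolute URI.
    """
    if not uri or not _ABSOLUTE_URI_RE.match(uri):
        raise MalformedURIError(f"not an absolute URI: {uri!r}")
    if uri.startswith(COMBINE_SPEC_PREFIX):
        return FormatURI(uri, FormatCategory.COMBINE_SPEC)
    if uri.startswith(MEDIATYPE_PREFIX):
        name = uri[len(MEDIATYPE_PREFIX):]
        m = _UNREGISTERED_NAME_RE.match(name)
        if m and m.group(1) in IANA_TOP_LEVEL_TYPES:
            return FormatURI(uri, FormatCategory.UNREGISTERED_MEDIA_TYPE)
    return FormatURI(uri, FormatCategory.MEDIA_TYPE)


def normalize_location(raw: str) -> str:
    """Normalize a relative archive location to canonical form.

    ``"."`` (the archive itself) is preserved.  A leading ``"./"`` is
    stripped, empty and ``"."`` segments are dropped, and ``".."`` segments
    are resolved.  Only forward slashes separate segments.

    Raises
    ------
    AbsolutePathError
        If *raw* carries a URI scheme or a leading ``/``.
    PathEscapeError
        If resolution would leave the archive root.
    """
    if not raw:
        raise AbsolutePathError("empty location")
    if raw == ".":
        return "."
    if raw.startswith("/"):
        raise AbsolutePathError(f"location must be relative, got {raw!r}")
    if _SCHEME_RE.match(raw):
        raise AbsolutePathError(f"location must not carry a URI scheme: {raw!r}")
    out: list[str] = []
    for seg in raw.split("/"):
        if seg in ("", "."):
            continue
        if seg == "..":
            if not out:
                raise PathEscapeError(f"location escapes the archive root: {raw!r}")
            out.pop()
        else:
            out.append(seg)
    return "/".join(out) or "."


@dataclass(frozen=True)
class ContentEntry:
    """One manifest ``<content>`` record.

    The three fields map one-to-one onto the three XML attributes of a
    ``<content>`` element: ``location``, ``format`` and ``master``.
    """

    location: str
    format: FormatURI
    master: bool = False

    @property
    def normalized_location(self) -> str:
        """Canonical form of :attr:`location`; may raise a LocationError."""
        return normalize_location(self.location)

    @classmethod
    def create(cls, location: str, format: FormatURI | str, master: bool = False) -> "ContentEntry":
        """Build an entry with eager location normalization and format classification."""
        fmt = classify_format(format) if isinstance(format, str) else format
        return cls(normalize_location(location), fmt, bool(master))


@dataclass
class Manifest:
    """Ordered collection of content entries describing an archive.

    A valid manifest has at least one entry — the one for the archive itself,
    at location ``"."`` — and no two entries sharing a normalized location.
    Construction is permissive (the validator reports defects on read paths);
    :meth:`check` enforces the invariants for writer paths.
    """

    entries: list[ContentEntry] = field(default_factory=list)

    def __iter__(self) -> Iterator[ContentEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def locations(self) -> list[str]:
        """Normalized locations in manifest order (non-normalizable ones verbatim)."""
        out = []
        for e in self.entries:
            try:
                out.append(e.normalized_location)
            except Exception:
                out.append(e.location)
        return out

    def get(self, location: str) -> ContentEntry | None:
        """Entry whose normalized location equals normalized *location*, or None."""
        target = normalize_location(location)
        for e in self.entries:
            try:
                if e.normalized_location == target:
                    return e
            except Exception:
                continue
        return None

    def payload_entries(self) -> list[ContentEntry]:
        """Entries that denote payload files (everything but "." and the manifest)."""
        out = []
        for e in self.entries:
            try:
                loc = e.normalized_location
            except Exception:
                loc = e.location
            if loc not in (".", MANIFEST_LOCATION):
                out.append(e)
        return out

    def check(self) -> None:
        """Raise unless the manifest satisfies its invariants."""
        if not self.entries:
            raise InvariantViolationError(
                "a manifest must have at least one entry (the archive itself)"
            )
        seen: set[str] = set()
        for e in self.entries:
            loc = e.normalized_location  # raises on escape / absolute
            if loc in seen:
                raise DuplicateLocationError(f"duplicate location: {loc!r}")
            seen.add(loc)


def master_entries(manifest: Manifest) -> list[ContentEntry]:
    """All entries flagged ``master``, in manifest order."""
    return [e for e in manifest.entries if e.master]


@dataclass(frozen=True)
class ExtensionRule:
    """Maps a dominant format (COMBINE spec name) to an archive file extension."""

    extension: str
    spec_name: str

    def matches(self, fmt: FormatURI) -> bool:
        return fmt.is_combine_spec(self.spec_name)


#: Published extension table; ``.omex`` is the default for everything else.
EXTENSION_RULES: tuple[ExtensionRule, ...] = (
    ExtensionRule(".sedx", "sed-ml"),
    ExtensionRule(".sbex", "sbml"),
    ExtensionRule(".cmex", "cellml"),
    ExtensionRule(".sbox", "sbol"),
    ExtensionRule(".neux", "neuroml"),
    ExtensionRule(".phex", "pharmml"),
)

DEFAULT_EXTENSION = ".omex"

_NON_PAYLOAD_FORMATS = (OMEX_FORMAT, OMEX_MANIFEST_FORMAT, OMEX_METADATA_FORMAT)


def _rule_for(fmt: FormatURI) -> ExtensionRule | None:
    for rule in EXTENSION_RULES:
        if rule.matches(fmt):
            return rule
    return None


def choose_extension(manifest: Manifest) -> str:
    """Suggest a file extension advertising the archive's main format.

    The extension is only a convenience hint for users.  The heuristic: if
    exactly one entry is flagged master, its format decides; otherwise, if
    every payload entry (ignoring ".", the manifest and metadata entries)
    maps to the same extension rule, that rule decides; otherwise the default
    ``.omex``.
    """
    masters = master_entries(manifest)
    if len(masters) == 1:
        rule = _rule_for(masters[0].format)
        return rule.extension if rule else DEFAULT_EXTENSION
    candidates = [
        e for e in manifest.payload_entries()
        if e.format.uri not in _NON_PAYLOAD_FORMATS
        and not e.format.uri.startswith(MEDIATYPE_PREFIX + "application/rdf")
    ]
    rules = {(_rule_for(e.format) or None) for e in candidates}
    if len(rules) == 1:
        rule = next(iter(rules))
        if rule is not None:
            return rule.extension
    return DEFAULT_EXTENSION


def iter_unique_locations(locations: Iterable[str]) -> Iterator[str]:
    """Yield normalized locations, raising on the first duplicate."""
    seen: set[str] = set()
    for raw in locations:
        loc = normalize_location(raw)
        if loc in seen:
            raise DuplicateLocationError(f"duplicate location: {loc!r}")
        seen.add(loc)
        yield loc
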