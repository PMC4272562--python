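"""Read and write the mandatory ``manifest.xml``.

The manifest is a flat XML list: one ``<content>`` element per file in the
archive, each carrying ``location``, ``format`` and an optional boolean
``master`` attribute.  The released OMEX v1 convention places the root
``<omexManifest>`` element in the namespace
``http://identifiers.org/combine.specifications/omex-manifest``; documents
without a namespace are accepted on read for interoperability with older
writers.
"""

from __future__ import annotations

import warnings

from lxml import etree

from .errors import MissingAttributeError, XmlParseError
from .model import ContentEntry, Manifest, classify_format, master_entries

MANIFEST_NAMESPACE = "http://identifiers.org/combine.specifications/omex-manifest"
ROOT_ELEMENT = "omexManifest"
CONTENT_ELEMENT = "content"

_KNOWN_ATTRS = {"location", "format", "master"}


def _localname(tag) -> str:
    if not isinstance(tag, str):  # comments / PIs
        return ""
    return tag.rsplit("}", 1)[-1]


def parse_manifest(data: bytes) -> Manifest:
    """Parse manifest bytes into a :class:`~omexarchive.model.Manifest`.

    Entry order is preserved exactly.  A missing ``master`` attribute means
    ``False``.  Unknown elements and attributes are tolerated with a warning
    (forward compatibility); a missing ``location`` or ``format`` attribute
    is an error.

    Raises
    ------
    XmlParseError, MissingAttributeError, MalformedURIError
    """
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise XmlParseError(f"manifest is not well-formed XML: {exc}") from exc

    if _localname(root.tag) != ROOT_ELEMENT:
        warnings.warn(
            f"unexpected manifest root element <{_localname(root.tag)}>; "
            f"expected <{ROOT_ELEMENT}>",
            stacklevel=2,
        )
    entries: list[ContentEntry] = []
    for child in root:
        name = _localname(child.tag)
        if not name:
            continue
        if name != CONTENT_ELEMENT:
            warnings.warn(f"ignoring unknown manifest element <{name}>", stacklevel=2)
            continue
        attrs = {_localname(k): v for k, v in child.attrib.items()}
        unknown = set(attrs) - _KNOWN_ATTRS
        if unknown:
            warnings.warn(
                f"ignoring unknown <content> attributes: {sorted(unknown)}", stacklevel=2
            )
        if "location" not in attrs:
            raise MissingAttributeError("<content> element lacks the 'location' attribute")
        if "format" not in attrs:
            raise MissingAttributeError(
                f"<content location={attrs['location']!r}> lacks the 'format' attribute"
            )
        master = attrs.get("master", "false").strip().lower() in ("true", "1")
        entries.append(
            ContentEntry(
                location=attrs["location"],
                format=classify_format(attrs["format"]),
                master=master,
            )
        )
    return Manifest(entries)


def write_manifest(manifest: Manifest, *, emit_master_always: bool = False) -> bytes:
    """Serialize a manifest to UTF-8 XML bytes.

    Output is deterministic: entry order is the manifest order and attributes
    are always written as ``location``, ``format``, ``master``.  By default
    the ``master`` attribute appears only on entries where it is true; with
    ``emit_master_always`` every entry carries an explicit ``"true"`` or
    ``"false"``.

    Raises
    ------
    InvariantViolationError
        If the manifest is empty.
    DuplicateLocationError, PathEscapeError, AbsolutePathError
        If an entry location is invalid (via :meth:`Manifest.check`).
    """
    manifest.check()
    if len(master_entries(manifest)) > 1:
        warnings.warn("more than one entry is flagged master", stacklevel=2)
    nsmap = {None: MANIFEST_NAMESPACE}
    root = etree.Element(f"{{{MANIFEST_NAMESPACE}}}{ROOT_ELEMENT}", nsmap=nsmap)
    for entry in manifest.entries:
        el = etree.SubElement(root, f"{{{MANIFEST_NAMESPACE}}}{CONTENT_ELEMENT}")
        el.set("location", entry.normalized_location)
        el.set("format", entry.format.uri)
        if entry.master or emit_master_always:
            el.set("master", "true" if entry.master else "false")
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
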