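"""Rule engine producing a structured report on an archive.

Rules mirror the container specification's normative language: "must"
clauses are errors, "should" clauses warnings, "could" clauses infos.

Registry
--------
=============  ========  ==========================================================
code           severity  meaning
=============  ========  ==========================================================
E1             error     no ``manifest.xml`` at the archive root
E2             error     manifest has no entries
E3             error     a listed file is missing from the ZIP
E4             error     a ``<content>`` attribute is absent or malformed
E5             error     a location is absolute or escapes the archive root
W1             warning   a ZIP member is not listed in the manifest
                         (error under the ``strict`` profile)
W2             warning   more than one entry is flagged master
W3             warning   minimal archive metadata is incomplete
W4             warning   format URI under neither the COMBINE-specifications
                         prefix nor the media-type URI prefix
NOT_A_ZIP      error     the file is not a ZIP container
XML_PARSE      error     the manifest is not well-formed XML
RDF_PARSE      error     the metadata is not parseable RDF
UNSUPPORTED    error     the ZIP uses an unsupported feature (encryption)
NO_METADATA    info      the archive carries no metadata file at all
=============  ========  ==========================================================
"""

from __future__ import annotations

import os
from typing import Literal

from .container import Archive, open_archive
from .errors import (
    LocationError,
    MalformedURIError,
    MissingAttributeError,
    MissingManifestError,
    NotAZipError,
    OmexError,
    RdfParseError,
    TimestampError,
    UnsupportedFeatureError,
    XmlParseError,
)
from .metadata import check_minimal_metadata
from .model import (
    COMBINE_SPEC_PREFIX,
    MANIFEST_LOCATION,
    MEDIATYPE_PREFIX,
    master_entries,
    normalize_location,
)
from .report import Finding, Severity

Profile = Literal["strict", "permissive"]

#: Every code the validator can emit (the fixtures' mutation corpus keys off this).
RULE_CODES = (
    "E1", "E2", "E3", "E4", "E5",
    "W1", "W2", "W3", "W4",
    "NOT_A_ZIP", "XML_PARSE", "RDF_PARSE", "UNSUPPORTED", "NO_METADATA",
)


def validate(archive: Archive, profile: Profile = "permissive") -> list[Finding]:
    """Evaluate all container rules on an open archive.

    Pure and deterministic: never mutates the archive, never raises for
    archive defects.  Under the ``strict`` profile, unlisted ZIP members
    (W1) are escalated to errors.
    """
    findings: list[Finding] = []
    manifest = archive.manifest
    members = set(archive.member_locations())

    if not manifest.entries:
        findings.append(
            Finding(
                Severity.ERROR, "E2", "",
                "manifest must have at least one entry (the archive itself)",
            )
        )

    bad_locations: set[str] = set()
    for entry in manifest.entries:
        if not entry.location:
            findings.append(
                Finding(Severity.ERROR, "E4", "", "entry has an empty location")
            )
            continue
        try:
            loc = normalize_location(entry.location)
        except LocationError as exc:
            bad_locations.add(entry.location)
            findings.append(Finding(Severity.ERROR, "E5", entry.location, str(exc)))
            continue
        if loc != "." and loc not in members:
            findings.append(
                Finding(
                    Severity.ERROR, "E3", loc,
                    f"file {loc!r} is listed in the manifest but missing "
                    "from the archive",
                )
            )
        fmt = entry.format.uri
        if not (
            fmt.startswith(COMBINE_SPEC_PREFIX) or fmt.startswith(MEDIATYPE_PREFIX)
        ):
            findings.append(
                Finding(
                    Severity.WARNING, "W4", loc,
                    f"format {fmt!r} is neither a COMBINE specification URI "
                    "nor a media-type URI",
                )
            )

    w1_severity = Severity.ERROR if profile == "strict" else Severity.WARNING
    for loc in sorted(archive.unlisted_payloads()):
        findings.append(
            Finding(
                w1_severity, "W1", loc,
                f"archive member {loc!r} is not listed in the manifest",
            )
        )

    masters = master_entries(manifest)
    if len(masters) > 1:
        findings.append(
            Finding(
                Severity.WARNING, "W2", "",
                f"{len(masters)} entries are flagged master; expected at most one",
            )
        )

    if archive.metadata:
        for f in check_minimal_metadata(archive.metadata):
            findings.append(
                Finding(Severity.WARNING, "W3", f.location, f"{f.code}: {f.message}")
            )
    else:
        findings.append(
            Finding(
                Severity.INFO, "NO_METADATA", "",
                "archive carries no metadata; creation date, last update and "
                "creator are recommended",
            )
        )
    return findings


_EXCEPTION_CODES = (
    (NotAZipError, "NOT_A_ZIP"),
    (MissingManifestError, "E1"),
    (XmlParseError, "XML_PARSE"),
    (MissingAttributeError, "E4"),
    (MalformedURIError, "E4"),
    (RdfParseError, "RDF_PARSE"),
    (TimestampError, "RDF_PARSE"),
    (UnsupportedFeatureError, "UNSUPPORTED"),
)


def validate_file(path: str | os.PathLike, profile: Profile = "permissive") -> list[Finding]:
    """Open and validate *path*; open failures become findings, not exceptions."""
    try:
        archive = open_archive(path)
    except OmexError as exc:
        for exc_type, code in _EXCEPTION_CODES:
            if isinstance(exc, exc_type):
                return [Finding(Severity.ERROR, code, "", str(exc))]
        return [Finding(Severity.ERROR, "E4", "", str(exc))]
    with archive:
        return validate(archive, profile)


def has_errors(findings: list[Finding]) -> bool:
    return any(f.severity is Severity.ERROR for f in findings)
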