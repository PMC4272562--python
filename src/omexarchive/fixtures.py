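"""Deterministic test-input generation: toy payloads, reference archives
and a single-fault mutation corpus for the validator.

Nothing here touches the network or the clock: payload bytes are a pure
function of the seed, ZIP member timestamps are pinned, and metadata uses
fixed dates, so the same :class:`FixtureSpec` always yields byte-identical
files.  Payload stubs are well-formed for their container syntax (XML for
the model/simulation stubs, a minimal ``%PDF`` document for the PDF stub)
but make no claim of semantic validity — the container layer never looks
inside payloads.
"""

from __future__ import annotations

import random
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

from .container import EPOCH_TIMESTAMP, create_archive
from .errors import OmexError
from .metadata import MetadataRecord, VCardPerson, W3CDTF, write_metadata
from .model import (
    COMBINE_SPEC_PREFIX,
    MANIFEST_LOCATION,
    MEDIATYPE_PREFIX,
    METADATA_LOCATION,
)

SBML_FORMAT = COMBINE_SPEC_PREFIX + "sbml"
SEDML_FORMAT = COMBINE_SPEC_PREFIX + "sed-ml.level-1.version-2"
PDF_FORMAT = MEDIATYPE_PREFIX + "application/pdf"
CSV_FORMAT = MEDIATYPE_PREFIX + "text/csv"
BINARY_FORMAT = MEDIATYPE_PREFIX + "application/octet-stream"

PAYLOAD_KINDS = ("sbml_like", "sedml_like", "pdf_stub", "csv", "random_binary")

_FIXED_CREATED = "2020-01-01T00:00:00Z"
_FIXED_MODIFIED = "2020-06-01T12:00:00Z"


def sbml_like(rng: random.Random) -> bytes:
    species = "".join(
        f'      <species id="s{i}" initialAmount="{rng.randint(0, 100)}"/>\n'
        for i in range(rng.randint(2, 6))
    )
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        '<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" '
        'level="3" version="1">\n'
        f'  <model id="m{rng.randint(0, 999)}">\n'
        "    <listOfSpecies>\n"
        f"{species}"
        "    </listOfSpecies>\n"
        "  </model>\n"
        "</sbml>\n"
    ).encode()


def sedml_like(rng: random.Random) -> bytes:
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        '<sedML xmlns="http://sed-ml.org/sed-ml/level1/version2" '
        'level="1" version="2">\n'
        "  <listOfSimulations>\n"
        f'    <uniformTimeCourse id="sim1" initialTime="0" '
        f'outputEndTime="{rng.randint(10, 1000)}" '
        f'numberOfPoints="{rng.randint(10, 500)}"/>\n'
        "  </listOfSimulations>\n"
        "</sedML>\n"
    ).encode()


def pdf_stub(rng: random.Random) -> bytes:
    body = f"(toy article {rng.randint(0, 9999)})".encode()
    return b"%PDF-1.4\n1 0 obj\n<< /Type /Catalog >>\nendobj\n" + body + b"\n%%EOF\n"


def csv_payload(rng: random.Random) -> bytes:
    rows = "".join(
        f"{t},{rng.uniform(0, 1):.6f}\n" for t in range(rng.randint(5, 20))
    )
    return ("time,value\n" + rows).encode()


def random_binary(rng: random.Random) -> bytes:
    return rng.randbytes(rng.randint(64, 4096))


_GENERATORS = {
    "sbml_like": (sbml_like, SBML_FORMAT, "model{i}.xml"),
    "sedml_like": (sedml_like, SEDML_FORMAT, "simulation{i}.xml"),
    "pdf_stub": (pdf_stub, PDF_FORMAT, "article{i}.pdf"),
    "csv": (csv_payload, CSV_FORMAT, "data{i}.csv"),
    "random_binary": (random_binary, BINARY_FORMAT, "blob{i}.bin"),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one deterministic fixture archive.

    ``fault`` selects which validation rule the generated archive breaks
    (one of the validator's registry codes) or ``None`` for a clean archive.
    """

    seed: int = 0
    n_payloads: int = 3
    payload_kinds: tuple[str, ...] = ("sbml_like", "sedml_like", "csv")
    fault: str | None = None


def default_metadata() -> list[MetadataRecord]:
    """A complete archive record satisfying the minimal-metadata check."""
    return [
        MetadataRecord(
            about=".",
            description="Deterministic fixture archive for container tests",
            creators=[
                VCardPerson(
                    family_name="Archivist",
                    given_name="Avery",
                    email="avery@example.org",
                    organization_name="Fixture Works",
                )
            ],
            created=W3CDTF.parse(_FIXED_CREATED),
            modified=[W3CDTF.parse(_FIXED_MODIFIED)],
        )
    ]


def make_payloads(spec: FixtureSpec) -> list[tuple[str, bytes, str, bool]]:
    """Deterministic payload tuples for *spec*; first entry is flagged master."""
    for kind in spec.payload_kinds:
        if kind not in _GENERATORS:
            raise OmexError(f"unknown payload kind: {kind!r}")
    rng = random.Random(spec.seed)
    out = []
    for i in range(spec.n_payloads):
        kind = spec.payload_kinds[i % len(spec.payload_kinds)]
        gen, fmt, name_tpl = _GENERATORS[kind]
        out.append((name_tpl.format(i=i), gen(rng), fmt, i == 0))
    return out


def make_reference_archive(directory: str | Path) -> Path:
    """Build the canonical worked example archive.

    Composition: an SBML-like model, a SED-ML-like simulation description
    flagged master, a PDF stub of the accompanying article, and an archive
    metadata record (description, creator, creation and modification dates).
    Together with the archive self-entry and the metadata entry, the
    manifest describes 5 files.  Output is byte-reproducible.
    """
    rng = random.Random(42)
    files = [
        ("model.xml", sbml_like(rng), SBML_FORMAT, False),
        ("simulation.xml", sedml_like(rng), SEDML_FORMAT, True),
        ("article.pdf", pdf_stub(rng), PDF_FORMAT, False),
    ]
    metadata = [
        MetadataRecord(
            about=".",
            description="A toy simulation study: model, simulation setup and article",
            creators=[
                VCardPerson(
                    family_name="Rivera",
                    given_name="Sam",
                    email="sam@example.org",
                )
            ],
            created=W3CDTF.parse(_FIXED_CREATED),
            modified=[W3CDTF.parse(_FIXED_MODIFIED)],
        )
    ]
    archive = create_archive(
        files,
        metadata,
        destination=Path(directory) / "study",
        zip_timestamp=EPOCH_TIMESTAMP,
    )
    return archive.path


def make_mutant(spec: FixtureSpec, directory: str | Path) -> Path:
    """Build an archive that breaks exactly the validation rule ``spec.fault``.

    With ``fault=None`` the archive validates clean.  Unknown fault codes
    raise :class:`~omexarchive.errors.OmexError`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fault = spec.fault
    name = f"mutant-{fault or 'clean'}-{spec.seed}.omex"
    path = directory / name

    if fault == "NOT_A_ZIP":
        path.write_bytes(b"this is not a zip archive\n")
        return path

    if fault == "E2":
        # A lone manifest with zero entries: no members to trip other rules.
        with zipfile.ZipFile(path, "w") as zf:
            info = zipfile.ZipInfo(MANIFEST_LOCATION, date_time=EPOCH_TIMESTAMP)
            zf.writestr(
                info,
                b'<?xml version="1.0" encoding="UTF-8"?>\n'
                b'<omexManifest xmlns='
                b'"http://identifiers.org/combine.specifications/omex-manifest"/>\n',
            )
        return path

    files = make_payloads(spec)
    metadata = [] if fault == "NO_METADATA" else default_metadata()
    archive = create_archive(
        files, metadata, destination=path, zip_timestamp=EPOCH_TIMESTAMP
    )
    if fault is None or fault == "NO_METADATA":
        return archive.path

    if fault == "E1":
        _rewrite_zip(path, drop={MANIFEST_LOCATION})
    elif fault == "E3":
        _edit_manifest(
            path,
            lambda root: _append_content(root, "phantom.csv", CSV_FORMAT),
        )
    elif fault == "E4":
        def drop_format(root):
            for el in root:
                if el.attrib.get("location") == files[0][0]:
                    del el.attrib["format"]
        _edit_manifest(path, drop_format)
    elif fault == "E5":
        _edit_manifest(
            path,
            lambda root: _append_content(root, "../escape.txt", CSV_FORMAT),
        )
    elif fault == "W1":
        _rewrite_zip(path, add={"unlisted.bin": b"\x00\x01stray payload"})
    elif fault == "W2":
        def two_masters(root):
            flagged = 0
            for el in root:
                if el.attrib.get("location") not in (".", MANIFEST_LOCATION):
                    el.attrib["master"] = "true"
                    flagged += 1
                    if flagged == 2:
                        break
        _edit_manifest(path, two_masters)
    elif fault == "W3":
        records = default_metadata()
        records[0].creators = []
        _rewrite_zip(
            path, replace={METADATA_LOCATION: write_metadata(records)}
        )
    elif fault == "W4":
        def odd_format(root):
            for el in root:
                if el.attrib.get("location") == files[0][0]:
                    el.attrib["format"] = "urn:example:homegrown-format"
        _edit_manifest(path, odd_format)
    elif fault == "XML_PARSE":
        _rewrite_zip(path, replace={MANIFEST_LOCATION: b"<omexManifest <broken"})
    elif fault == "RDF_PARSE":
        _rewrite_zip(path, replace={METADATA_LOCATION: b"@@@ not rdf at all @@@"})
    elif fault == "UNSUPPORTED":
        _flag_first_member_encrypted(path)
    else:
        raise OmexError(f"unknown fault code: {fault!r}")
    return path


def make_mutation_corpus(directory: str | Path, seed: int = 0) -> dict[str, Path]:
    """One single-fault archive per validator rule code, plus a clean one."""
    from .validate import RULE_CODES

    corpus = {"clean": make_mutant(FixtureSpec(seed=seed), directory)}
    for code in RULE_CODES:
        corpus[code] = make_mutant(FixtureSpec(seed=seed, fault=code), directory)
    return corpus


# -- low-level mutation helpers ---------------------------------------


def _rewrite_zip(path: Path, drop=(), add=None, replace=None) -> None:
    drop = set(drop)
    add = dict(add or {})
    replace = dict(replace or {})
    with zipfile.ZipFile(path) as zf:
        members = [(i.filename, zf.read(i.filename)) for i in zf.infolist()]
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, data in members:
            if name in drop:
                continue
            info = zipfile.ZipInfo(name, date_time=EPOCH_TIMESTAMP)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, replace.get(name, data))
        for name, data in add.items():
            info = zipfile.ZipInfo(name, date_time=EPOCH_TIMESTAMP)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, data)


def _edit_manifest(path: Path, mutate) -> None:
    from lxml import etree

    with zipfile.ZipFile(path) as zf:
        root = etree.fromstring(zf.read(MANIFEST_LOCATION))
    mutate(root)
    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8")
    _rewrite_zip(path, replace={MANIFEST_LOCATION: data})


def _append_content(root, location: str, format_uri: str) -> None:
    from lxml import etree

    ns = root.tag.split("}")[0].strip("{") if "}" in root.tag else None
    tag = f"{{{ns}}}content" if ns else "content"
    el = etree.SubElement(root, tag)
    el.set("location", location)
    el.set("format", format_uri)


def _flag_first_member_encrypted(path: Path) -> None:
    """Set the encryption bit of the first member in both ZIP headers."""
    data = bytearray(path.read_bytes())
    local_sig = data.find(b"PK\x03\x04")
    central_sig = data.find(b"PK\x01\x02")
    if local_sig < 0 or central_sig < 0:
        raise OmexError("cannot locate ZIP headers to mutate")
    for offset in (local_sig + 6, central_sig + 8):
        (flags,) = struct.unpack_from("<H", data, offset)
        struct.pack_into("<H", data, offset, flags | 0x1)
    path.write_bytes(bytes(data))
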