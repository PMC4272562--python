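"""Bind the archive model to the ZIP physical layer.

An archive on disk is a plain ZIP file whose root holds the mandatory
``manifest.xml`` and, by convention, a ``metadata.rdf``.  Payloads sit at
the locations the manifest declares; directory hierarchy is implied by the
locations, so no directory entries are written.  Entries are deflated by
default; payloads whose declared media type marks them as already compressed
(zip, gzip, png, jpeg) are stored as-is.

Encrypted ZIP entries are not supported and are rejected on open.
"""

from __future__ import annotations

import os
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import manifest as manifest_io
from . import metadata as metadata_io
from .errors import (
    DuplicateLocationError,
    MissingManifestError,
    NotAZipError,
    UnknownLocationError,
    UnsupportedFeatureError,
)
from .metadata import MetadataRecord
from .model import (
    MANIFEST_LOCATION,
    MEDIATYPE_PREFIX,
    METADATA_LOCATION,
    OMEX_FORMAT,
    OMEX_MANIFEST_FORMAT,
    OMEX_METADATA_FORMAT,
    ContentEntry,
    Manifest,
    choose_extension,
    normalize_location,
)

#: Media-type names treated as pre-compressed and therefore stored, not deflated.
PRECOMPRESSED_MEDIA_TYPES = frozenset(
    {
        "application/zip",
        "application/gzip",
        "application/x-gzip",
        "image/png",
        "image/jpeg",
    }
)

#: Fixed ZIP member timestamp used when the caller wants byte-reproducible output.
EPOCH_TIMESTAMP = (1980, 1, 1, 0, 0, 0)


@dataclass(frozen=True)
class ArchiveStats:
    """Size accounting for an archive on disk.

    ``compression_ratio`` is ``100 * (1 - compressed / uncompressed)``,
    clamped at 0 (deflate overhead can make incompressible content a shade
    larger than its input).  ``uncompressed_total`` counts every member,
    manifest and metadata included.
    """

    compressed_size: int
    uncompressed_total: int
    compression_ratio: float


class Archive:
    """An in-memory view of a COMBINE Archive.

    Payload bytes are held in memory for archives built programmatically and
    read lazily from the backing ZIP for archives opened from disk.  Use as a
    context manager (or call :meth:`close`) when opened from a file.
    """

    def __init__(
        self,
        manifest: Manifest,
        metadata: list[MetadataRecord] | None = None,
        *,
        path: Path | None = None,
        payloads: dict[str, bytes] | None = None,
    ) -> None:
        self.manifest = manifest
        self.metadata = list(metadata or [])
        self.path = path
        self._payloads: dict[str, bytes] = dict(payloads or {})
        self._zip: zipfile.ZipFile | None = None

    # -- lifecycle -----------------------------------------------------
    def close(self) -> None:
        if self._zip is not None:
            self._zip.close()
            self._zip = None

    def __enter__(self) -> "Archive":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- payload access ------------------------------------------------
    def member_locations(self) -> list[str]:
        """Every file physically present in the archive (manifest included)."""
        if self._zip is not None:
            return [n for n in self._zip.namelist() if not n.endswith("/")]
        names = list(self._payloads)
        if names and MANIFEST_LOCATION not in names:
            names.append(MANIFEST_LOCATION)
        return names

    def read_entry(self, location: str) -> bytes:
        """Payload bytes for a normalized location.

        The archive self-entry ``"."`` denotes the container, not a file.
        """
        loc = normalize_location(location)
        if loc == ".":
            raise UnknownLocationError(
                '"." denotes the archive itself and has no payload'
            )
        if loc in self._payloads:
            return self._payloads[loc]
        if self._zip is not None:
            try:
                return self._zip.read(loc)
            except KeyError:
                pass
        raise UnknownLocationError(f"no such entry in archive: {loc!r}")

    def has_member(self, location: str) -> bool:
        try:
            self.read_entry(location)
            return True
        except UnknownLocationError:
            return False

    def unlisted_payloads(self) -> list[str]:
        """ZIP members that the manifest does not list (manifest.xml excluded)."""
        listed = set(self.manifest.locations())
        return [
            n
            for n in self.member_locations()
            if n != MANIFEST_LOCATION and n not in listed
        ]


def _compression_for(format_uri: str) -> int:
    name = (
        format_uri[len(MEDIATYPE_PREFIX):]
        if format_uri.startswith(MEDIATYPE_PREFIX)
        else ""
    )
    if name in PRECOMPRESSED_MEDIA_TYPES:
        return zipfile.ZIP_STORED
    return zipfile.ZIP_DEFLATED


def create_archive(
    files: Iterable[tuple],
    metadata: Sequence[MetadataRecord] = (),
    destination: str | os.PathLike = "archive",
    *,
    compression_level: int | None = None,
    emit_master_always: bool = False,
    write_manifest_self_entry: bool = False,
    zip_timestamp: tuple | None = None,
) -> Archive:
    """Create an archive on disk from payload files and metadata records.

    Parameters
    ----------
    files:
        Iterable of ``(location, bytes, format_uri, master)`` tuples (the
        master flag may be omitted).
    metadata:
        Records written to ``metadata.rdf`` when non-empty; the manifest
        then gains a metadata entry automatically.
    destination:
        Output path.  When it has no extension, one advertising the main
        format is chosen (``.sedx``, ``.sbex``, ... or the default
        ``.omex``).
    compression_level:
        Deflate level 0-9; ``None`` uses the zlib default.
    write_manifest_self_entry:
        Also list ``manifest.xml`` itself as a content entry.
    zip_timestamp:
        Fixed ``(Y, M, D, h, m, s)`` for all ZIP members, for byte-level
        reproducibility; defaults to the current time.

    Returns the created archive; the manifest always includes the archive
    self-entry at location ``"."``.
    """
    entries: list[ContentEntry] = [ContentEntry.create(".", OMEX_FORMAT)]
    if write_manifest_self_entry:
        entries.append(ContentEntry.create(MANIFEST_LOCATION, OMEX_MANIFEST_FORMAT))
    payloads: dict[str, bytes] = {}
    for item in files:
        location, data, format_uri = item[0], item[1], item[2]
        master = bool(item[3]) if len(item) > 3 else False
        entry = ContentEntry.create(location, format_uri, master)
        if entry.location in payloads or entry.location in (".", MANIFEST_LOCATION):
            raise DuplicateLocationError(f"duplicate location: {entry.location!r}")
        payloads[entry.location] = bytes(data)
        entries.append(entry)

    metadata = list(metadata)
    if metadata:
        if METADATA_LOCATION in payloads:
            raise DuplicateLocationError(
                f"{METADATA_LOCATION!r} passed as payload and as metadata records"
            )
        entries.append(ContentEntry.create(METADATA_LOCATION, OMEX_METADATA_FORMAT))

    manifest = Manifest(entries)
    manifest.check()
    manifest_bytes = manifest_io.write_manifest(
        manifest, emit_master_always=emit_master_always
    )
    if metadata:
        payloads[METADATA_LOCATION] = metadata_io.write_metadata(
            metadata, locations=manifest.locations()
        )

    destination = Path(destination)
    if destination.suffix == "":
        destination = destination.with_name(
            destination.name + choose_extension(manifest)
        )
    destination.parent.mkdir(parents=True, exist_ok=True)

    date_time = zip_timestamp
    with zipfile.ZipFile(destination, "w") as zf:
        _write_member(zf, MANIFEST_LOCATION, manifest_bytes,
                      zipfile.ZIP_DEFLATED, compression_level, date_time)
        for entry in manifest.payload_entries():
            loc = entry.normalized_location
            _write_member(
                zf, loc, payloads[loc],
                _compression_for(entry.format.uri), compression_level, date_time,
            )
    return Archive(manifest, metadata, path=destination, payloads=payloads)


def _write_member(zf, name, data, compress_type, level, date_time) -> None:
    if date_time is None:
        zf.writestr(name, data, compress_type=compress_type, compresslevel=level)
    else:
        info = zipfile.ZipInfo(name, date_time=date_time)
        info.compress_type = compress_type
        info.external_attr = 0o644 << 16
        zf.writestr(info, data, compress_type=compress_type, compresslevel=level)


def open_archive(path: str | os.PathLike) -> Archive:
    """Open an existing archive for reading.

    The manifest is parsed immediately; metadata is read from every manifest
    entry whose format is the OMEX metadata URI (and merged when split over
    several files); payloads are read lazily.

    Raises
    ------
    NotAZipError, MissingManifestError, UnsupportedFeatureError
    and parse errors propagated from the manifest/metadata readers.
    """
    path = Path(path)
    try:
        zf = zipfile.ZipFile(path, "r")
    except zipfile.BadZipFile as exc:
        raise NotAZipError(f"{path} is not a ZIP file") from exc
    try:
        for info in zf.infolist():
            if info.flag_bits & 0x1:
                raise UnsupportedFeatureError(
                    f"encrypted ZIP entry {info.filename!r} is not supported"
                )
        names = set(zf.namelist())
        if MANIFEST_LOCATION not in names:
            raise MissingManifestError(
                f"{path} has no {MANIFEST_LOCATION} at its root"
            )
        manifest = manifest_io.parse_manifest(zf.read(MANIFEST_LOCATION))
        records: list[MetadataRecord] = []
        for entry in manifest.entries:
            if entry.format.uri == OMEX_METADATA_FORMAT:
                try:
                    loc = entry.normalized_location
                except Exception:
                    continue
                if loc in names:
                    records.extend(metadata_io.read_metadata(zf.read(loc)))
    except Exception:
        zf.close()
        raise
    archive = Archive(manifest, records, path=path)
    archive._zip = zf
    return archive


def extract_entry(
    archive: Archive, location: str, destination: str | os.PathLike
) -> Path:
    """Write one payload verbatim below *destination* and return the path.

    *destination* may be a directory (the entry's relative location is
    recreated beneath it) or a target file path when extracting a single
    entry.
    """
    loc = normalize_location(location)
    data = archive.read_entry(loc)
    destination = Path(destination)
    if destination.is_dir() or str(destination).endswith(("/", os.sep)):
        target = destination / loc
    else:
        target = destination
    target.parent.mkdir(parents=True, exist_ok=True)
    target.write_bytes(data)
    return target


def extract_all(archive: Archive, destination: str | os.PathLike) -> list[Path]:
    """Extract every payload member (manifest excluded) under *destination*."""
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    out = []
    for loc in archive.member_locations():
        if loc == MANIFEST_LOCATION:
            continue
        target = destination / normalize_location(loc)
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_bytes(archive.read_entry(loc))
        out.append(target)
    return out


def compute_stats(archive: Archive) -> ArchiveStats:
    """Measure compression achieved by the archive.

    Compressed size is the sum of the stored member streams; uncompressed
    size is the sum of the member file sizes (payloads plus manifest and
    metadata).  The ratio is invariant under entry reordering.
    """
    if archive._zip is not None:
        infos = archive._zip.infolist()
    elif archive.path is not None:
        with zipfile.ZipFile(archive.path) as zf:
            infos = zf.infolist()
    else:
        raise UnknownLocationError("archive has no backing ZIP to measure")
    compressed = sum(i.compress_size for i in infos)
    uncompressed = sum(i.file_size for i in infos)
    ratio = 0.0
    if uncompressed > 0:
        ratio = max(0.0, 100.0 * (1.0 - compressed / uncompressed))
    return ArchiveStats(compressed, uncompressed, ratio)
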