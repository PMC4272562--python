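"""ZIP container tests: create/open/extract round trips and size accounting."""

import random
import zipfile

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omexarchive.container import (
    compute_stats,
    create_archive,
    extract_all,
    extract_entry,
    open_archive,
)
from omexarchive.errors import (
    DuplicateLocationError,
    MissingManifestError,
    NotAZipError,
    PathEscapeError,
    UnknownLocationError,
    UnsupportedFeatureError,
)
from omexarchive.fixtures import (
    CSV_FORMAT,
    PDF_FORMAT,
    SBML_FORMAT,
    SEDML_FORMAT,
    default_metadata,
)
from omexarchive.model import MANIFEST_LOCATION
from omexarchive.validate import validate
from omexarchive.report import Severity


def toy_files():
    return [
        ("model.xml", b"<model/>", SBML_FORMAT, False),
        ("simulation.xml", b"<simulation/>", SEDML_FORMAT, True),
        ("article.pdf", b"%PDF-1.4\n%%EOF\n", PDF_FORMAT, False),
    ]


class TestCreate:
    def test_reference_composition_yields_five_entries(self, tmp_path):
        archive = create_archive(toy_files(), default_metadata(), tmp_path / "study")
        assert len(archive.manifest) == 5
        assert archive.path.suffix == ".sedx"  # master is the SED-ML file
        assert not [f for f in validate(archive) if f.severity is not Severity.INFO]

    def test_empty_archive_has_only_self_entry(self, tmp_path):
        archive = create_archive([], [], tmp_path / "empty")
        assert [e.location for e in archive.manifest.entries] == ["."]
        assert archive.path.suffix == ".omex"

    def test_duplicate_location_rejected(self, tmp_path):
        files = [("a.xml", b"x", SBML_FORMAT), ("./a.xml", b"y", SBML_FORMAT)]
        with pytest.raises(DuplicateLocationError):
            create_archive(files, [], tmp_path / "dup")

    def test_explicit_extension_honored(self, tmp_path):
        archive = create_archive(toy_files(), [], tmp_path / "study.omex")
        assert archive.path.name == "study.omex"

    def test_manifest_self_entry_opt_in(self, tmp_path):
        archive = create_archive(
            [], [], tmp_path / "a", write_manifest_self_entry=True
        )
        assert MANIFEST_LOCATION in archive.manifest.locations()


class TestOpen:
    def test_round_trip_equals_created(self, tmp_path, reference_archive):
        with open_archive(reference_archive) as archive:
            assert [e.location for e in archive.manifest.entries] == [
                ".", "model.xml", "simulation.xml", "article.pdf", "metadata.rdf"
            ]
            assert archive.metadata[0].creators[0].family_name == "Rivera"

    def test_zip_without_manifest(self, tmp_path):
        p = tmp_path / "bare.omex"
        with zipfile.ZipFile(p, "w") as zf:
            zf.writestr("model.xml", b"<model/>")
        with pytest.raises(MissingManifestError):
            open_archive(p)

    def test_not_a_zip(self, tmp_path):
        p = tmp_path / "nope.omex"
        p.write_bytes(b"plain text")
        with pytest.raises(NotAZipError):
            open_archive(p)

    def test_missing_listed_file_opens_but_flags_e3(self, tmp_path):
        archive = create_archive(
            [("data.csv", b"a,b\n", CSV_FORMAT)], [], tmp_path / "x"
        )
        # remove the payload behind the manifest's back
        with zipfile.ZipFile(archive.path) as zf:
            keep = {n: zf.read(n) for n in zf.namelist() if n != "data.csv"}
        with zipfile.ZipFile(archive.path, "w") as zf:
            for n, d in keep.items():
                zf.writestr(n, d)
        with open_archive(archive.path) as reopened:
            codes = [f.code for f in validate(reopened)]
        assert "E3" in codes

    def test_encrypted_entry_rejected(self, tmp_path):
        from omexarchive.fixtures import FixtureSpec, make_mutant

        p = make_mutant(FixtureSpec(fault="UNSUPPORTED"), tmp_path)
        with pytest.raises(UnsupportedFeatureError):
            open_archive(p)


class TestExtract:
    def test_single_entry_bytes_identical(self, tmp_path, reference_archive):
        with open_archive(reference_archive) as archive:
            original = archive.read_entry("simulation.xml")
            out = extract_entry(archive, "simulation.xml", tmp_path / "out" / "sim.xml")
        assert out.read_bytes() == original

    def test_archive_self_entry_is_not_extractable(self, tmp_path, reference_archive):
        with open_archive(reference_archive) as archive:
            with pytest.raises(UnknownLocationError):
                extract_entry(archive, ".", tmp_path)

    @pytest.mark.parametrize(
        "hostile", ["../x", "a/../../x", "../../etc/passwd", "/etc/passwd"]
    )
    def test_traversal_corpus_rejected(self, tmp_path, reference_archive, hostile):
        with open_archive(reference_archive) as archive:
            with pytest.raises(Exception) as err:
                extract_entry(archive, hostile, tmp_path)
            assert not isinstance(err.value, OSError)

    payload_sets = st.lists(
        st.tuples(
            st.from_regex(r"[a-z][a-z0-9]{0,6}(/[a-z][a-z0-9]{0,4})?\.[a-z]{2,3}",
                          fullmatch=True),
            st.binary(min_size=0, max_size=2048),
        ),
        min_size=1, max_size=5,
        unique_by=lambda t: t[0],
    )

    @given(payload_sets)
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_create_open_extract_identity(self, tmp_path_factory, payloads):
        """Byte-equality oracle: whatever goes in comes out verbatim."""
        tmp = tmp_path_factory.mktemp("rt")
        files = [(loc, data, CSV_FORMAT) for loc, data in payloads]
        archive = create_archive(files, [], tmp / "a.omex")
        with open_archive(archive.path) as reopened:
            for loc, data in payloads:
                assert reopened.read_entry(loc) == data
            outs = extract_all(reopened, tmp / "out")
        assert len(outs) == len(payloads)


class TestStats:
    def test_incompressible_payload_ratio_near_zero(self, tmp_path):
        blob = random.Random(7).randbytes(200_000)
        archive = create_archive(
            [("blob.bin", blob, CSV_FORMAT)], [], tmp_path / "r.omex"
        )
        stats = compute_stats(archive)
        assert stats.uncompressed_total >= 200_000
        assert stats.compression_ratio < 2.0

    def test_constant_megabyte_compresses_above_99(self, tmp_path):
        archive = create_archive(
            [("zeros.dat", b"\x00" * 10**6, CSV_FORMAT)], [], tmp_path / "z.omex"
        )
        assert compute_stats(archive).compression_ratio > 99.0

    def test_stored_for_precompressed_media_types(self, tmp_path):
        png_format = "http://purl.org/NET/mediatypes/image/png"
        archive = create_archive(
            [("img.png", b"\x89PNG fake" * 100, png_format)], [], tmp_path / "p.omex"
        )
        with zipfile.ZipFile(archive.path) as zf:
            assert zf.getinfo("img.png").compress_type == zipfile.ZIP_STORED

    def test_ratio_invariant_under_reordering(self, tmp_path):
        files = [(f"f{i}.csv", bytes([i]) * 5000, CSV_FORMAT) for i in range(4)]
        a = create_archive(files, [], tmp_path / "fwd.omex",
                           zip_timestamp=(1980, 1, 1, 0, 0, 0))
        b = create_archive(list(reversed(files)), [], tmp_path / "rev.omex",
                           zip_timestamp=(1980, 1, 1, 0, 0, 0))
        assert compute_stats(a).compression_ratio == pytest.approx(
            compute_stats(b).compression_ratio, abs=1e-9
        )
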