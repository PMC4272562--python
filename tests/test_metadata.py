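"""Metadata (Dublin Core + vCard RDF/XML) round-trip and rule tests."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdflib import Graph
from rdflib.compare import isomorphic, to_isomorphic

from omexarchive.errors import (
    InvariantViolationError,
    RdfParseError,
    TimestampError,
)
from omexarchive.metadata import (
    MISSING_CREATED,
    MISSING_CREATOR,
    MISSING_MODIFIED,
    MetadataRecord,
    VCardPerson,
    W3CDTF,
    check_minimal_metadata,
    read_metadata,
    write_metadata,
)


def full_record(about="."):
    return MetadataRecord(
        about=about,
        description="A toy study bundling a model and its simulation setup",
        creators=[
            VCardPerson(
                family_name="Rivera",
                given_name="Sam",
                email="sam@example.org",
                organization_name="Example Lab",
            )
        ],
        created=W3CDTF.parse("2020-01-01T00:00:00Z"),
        modified=[W3CDTF.parse("2020-06-01T12:00:00Z")],
    )


class TestW3CDTF:
    @pytest.mark.parametrize(
        "raw",
        ["2020", "2020-06", "2020-06-01", "2020-06-01T12:30Z",
         "2020-06-01T12:30:05Z", "2020-06-01T12:30:05.25+02:00"],
    )
    def test_accepted_profiles_reparse(self, raw):
        stamp = W3CDTF.parse(raw)
        assert stamp.raw == raw
        assert W3CDTF.parse(stamp.raw) == stamp

    def test_missing_timezone_defaults_to_utc_with_warning(self):
        with pytest.warns(UserWarning, match="timezone"):
            stamp = W3CDTF.parse("2020-06-01T12:30:00")
        assert stamp.instant.utcoffset().total_seconds() == 0

    @pytest.mark.parametrize("bad", ["June 1st", "2020-13-01", "20200601", ""])
    def test_rejected(self, bad):
        with pytest.raises(TimestampError):
            W3CDTF.parse(bad)

    def test_offsets_compare_on_the_instant_timeline(self):
        assert (
            W3CDTF.parse("2020-06-01T14:00:00+02:00").instant
            == W3CDTF.parse("2020-06-01T12:00:00Z").instant
        )


class TestReadWrite:
    def test_archive_record_round_trips_all_fields(self):
        rec = full_record()
        (back,) = read_metadata(write_metadata([rec]))
        assert back.about == "."
        assert back.description == rec.description
        assert back.creators == rec.creators
        assert back.created == rec.created
        assert back.modified == rec.modified

    def test_empty_document_yields_no_records(self):
        empty = b'<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"/>'
        assert read_metadata(empty) == []

    def test_two_subjects_one_document(self):
        recs = [full_record("."), full_record("model.xml")]
        data = write_metadata(recs, locations=[".", "model.xml"])
        back = read_metadata(data)
        assert sorted(r.about for r in back) == [".", "model.xml"]

    def test_unknown_about_location_rejected(self):
        with pytest.raises(InvariantViolationError):
            write_metadata([full_record("ghost.xml")], locations=["."])

    def test_modified_before_created_rejected(self):
        rec = full_record()
        rec.modified = [W3CDTF.parse("2019-01-01")]
        with pytest.raises(InvariantViolationError):
            write_metadata([rec])

    def test_unparseable_rdf_rejected(self):
        with pytest.raises(RdfParseError):
            read_metadata(b"@@@ neither xml nor turtle @@@")

    def test_unrecognized_triples_survive_round_trip(self):
        doc = b"""<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:dcterms="http://purl.org/dc/terms/"
         xmlns:foaf="http://xmlns.com/foaf/0.1/">
  <rdf:Description rdf:about=".">
    <dcterms:description>annotated archive</dcterms:description>
    <foaf:homepage rdf:resource="http://example.org/project"/>
    <dcterms:license rdf:resource="http://example.org/license"/>
  </rdf:Description>
</rdf:RDF>
"""
        (rec,) = read_metadata(doc)
        assert len(rec.extra) == 2
        out = write_metadata([rec])
        assert b"homepage" in out and b"license" in out
        g1 = Graph().parse(data=doc, format="xml", publicID="http://b.invalid/")
        g2 = Graph().parse(data=out, format="xml", publicID="http://b.invalid/")
        assert isomorphic(g1, g2)

    def test_turtle_accepted_on_read(self):
        ttl = b"""@prefix dcterms: <http://purl.org/dc/terms/> .
<.> dcterms:description "turtle-annotated archive" .
"""
        (rec,) = read_metadata(ttl)
        assert rec.description == "turtle-annotated archive"

    def test_write_is_deterministic(self):
        recs = [full_record(), full_record("model.xml")]
        assert write_metadata(recs) == write_metadata(recs)


names = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyzABC ", min_size=1, max_size=12
).filter(str.strip)
stamps = st.sampled_from(
    ["2019-05-04", "2020-01-01T00:00:00Z", "2021-07-01T06:30:00+01:00", "2018"]
)


@st.composite
def records(draw, about="."):
    people = draw(st.lists(
        st.builds(
            VCardPerson,
            family_name=names,
            given_name=names,
            email=st.one_of(st.none(), st.just("someone@example.org")),
            organization_name=st.one_of(st.none(), names),
        ),
        max_size=2,
    ))
    created = W3CDTF.parse(draw(stamps))
    mods = sorted(
        (W3CDTF.parse(s) for s in draw(st.lists(stamps, max_size=3))),
        key=lambda w: w.instant,
    )
    mods = [m for m in mods if m.instant >= created.instant]
    return MetadataRecord(
        about=about,
        description=draw(st.one_of(st.none(), names)),
        creators=people,
        created=created,
        modified=mods,
    )


class TestRoundTripProperties:
    @given(records())
    @settings(max_examples=100, derandomize=True)
    def test_graph_isomorphic_fixpoint(self, rec):
        """write(read(write(r))) and write(r) describe isomorphic RDF graphs."""
        data = write_metadata([rec])
        back = read_metadata(data)
        data2 = write_metadata(back)
        g1 = Graph().parse(data=data, format="xml", publicID="http://b.invalid/")
        g2 = Graph().parse(data=data2, format="xml", publicID="http://b.invalid/")
        assert to_isomorphic(g1) == to_isomorphic(g2)

    @given(records())
    @settings(max_examples=100, derandomize=True)
    def test_emitted_timestamps_reparse_as_w3cdtf(self, rec):
        for r in read_metadata(write_metadata([rec])):
            if r.created is not None:
                W3CDTF.parse(r.created.raw)
            for m in r.modified:
                W3CDTF.parse(m.raw)


class TestMinimalMetadata:
    def test_complete_archive_record_is_clean(self):
        assert check_minimal_metadata([full_record()]) == []

    def test_missing_creator_only(self):
        rec = full_record()
        rec.creators = []
        (finding,) = check_minimal_metadata([rec])
        assert finding.code == MISSING_CREATOR

    def test_no_archive_record_yields_three_findings(self):
        findings = check_minimal_metadata([full_record("model.xml")])
        assert {f.code for f in findings} == {
            MISSING_CREATED, MISSING_MODIFIED, MISSING_CREATOR
        }

    @pytest.mark.parametrize(
        "has_created, has_modified, has_creator",
        list(itertools.product([True, False], repeat=3)),
    )
    def test_finding_count_matches_missing_items(
        self, has_created, has_modified, has_creator
    ):
        """Enumerate all presence combinations: one finding per unmet item."""
        rec = full_record()
        if not has_created:
            rec.created = None
        if not has_modified:
            rec.modified = []
        if not has_creator:
            rec.creators = []
        findings = check_minimal_metadata([rec])
        assert len(findings) == [has_created, has_modified, has_creator].count(False)
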