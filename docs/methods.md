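# Methods

## The container model

An archive is a ZIP file holding a flat set of members. Its logical
description is the manifest: an ordered list of `<content>` entries, each
with exactly three attributes — `location` (a relative URI inside the
archive, or `"."` for the archive itself), `format` (an absolute URI), and
an optional boolean `master`. Two invariants are treated as "must" rules: a
valid manifest has at least one entry (the archive self-entry), and every
listed file must actually be present in the ZIP. The converse — every ZIP
member should be listed — is a "should" rule, so unlisted members are
surfaced (as `unlisted_payloads()` and validator warning `W1`) rather than
hidden.

Format URIs partition into three categories. URIs under
`http://identifiers.org/combine.specifications/` are COMBINE specification
identifiers; URIs under `http://purl.org/NET/mediatypes/` are Internet media
types; and a media-type whose name matches `type/x.name` (with `type` drawn
from a pinned set of IANA top-level types: application, audio, example,
font, haptics, image, message, model, multipart, text, video) is an
*unregistered* media type. Registration of ordinary subtypes is deliberately
not checked — that would require a live IANA snapshot and the container's
semantics do not depend on it. Any other syntactically valid absolute URI is
accepted and classified as a media-type claim, but the validator flags it
(`W4`, warning) since tools cannot be expected to resolve it.

Locations are case-sensitive byte strings compared after normalization
(leading `./` stripped, empty and `.` segments dropped, `..` resolved,
forward slashes only). Normalization is idempotent and total on accepted
inputs; anything with a scheme or leading `/`, or that escapes the archive
root, is rejected — this is also the path-traversal guard for extraction.
The property suite checks normalization against `posixpath.normpath` as an
independent oracle.

## Extension choice

`.omex` is the default extension; `.sedx`/`.sbex`/`.cmex`/`.sbox`/`.neux`/
`.phex` advertise a dominant SED-ML/SBML/CellML/SBOL/NeuroML/PharmML
content. Because the extension is only a convenience hint, a heuristic
suffices: a unique master entry's format decides; failing that, if all
payload entries (ignoring `"."`, the manifest and metadata entries) map to
one extension rule, that rule decides; otherwise `.omex`. Explicit
extensions given by the caller are always honored verbatim.

## Manifest serialization

The writer emits the released v1 namespace
(`http://identifiers.org/combine.specifications/omex-manifest`, root
`omexManifest`); the reader also accepts un-namespaced documents, and
ignores unknown elements/attributes with a warning for forward
compatibility. `master` is serialized as literal `"true"`/`"false"` and
absent means false; by default it is written only when true
(`emit_master_always` writes it on every entry). Output is deterministic:
fixed attribute order, manifest entry order, UTF-8, stable pretty-printing.

On creation the library inserts the `"."` self-entry automatically; payload
entries and (when records are given) a `metadata.rdf` entry follow, giving
the canonical five-entry shape for a model + simulation + article + metadata
archive. Whether `manifest.xml` should additionally list itself is genuinely
ambiguous in practice, so it is opt-in (`write_manifest_self_entry`) and
never required on read.

## Metadata

Records attach to `"."` (the archive) or to an entry location, and carry a
Dublin Core description, creators as vCard persons (`hasName` with
`family-name`/`given-name`, `hasEmail`, `organization-name`), one `created`
date and a multi-valued `modified` audit trail. Dates use the W3C date-time
profile; the parser accepts all profile granularities (`YYYY` through full
timestamps with fractional seconds), keeps the original lexical form so
round trips preserve literals, compares on the instant timeline, and
interprets a missing timezone as UTC with a warning. `created` must not be
later than any `modified` date.

The writer is a hand-rolled deterministic RDF/XML emitter (generic RDF
serializers do not guarantee stable blank-node layout, and byte-stable
output is needed for reproducible fixtures); the reader is rdflib, which
also accepts Turtle when the payload is plainly not XML. Triples outside the
modeled vocabulary are preserved opaquely per subject and re-emitted, so
third-party annotations survive a round trip; the tests verify round trips
up to RDF graph isomorphism with rdflib's canonicalization as the oracle.
Metadata may be split over several files: every manifest entry typed with
the omex-metadata format URI is read and merged; writing always produces a
single `metadata.rdf`.

The minimal-metadata check requires the `"."` record to have a creation
date, at least one modification date and at least one creator, returning one
machine-readable finding per missing item. An archive with *no* metadata at
all gets only an informational note (`NO_METADATA`), not a warning: the
metadata file is recommended, not mandatory, and a bare but well-formed
archive should validate clean.

## ZIP layer

Members are deflated at zlib's default level (configurable 0–9); payloads
whose declared media type is already compressed (zip, gzip, png, jpeg) are
stored. Directory entries are never written — locations imply hierarchy.
ZIP64 engages automatically for large archives and entry names are UTF-8.
Encryption is not supported: any entry with the encryption flag set raises a
clear unsupported-feature error on open. Compression statistics count every
member (manifest and metadata included) and define
`ratio = 100 × (1 − compressed/uncompressed)`, clamped at 0 because deflate
adds a few bytes of framing on incompressible input; the ratio is invariant
under entry reordering.

## Validation

The validator is pure and deterministic: it returns findings, never raises,
and severity maps the normative language (must → error, should → warning,
could → info). Errors: missing manifest (`E1`), empty manifest (`E2`),
listed-but-absent file (`E3`), missing/malformed content attributes (`E4`),
non-relative or escaping location (`E5`), plus open-failure codes
(`NOT_A_ZIP`, `XML_PARSE`, `RDF_PARSE`, `UNSUPPORTED`). Warnings: unlisted
member (`W1`, escalated to error under the `strict` profile), multiple
masters (`W2` — readers tolerate several; cardinality is checked, reading
order is not a container concern), incomplete minimal metadata (`W3`),
unrecognizable format URI (`W4`). Entries whose location already failed
`E5` are excluded from the `E3` presence check so a single fault yields a
single finding. Payload bytes are never inspected against the declared
format: validating SBML or SED-ML content is a payload-standard concern,
out of scope for the container.

## Fixtures and what they show

All test inputs are generated: payload stubs are syntactically well-formed
for their container syntax (well-formed XML for the model/simulation stubs,
a `%PDF-1.4` header and `%%EOF` for the PDF stub, seeded bytes for binary
blobs) but semantically meaningless. ZIP timestamps are pinned and metadata
dates fixed, so fixture bytes are a pure function of the fixture spec. The
mutation corpus produces, per validator rule code, an archive breaking
exactly that rule; the test suite asserts exact single-rule firing.
Passing tests therefore demonstrate the container mechanics — manifest and
metadata fidelity, byte-exact payload round trips, rule coverage — not
interoperability with any particular modeling tool, and say nothing about
the biological validity of real payloads.

## Problem sizes and numerical choices

The randomized round-trip suite runs 100 cases of 1–4 payloads up to 2 KB
each; the compression measurement in `scripts/acceptance.py` uses about
10 MB of generated redundant model XML, which deflate reduces by ~99.5% —
chosen as a corpus large enough for stable ratios while keeping the whole
script around a second. Verifying the ≥90% reduction on the published
230 MB metabolic-reconstruction supplement requires downloading that
supplement; the corresponding test performs the download and repack and
fails when the file is unreachable.

## Known limitations

No archive encryption; no remote (URL) payload resolution — everything must
be inside the file; no in-place incremental mutation (the `meta set` command
rebuilds the archive); no schema validation of payload formats; no
element-level cross-linking between files. Locations containing `:` cannot
be given through the CLI's `path:format` shorthand syntax (use the library
API).
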