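"""Exception hierarchy for the package.

Every error raised by this library derives from :class:`OmexError`, so callers
can catch one type at an API boundary.  The validator never raises these for
archive defects — it reports findings — but the constructive APIs (create,
write, extract) fail fast.
"""


class OmexError(Exception):
    """Base class for all errors raised by omexarchive."""


class MalformedURIError(OmexError):
    """A format identifier is not a syntactically valid absolute URI."""


class LocationError(OmexError):
    """Base class for archive-location problems."""


class AbsolutePathError(LocationError):
    """A location carries a scheme or a leading slash; only relative URIs are allowed."""


class PathEscapeError(LocationError):
    """A location resolves outside the archive root (residual '..')."""


class DuplicateLocationError(OmexError):
    """Two entries normalize to the same location."""


class InvariantViolationError(OmexError):
    """A domain-type invariant would be broken by the requested operation."""


class XmlParseError(OmexError):
    """The manifest is not well-formed XML."""


class MissingAttributeError(OmexError):
    """A ``<content>`` element lacks a mandatory ``location`` or ``format`` attribute."""


class RdfParseError(OmexError):
    """The metadata document could not be parsed as RDF."""


class TimestampError(OmexError):
    """A date value is not parseable under the W3C date-time profile."""


class NotAZipError(OmexError):
    """The file is not a ZIP container."""


class MissingManifestError(OmexError):
    """The ZIP has no ``manifest.xml`` at its root."""


class UnknownLocationError(OmexError):
    """The requested location does not exist in the archive."""


class UnsupportedFeatureError(OmexError):
    """The archive uses a ZIP feature this library does not support (e.g. encryption)."""
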