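import pytest

from omexarchive.fixtures import make_reference_archive


@pytest.fixture()
def reference_archive(tmp_path):
    """Path of the worked-example archive (5 manifest entries, SED-ML master)."""
    return make_reference_archive(tmp_path)


# A handwritten five-entry manifest in the published layout: the archive
# self-entry, a model, a simulation flagged master, an article and metadata.
FIVE_ENTRY_MANIFEST = b"""<?xml version="1.0" encoding="utf-8"?>
<omexManifest xmlns="http://identifiers.org/combine.specifications/omex-manifest">
  <content location="." format="http://identifiers.org/combine.specifications/omex"/>
  <content location="./model.xml"
           format="http://identifiers.org/combine.specifications/sbml"/>
  <content location="./simulation.xml"
           format="http://identifiers.org/combine.specifications/sed-ml.level-1.version-2"
           master="true"/>
  <content location="./article.pdf"
           format="http://purl.org/NET/mediatypes/application/pdf"/>
  <content location="./metadata.rdf"
           format="http://identifiers.org/combine.specifications/omex-metadata"/>
</omexManifest>
"""


@pytest.fixture()
def five_entry_manifest_bytes():
    return FIVE_ENTRY_MANIFEST
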