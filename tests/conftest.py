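import pytest

from dasserve.config import parse_server_config
from dasserve.fixtures import (
    FixtureSpec,
    default_stylesheet,
    generate_gff,
    generate_reference,
)
from dasserve.server import DasApplication
from dasserve.sources import parse_gff
from dasserve.xml_io import serialize_stylesheet
from dasserve.commands import StylesheetDocument

# the demo conditions used across the suite: 3 segments of 10 kb with 400
# mixed-type features, and matching 1 kb reference sequences
DEMO_SPEC = FixtureSpec(
    seed=7,
    n_segments=3,
    segment_length=10_000,
    n_features=400,
    feature_length_range=(20, 500),
    fraction_nonpositional=0.02,
)
REF_SPEC = FixtureSpec(
    seed=7,
    n_segments=3,
    segment_length=1000,
    n_features=1,
    feature_length_range=(20, 500),
)


@pytest.fixture(scope="session")
def demo_gff():
    text, book = generate_gff(DEMO_SPEC)
    return text, book


@pytest.fixture(scope="session")
def demo_store(demo_gff):
    text, _ = demo_gff
    return parse_gff(text)


@pytest.fixture(scope="session")
def demo_sequences():
    return generate_reference(REF_SPEC)


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory, demo_gff, demo_sequences):
    """On-disk fixture set: GFF, reference TSV, stylesheet, config."""
    root = tmp_path_factory.mktemp("demo")
    (root / "demo.gff").write_text(demo_gff[0])
    (root / "ref.tsv").write_text(
        "".join(f"{sid}\t{seq}\n" for sid, seq in sorted(demo_sequences.items()))
    )
    (root / "style.xml").write_bytes(
        serialize_stylesheet(StylesheetDocument(stylesheet=default_stylesheet())).bytes
    )
    (root / "config.yaml").write_text(
        f"""
server:
  base_url: http://localhost:8080/das
  gzip: true
  stylesheet: {root / 'style.xml'}
sources:
  - id: demo
    title: Demo annotations
    description: Synthetic demonstration annotations
    maintainer: curator@example.org
    adapter: gff
    capabilities: [features, types, entry_points, stylesheet]
    coordinates:
      authority: TestAssembly
      source_type: Chromosome
      taxid: 9606
    properties:
      file: {root / 'demo.gff'}
  - id: ref
    title: Demo reference
    adapter: reference
    capabilities: [sequence, entry_points, features, types]
    properties:
      file: {root / 'ref.tsv'}
"""
    )
    return root


@pytest.fixture(scope="session")
def demo_config(demo_dir):
    return parse_server_config((demo_dir / "config.yaml").read_text())


@pytest.fixture(scope="session")
def demo_app(demo_config):
    return DasApplication(demo_config)
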