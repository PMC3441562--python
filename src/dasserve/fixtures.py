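"""Deterministic synthetic data: GFF fixtures, reference sequences, and
random DAS documents.

Everything here is seeded and byte-deterministic across platforms (the
PRNG is Python's Mersenne Twister via ``random.Random``), so generator
bookkeeping can serve as exact ground truth for parser and query-engine
oracles. The generator emulates the *shape* of annotation data — segment
counts, feature densities, length distributions, a type/category
vocabulary, a fraction of whole-sequence annotations — not biologically
realistic annotation statistics.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .commands import (
    EntryPointsDocument,
    FeaturesDocument,
    SequenceDocument,
    SourceEntry,
    SourcesDocument,
    StylesheetDocument,
    TypesDocument,
    UnknownSegmentMarker,
)
from .model import (
    DasFeature,
    DasMethod,
    DasType,
    EntryPoint,
    Glyph,
    Segment,
    SequenceRecord,
    Stylesheet,
    TypeCount,
)

DEFAULT_VOCABULARY = [
    ("exon", "transcription"),
    ("intron", "transcription"),
    ("CDS", "translation"),
    ("repeat_region", "structural"),
    ("binding_site", "miscellaneous"),
]

_RESIDUE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    seed: int
    n_segments: int = 5
    segment_length: int = 100_000
    n_features: int = 1000
    type_vocabulary: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_VOCABULARY)
    )
    feature_length_range: tuple[int, int] = (50, 2000)
    fraction_nonpositional: float = 0.02

    def validate(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments: must be >= 1")
        if self.segment_length < 1:
            raise ValueError("segment_length: must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features: must be >= 1")
        if not self.type_vocabulary:
            raise ValueError("type_vocabulary: must be non-empty")
        lo, hi = self.feature_length_range
        if not (1 <= lo <= hi <= self.segment_length):
            raise ValueError(
                "feature_length_range: need 1 <= min <= max <= segment_length"
            )
        if not (0.0 <= self.fraction_nonpositional <= 1.0):
            raise ValueError("fraction_nonpositional: must be in [0, 1]")


@dataclass
class Bookkeeping:
    """Exact ground truth for the emitted GFF: the oracle side of tests."""

    segment_lengths: dict[str, int]
    per_segment: dict[str, list[DasFeature]]  # sorted by (start, feature_id)
    type_counts: dict[str, int]  # type id -> count


def _segment_id(i: int) -> str:
    return f"seg{i:03d}"


def generate_gff(spec: FixtureSpec) -> tuple[str, Bookkeeping]:
    """Emit GFF3 text plus exact bookkeeping.

    Same seed, same bytes. Feature ids are ``f{segment_index}_{ordinal}``
    (stable, sortable, collision-free). Whole-sequence features are
    written with the ``0 0`` coordinate convention (see
    docs/wire-format.md).
    """
    spec.validate()
    rng = random.Random(spec.seed)
    seg_ids = [_segment_id(i) for i in range(spec.n_segments)]
    lengths = {sid: spec.segment_length for sid in seg_ids}
    per_segment: dict[str, list[DasFeature]] = {sid: [] for sid in seg_ids}
    ordinals = {sid: 0 for sid in seg_ids}
    type_counts: Counter = Counter()
    lines = ["##gff-version 3"]
    for sid in seg_ids:
        lines.append(f"##sequence-region {sid} 1 {spec.segment_length}")
    lo, hi = spec.feature_length_range
    for _ in range(spec.n_features):
        seg_index = rng.randrange(spec.n_segments)
        sid = seg_ids[seg_index]
        ordinals[sid] += 1
        fid = f"f{seg_index}_{ordinals[sid]}"
        type_id, category = rng.choice(spec.type_vocabulary)
        nonpositional = rng.random() < spec.fraction_nonpositional
        if nonpositional:
            start = stop = 0
            orientation, phase = "0", "-"
        else:
            length = rng.randint(lo, hi)
            start = rng.randint(1, spec.segment_length - length + 1)
            stop = start + length - 1
            orientation = rng.choice(("+", "-", "0"))
            phase = rng.choice(("0", "1", "2", "-"))
        score = round(rng.uniform(0, 1000), 3) if rng.random() < 0.5 else None
        notes = [f"synthetic note {fid}"] if rng.random() < 0.2 else []
        feature = DasFeature(
            feature_id=fid,
            type=DasType(id=type_id, category=category),
            method=DasMethod(id="dasserve_fixture"),
            start=start,
            stop=stop,
            score=score,
            orientation=orientation,
            phase=phase,
            notes=notes,
        )
        per_segment[sid].append(feature)
        type_counts[type_id] += 1
        attrs = [f"ID={fid}"]
        if notes:
            attrs.append("Note=" + ",".join(n.replace(" ", "%20") for n in notes))
        if category:
            attrs.append(f"category={category}")
        lines.append(
            "\t".join(
                [
                    sid,
                    "dasserve_fixture",
                    type_id,
                    str(start),
                    str(stop),
                    "." if score is None else repr(score),
                    "." if orientation == "0" else orientation,
                    "." if phase == "-" else phase,
                    ";".join(attrs),
                ]
            )
        )
    for sid in seg_ids:
        per_segment[sid].sort(key=lambda f: (f.start, f.feature_id))
    return "\n".join(lines) + "\n", Bookkeeping(
        segment_lengths=lengths,
        per_segment=per_segment,
        type_counts=dict(type_counts),
    )


def generate_reference(spec: FixtureSpec) -> dict[str, str]:
    """Residue map (segment id -> sequence) matching the GFF segment ids.

    Deterministic by seed; every sequence has length ``segment_length``.
    The stream is independent of :func:`generate_gff` so the two can be
    combined freely under one seed.
    """
    spec.validate()
    rng = random.Random(spec.seed * 2 + 1)
    return {
        _segment_id(i): "".join(
            rng.choice(_RESIDUE_ALPHABET) for _ in range(spec.segment_length)
        )
        for i in range(spec.n_segments)
    }


def whole_file_features_document(spec: FixtureSpec, href: str = "") -> FeaturesDocument:
    """The features response covering every segment of a fixture in full."""
    _, book = generate_gff(spec)
    blocks = []
    for sid in sorted(book.per_segment):
        seg = Segment(id=sid, start=1, stop=book.segment_lengths[sid], version="1.0")
        blocks.append((seg, book.per_segment[sid]))
    return FeaturesDocument(blocks=blocks, href=href)


def measure_features_response(spec: FixtureSpec) -> int:
    """Serialized byte size of the whole-file features response."""
    from .xml_io import serialize_features

    return len(serialize_features(whole_file_features_document(spec)).bytes)


def size_targeted_fixture(
    target_bytes: int,
    tolerance: float = 0.25,
    seed: int = 0,
    max_features: int = 1 << 21,
) -> FixtureSpec:
    """Find a FixtureSpec whose whole-file features response serializes to
    within ``tolerance * target_bytes`` of the target.

    Searches ``n_features`` by doubling then bisection on the monotone
    size-vs-count relation. Raises ValueError reporting the best achieved
    size when the target is unreachable (e.g. below the minimal document).
    """
    if target_bytes < 1:
        raise ValueError("target_bytes: must be positive")

    def spec_for(n: int) -> FixtureSpec:
        return FixtureSpec(seed=seed, n_segments=1, n_features=n)

    def size(n: int) -> int:
        return measure_features_response(spec_for(n))

    lo_n, lo_size = 1, size(1)
    if lo_size > target_bytes * (1 + tolerance):
        raise ValueError(
            f"target {target_bytes} B unreachable: minimal document is {lo_size} B"
        )
    hi_n = 1
    hi_size = lo_size
    while hi_size < target_bytes and hi_n < max_features:
        hi_n *= 2
        hi_size = size(hi_n)
    # bisect for the count whose size is closest to the target
    while hi_n - lo_n > 1:
        mid = (lo_n + hi_n) // 2
        mid_size = size(mid)
        if mid_size < target_bytes:
            lo_n, lo_size = mid, mid_size
        else:
            hi_n, hi_size = mid, mid_size
    best_n, best_size = min(
        ((lo_n, lo_size), (hi_n, hi_size)),
        key=lambda ns: abs(ns[1] - target_bytes),
    )
    if abs(best_size - target_bytes) > tolerance * target_bytes:
        raise ValueError(
            f"target {target_bytes} B unreachable within ±{tolerance:.0%}: "
            f"best achieved {best_size} B with {best_n} features"
        )
    return spec_for(best_n)


# ---------------------------------------------------------------------------
# Random DAS documents (round-trip test material)

_SPECIALS = 'with "<&>\'" specials'


def _token(rng: random.Random, prefix: str) -> str:
    return f"{prefix}{rng.randrange(10_000)}"


def _text(rng: random.Random) -> str:
    if rng.random() < 0.3:
        return f"text {rng.randrange(1000)} {_SPECIALS}"
    return f"plain text {rng.randrange(1000)}"


def _maybe(rng: random.Random, value):
    return value if rng.random() < 0.5 else None


def random_feature(rng: random.Random) -> DasFeature:
    if rng.random() < 0.1:
        start = stop = 0
    else:
        start = rng.randint(1, 10_000)
        stop = start + rng.randint(0, 5000)
    return DasFeature(
        feature_id=_token(rng, "feat"),
        label=_maybe(rng, _text(rng)),
        type=DasType(
            id=_token(rng, "type"),
            category=rng.choice(["transcription", "translation", "", "misc"]),
            cv_id=_maybe(rng, _token(rng, "SO:")),
            description=_maybe(rng, _text(rng)),
        ),
        method=DasMethod(
            id=_token(rng, "method"),
            cv_id=_maybe(rng, _token(rng, "ECO:")),
            label=_maybe(rng, _text(rng)),
        ),
        start=start,
        stop=stop,
        score=_maybe(rng, round(rng.uniform(-100, 100), 4)),
        orientation=rng.choice(("+", "-", "0")),
        phase=rng.choice(("0", "1", "2", "-")),
        notes=[_text(rng) for _ in range(rng.randrange(3))],
        links=[
            (f"http://example.org/{_token(rng, 'link')}", _text(rng))
            for _ in range(rng.randrange(2))
        ],
        targets=[
            (_token(rng, "tgt"), 1 + rng.randrange(100), 101 + rng.randrange(100))
            for _ in range(rng.randrange(2))
        ],
        parents=[_token(rng, "parent") for _ in range(rng.randrange(2))],
        parts=[_token(rng, "part") for _ in range(rng.randrange(2))],
    )


def _random_segment(rng: random.Random) -> Segment:
    start = rng.randint(1, 1000)
    return Segment(
        id=_token(rng, "seg"),
        start=start,
        stop=start + rng.randrange(10_000),
        version=_maybe(rng, _token(rng, "v")),
        label=_maybe(rng, _text(rng)),
    )


def random_features_document(rng: random.Random) -> FeaturesDocument:
    blocks = []
    for _ in range(rng.randint(1, 3)):
        if rng.random() < 0.15:
            if rng.random() < 0.5:
                start = rng.randint(1, 100)
                marker = UnknownSegmentMarker(
                    id=_token(rng, "missing"), start=start, stop=start + rng.randrange(100)
                )
            else:
                marker = UnknownSegmentMarker(id=_token(rng, "missing"))
            blocks.append((marker, []))
            continue
        blocks.append(
            (_random_segment(rng), [random_feature(rng) for _ in range(rng.randrange(5))])
        )
    return FeaturesDocument(blocks=blocks, href=f"http://example.org/das/{_token(rng, 's')}/features")


def random_sequence_document(rng: random.Random) -> SequenceDocument:
    records = []
    for _ in range(rng.randint(1, 3)):
        length = rng.randint(10, 60)
        start = rng.randint(1, 500)
        records.append(
            SequenceRecord(
                segment_id=_token(rng, "seq"),
                start=start,
                stop=start + length - 1,
                version=_token(rng, "v"),
                residues="".join(rng.choice(_RESIDUE_ALPHABET) for _ in range(length)),
            )
        )
    return SequenceDocument(records=records)


def random_types_document(rng: random.Random) -> TypesDocument:
    blocks = []
    if rng.random() < 0.3:
        blocks.append((None, _random_type_counts(rng)))
    else:
        for _ in range(rng.randint(1, 3)):
            if rng.random() < 0.15:
                blocks.append((UnknownSegmentMarker(id=_token(rng, "missing")), []))
            else:
                blocks.append((_random_segment(rng), _random_type_counts(rng)))
    return TypesDocument(blocks=blocks, href=f"http://example.org/das/{_token(rng, 's')}/types")


def _random_type_counts(rng: random.Random) -> list[TypeCount]:
    return [
        TypeCount(
            type=DasType(
                id=_token(rng, "type"),
                category=rng.choice(["transcription", "misc", ""]),
                cv_id=_maybe(rng, _token(rng, "SO:")),
                description=_maybe(rng, _text(rng)),
            ),
            count=_maybe(rng, rng.randrange(10_000)),
        )
        for _ in range(rng.randrange(4))
    ]


def random_entry_points_document(rng: random.Random) -> EntryPointsDocument:
    n = rng.randrange(5)
    first = rng.randint(1, 10)
    return EntryPointsDocument(
        total=n + rng.randrange(100),
        first=first,
        last=first + n - 1,
        entry_points=[
            EntryPoint(
                id=_token(rng, "ep"),
                start=1,
                stop=rng.randint(1, 100_000),
                orientation=rng.choice(("+", "-", "0")),
                type_label=_maybe(rng, _token(rng, "chromosome")),
                description=_maybe(rng, _text(rng)),
                has_subparts=rng.random() < 0.3,
            )
            for _ in range(n)
        ],
        href=f"http://example.org/das/{_token(rng, 's')}/entry_points",
        version=rng.choice(["", "1.0", "2024-01"]),
    )


def random_sources_document(rng: random.Random) -> SourcesDocument:
    sources = []
    for _ in range(rng.randint(1, 3)):
        sid = _token(rng, "src")
        base = f"http://example.org/das/{sid}"
        caps = rng.sample(
            ["entry_points", "sequence", "types", "features", "stylesheet"],
            rng.randint(1, 4),
        )
        sources.append(
            SourceEntry(
                uri=base,
                title=_text(rng),
                description=_text(rng),
                maintainer_email=f"{sid}@example.org",
                version=_token(rng, "v"),
                coordinate_authority=rng.choice(["UniProt", "GRCh38", ""]),
                coordinate_source_type=rng.choice(["Protein Sequence", "Chromosome", ""]),
                organism_taxid=_maybe(rng, rng.randrange(1, 10_000)),
                capabilities=[(c, f"{base}/{c}") for c in caps],
                properties=sorted(
                    (_token(rng, "prop"), _text(rng)) for _ in range(rng.randrange(3))
                ),
            )
        )
    return SourcesDocument(sources=sources)


GLYPH_NAMES = ("box", "line", "arrow", "anchored_arrow", "triangle", "span")
GLYPH_ATTRS = ("FGCOLOR", "BGCOLOR", "HEIGHT", "BUMP", "LABEL")


def random_stylesheet_document(rng: random.Random) -> StylesheetDocument:
    categories = []
    for ci in range(rng.randint(1, 3)):
        type_ids = [f"t{ci}_{i}" for i in range(rng.randint(1, 3))]
        if rng.random() < 0.5:
            type_ids.append("default")
        types = tuple(
            (
                tid,
                Glyph(
                    name=rng.choice(GLYPH_NAMES),
                    attributes=tuple(
                        (attr, _token(rng, "val"))
                        for attr in rng.sample(GLYPH_ATTRS, rng.randrange(len(GLYPH_ATTRS)))
                    ),
                ),
            )
            for tid in type_ids
        )
        categories.append((f"cat{ci}", types))
    return StylesheetDocument(stylesheet=Stylesheet(categories=tuple(categories)))


def default_stylesheet() -> Stylesheet:
    """A small server-default stylesheet covering the fixture vocabulary."""
    return Stylesheet(
        categories=(
            (
                "transcription",
                (
                    ("exon", Glyph("box", (("FGCOLOR", "blue"), ("HEIGHT", "10")))),
                    ("intron", Glyph("line", (("FGCOLOR", "grey"),))),
                    ("default", Glyph("box", (("FGCOLOR", "black"),))),
                ),
            ),
            (
                "default",
                (("default", Glyph("box", (("FGCOLOR", "green"),))),),
            ),
        )
    )


RANDOM_DOCUMENT_GENERATORS = {
    "features": random_features_document,
    "sequence": random_sequence_document,
    "types": random_types_document,
    "entry_points": random_entry_points_document,
    "sources": random_sources_document,
    "stylesheet": random_stylesheet_document,
}
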