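"""Internal DAS object model.

Every adapter populates these types and every serializer consumes them.
Coordinates follow the DAS convention throughout: 1-based, fully
inclusive, forward strand. A feature is either *positional*
(``1 <= start <= stop``) or *non-positional* — an annotation that applies
to the whole sequence (a publication, a taxonomy assignment) — encoded as
``start == stop == 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

ORIENTATIONS = ("+", "-", "0")
PHASES = ("0", "1", "2", "-")


@dataclass(frozen=True)
class Segment:
    """A reference object (chromosome, protein, contig) with its extent."""

    id: str
    start: int
    stop: int
    version: Optional[str] = None
    label: Optional[str] = None


@dataclass(frozen=True)
class SegmentQuery:
    """An accession with an optional 1-based inclusive range.

    ``start`` and ``stop`` are both present (ranged query) or both absent
    (whole-segment query).
    """

    id: str
    start: Optional[int] = None
    stop: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.start is None) != (self.stop is None):
            raise ValueError("segment query range must set both start and stop")
        if self.start is not None and not (1 <= self.start <= self.stop):
            raise ValueError(
                f"invalid segment range {self.start},{self.stop}: need 1 <= start <= stop"
            )

    @property
    def is_ranged(self) -> bool:
        return self.start is not None


@dataclass(frozen=True)
class DasType:
    id: str
    category: str = ""
    cv_id: Optional[str] = None
    description: Optional[str] = None


@dataclass(frozen=True)
class DasMethod:
    id: str
    cv_id: Optional[str] = None
    label: Optional[str] = None


@dataclass
class DasFeature:
    """One annotation on a segment.

    ``score=None`` means "no score" and serializes as the DASGFF literal
    ``-``; it is distinct from a score of 0.0. Orientation ``0`` and phase
    ``-`` mean "not applicable / unknown".
    """

    feature_id: str
    type: DasType
    method: DasMethod
    start: int
    stop: int
    label: Optional[str] = None
    score: Optional[float] = None
    orientation: str = "0"
    phase: str = "-"
    notes: list[str] = field(default_factory=list)
    links: list[tuple[str, str]] = field(default_factory=list)
    targets: list[tuple[str, int, int]] = field(default_factory=list)
    parents: list[str] = field(default_factory=list)
    parts: list[str] = field(default_factory=list)

    @property
    def is_positional(self) -> bool:
        return not (self.start == 0 and self.stop == 0)


@dataclass(frozen=True)
class SequenceRecord:
    segment_id: str
    start: int
    stop: int
    version: str
    residues: str


@dataclass(frozen=True)
class EntryPoint:
    id: str
    start: int
    stop: int
    orientation: str = "0"
    type_label: Optional[str] = None
    description: Optional[str] = None
    has_subparts: bool = False


@dataclass(frozen=True)
class Glyph:
    name: str
    attributes: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class Stylesheet:
    """Server rendering hints: per category, per type id, a glyph.

    The wildcard type id ``default`` applies to types without an explicit
    entry, per classical DAS stylesheet practice.
    """

    categories: tuple[tuple[str, tuple[tuple[str, Glyph], ...]], ...] = ()


@dataclass(frozen=True)
class TypeCount:
    type: DasType
    count: Optional[int] = None


def overlaps(feature: DasFeature, q: SegmentQuery) -> bool:
    """Does ``feature`` belong in the response window of ``q``?

    A whole-segment query matches every feature of the segment. A ranged
    query matches positional features by inclusive interval intersection,
    and always matches non-positional features: a whole-sequence
    annotation is relevant to any window (clients may discard it).
    Total function — never raises.
    """
    if not q.is_ranged:
        return True
    if not feature.is_positional:
        return True
    return feature.start <= q.stop and feature.stop >= q.start


def validate_feature(f: DasFeature) -> list[str]:
    """Return a list of invariant violations, each naming the field.

    Empty list means the feature is well-formed. Out-of-order or mixed
    positional/non-positional coordinates are rejected, never clamped.
    """
    violations: list[str] = []
    if not f.feature_id:
        violations.append("feature_id: must be non-empty")
    if not f.type.id:
        violations.append("type.id: must be non-empty")
    if not f.method.id:
        violations.append("method.id: must be non-empty")
    if f.start == 0 and f.stop == 0:
        pass  # non-positional: whole-sequence annotation
    elif f.start == 0 or f.stop == 0:
        violations.append(
            "start/stop: mixed positional and non-positional coordinates "
            f"({f.start}, {f.stop}); whole-sequence features use start=stop=0"
        )
    elif not (1 <= f.start <= f.stop):
        violations.append(
            f"start/stop: need 1 <= start <= stop, got ({f.start}, {f.stop})"
        )
    if f.orientation not in ORIENTATIONS:
        violations.append(f"orientation: {f.orientation!r} not in {ORIENTATIONS}")
    if f.phase not in PHASES:
        violations.append(f"phase: {f.phase!r} not in {PHASES}")
    if f.score is not None and not isinstance(f.score, (int, float)):
        violations.append("score: must be a real number or absent")
    for tid, tstart, tstop in f.targets:
        if not tid:
            violations.append("targets: target id must be non-empty")
        if not (1 <= tstart <= tstop):
            violations.append(
                f"targets: need 1 <= start <= stop, got ({tstart}, {tstop})"
            )
    return violations
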