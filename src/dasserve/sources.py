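"""Data-source adapter contract and the two built-in adapters.

A provider publishes data by implementing :class:`AnnotationSource` (or
:class:`ReferenceSource` for sources that also serve residues) and
registering the class under a name; the configuration file binds each
declared source to a registered adapter name plus a properties map.

Built-ins:

* ``gff`` — loads a GFF3 file fully into memory and indexes features per
  segment with an interval tree.
* ``reference`` — serves sequences from a plain-text tab-separated file
  (``segment_id<TAB>residues`` per line).
"""

from __future__ import annotations

import abc
import logging
import urllib.parse
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from intervaltree import IntervalTree

from .errors import UNKNOWN_SEGMENT, AdapterError, BadReferenceObject
from .model import (
    DasFeature,
    DasMethod,
    DasType,
    EntryPoint,
    Segment,
    SegmentQuery,
    SequenceRecord,
    Stylesheet,
    TypeCount,
    overlaps,
    validate_feature,
)

log = logging.getLogger(__name__)


class AnnotationSource(abc.ABC):
    """Contract every annotation adapter must satisfy.

    Invariants: a ranged ``get_features_by_segment`` result is a subset of
    the whole-segment result for the same id; entry-point totals are
    stable across pages.
    """

    #: capabilities instances of this adapter can serve
    capabilities: frozenset[str] = frozenset(
        {"entry_points", "types", "features", "stylesheet"}
    )

    @abc.abstractmethod
    def init(self, properties: dict[str, str]) -> None:
        """Bind the adapter to its backing data; raise AdapterError on failure."""

    @abc.abstractmethod
    def get_entry_points(
        self, offset: int, limit: int
    ) -> tuple[int, list[EntryPoint]]:
        """Return (total count, page) with lexicographic id ordering.

        ``offset`` is 0-based into the full lexicographic listing.
        """

    @abc.abstractmethod
    def get_features_by_segment(self, q: SegmentQuery):
        """Features overlapping ``q`` in (start, feature_id) order, or
        the UNKNOWN_SEGMENT signal."""

    @abc.abstractmethod
    def get_features_by_id(
        self, feature_id: str
    ) -> list[tuple[Segment, DasFeature]]:
        """Features with the given id, each with its owning segment."""

    @abc.abstractmethod
    def get_types(self) -> list[TypeCount]:
        """Source-wide type counts, ordered by type id."""

    @abc.abstractmethod
    def get_types_for_segment(self, q: SegmentQuery) -> list[TypeCount]:
        """Type counts over the features overlapping ``q``."""

    def get_stylesheet(self) -> Optional[Stylesheet]:
        return None

    def get_segment(self, segment_id: str) -> Optional[Segment]:
        """Extent of a segment this source covers, or None."""
        return None


class ReferenceSource(AnnotationSource):
    """An annotation source that additionally serves residues."""

    capabilities = frozenset(
        {"entry_points", "types", "features", "stylesheet", "sequence"}
    )

    @abc.abstractmethod
    def get_sequence(self, q: SegmentQuery):
        """SequenceRecord for ``q`` or the UNKNOWN_SEGMENT signal.

        A ranged query past the segment's length raises
        :class:`BadReferenceObject` — never silent truncation.
        """


# ---------------------------------------------------------------------------
# GFF3 parsing and interval-indexed store


@dataclass
class _SegmentIndex:
    bound: int = 0  # from ##sequence-region, else max feature stop
    tree: IntervalTree = field(default_factory=IntervalTree)
    nonpositional: list[DasFeature] = field(default_factory=list)
    n_features: int = 0


@dataclass
class GffStore:
    """In-memory feature store: per-segment interval indexes plus lookups."""

    segments: dict[str, _SegmentIndex] = field(default_factory=dict)
    feature_index: dict[str, tuple[str, DasFeature]] = field(default_factory=dict)
    types: Counter = field(default_factory=Counter)  # DasType -> count


def _parse_attributes(text: str) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    if text in (".", ""):
        return attrs
    for part in text.split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs.setdefault(key, []).extend(
            urllib.parse.unquote(v) for v in value.split(",")
        )
    return attrs


def parse_gff(stream: Union[str, Iterable[str]]) -> GffStore:
    """Parse GFF3 text into a :class:`GffStore`.

    Column mapping: seqid -> segment id, source -> method id, type ->
    type id, start/stop -> positions (``0 0`` encodes a whole-sequence
    feature — a dialect extension, see docs/wire-format.md), score
    (``.`` -> absent), strand (``.`` -> ``0``), phase (``.`` -> ``-``).
    Attributes: ``ID`` -> feature id (``line<N>`` autogenerated when
    absent), ``Note`` -> notes, ``Parent`` -> parents, ``category`` ->
    the type's category. ``##sequence-region`` directives set segment
    bounds. Raises ValueError with the line number on malformed lines.
    """
    if isinstance(stream, str):
        lines: Iterable[str] = stream.splitlines()
    else:
        lines = stream
    store = GffStore()
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                seg = store.segments.setdefault(parts[1], _SegmentIndex())
                try:
                    seg.bound = max(seg.bound, int(parts[3]))
                except ValueError as exc:
                    raise ValueError(
                        f"line {lineno}: non-numeric sequence-region bound"
                    ) from exc
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
            )
        seqid, source, ftype, start_s, stop_s, score_s, strand, phase, attr_s = cols
        try:
            start, stop = int(start_s), int(stop_s)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric coordinate") from exc
        if (start == 0) != (stop == 0):
            raise ValueError(
                f"line {lineno}: coordinate 0 is only valid as start=stop=0 "
                "(whole-sequence feature)"
            )
        if start > stop:
            raise ValueError(f"line {lineno}: start {start} > stop {stop}")
        score = None if score_s == "." else float(score_s)
        orientation = "0" if strand == "." else strand
        if orientation not in ("+", "-", "0"):
            raise ValueError(f"line {lineno}: bad strand {strand!r}")
        phase_v = "-" if phase == "." else phase
        attrs = _parse_attributes(attr_s)
        feature_id = attrs.get("ID", [f"line{lineno}"])[0]
        category = attrs.get("category", [""])[0]
        feature = DasFeature(
            feature_id=feature_id,
            type=DasType(id=ftype, category=category),
            method=DasMethod(id=source),
            start=start,
            stop=stop,
            score=score,
            orientation=orientation,
            phase=phase_v,
            notes=attrs.get("Note", []),
            parents=attrs.get("Parent", []),
        )
        problems = validate_feature(feature)
        if problems:
            raise ValueError(f"line {lineno}: invalid feature: {'; '.join(problems)}")
        seg = store.segments.setdefault(seqid, _SegmentIndex())
        if feature.is_positional:
            # intervaltree is half-open; DAS coordinates are inclusive
            seg.tree.addi(feature.start, feature.stop + 1, feature)
            seg.bound = max(seg.bound, feature.stop)
        else:
            seg.nonpositional.append(feature)
        seg.n_features += 1
        if feature_id in store.feature_index:
            log.warning("duplicate feature ID %r: last occurrence wins", feature_id)
        store.feature_index[feature_id] = (seqid, feature)
        store.types[feature.type] += 1
    return store


def _escape_attr(value: str) -> str:
    return urllib.parse.quote(value, safe=" :/^*!|&@()[]{}'\"<>`~?+=")


def serialize_gff(store: GffStore) -> str:
    """Write a :class:`GffStore` back out as GFF3 (feature-level round-trip;
    comment lines are not preserved)."""
    out = ["##gff-version 3"]
    for seqid in sorted(store.segments):
        seg = store.segments[seqid]
        out.append(f"##sequence-region {seqid} 1 {seg.bound}")
    for seqid in sorted(store.segments):
        for f in iter_segment_features(store, seqid):
            attrs = [f"ID={_escape_attr(f.feature_id)}"]
            if f.parents:
                attrs.append("Parent=" + ",".join(_escape_attr(p) for p in f.parents))
            if f.notes:
                attrs.append("Note=" + ",".join(_escape_attr(n) for n in f.notes))
            if f.type.category:
                attrs.append(f"category={_escape_attr(f.type.category)}")
            out.append(
                "\t".join(
                    [
                        seqid,
                        f.method.id,
                        f.type.id,
                        str(f.start),
                        str(f.stop),
                        "." if f.score is None else repr(f.score),
                        "." if f.orientation == "0" else f.orientation,
                        "." if f.phase == "-" else f.phase,
                        ";".join(attrs),
                    ]
                )
            )
    return "\n".join(out) + "\n"


def iter_segment_features(store: GffStore, segment_id: str) -> list[DasFeature]:
    """All features of one segment in deterministic (start, feature_id) order;
    non-positional features sort first (start 0)."""
    seg = store.segments[segment_id]
    feats = [iv.data for iv in seg.tree] + list(seg.nonpositional)
    feats.sort(key=lambda f: (f.start, f.feature_id))
    return feats


def query_interval_index(store: GffStore, q: SegmentQuery):
    """Features of ``store`` overlapping ``q``, or UNKNOWN_SEGMENT.

    Exactly the features for which :func:`dasserve.model.overlaps` is
    true, in ascending (start, feature_id) order. Non-positional features
    are returned for both whole-segment and ranged queries.
    """
    seg = store.segments.get(q.id)
    if seg is None:
        return UNKNOWN_SEGMENT
    if not q.is_ranged:
        return iter_segment_features(store, q.id)
    hits = [iv.data for iv in seg.tree.overlap(q.start, q.stop + 1)]
    hits.extend(seg.nonpositional)
    hits.sort(key=lambda f: (f.start, f.feature_id))
    return hits


# ---------------------------------------------------------------------------
# Built-in adapters


def _tally(features: list[DasFeature]) -> list[TypeCount]:
    counts: Counter = Counter(f.type for f in features)
    return [TypeCount(type=t, count=n) for t, n in sorted(counts.items(), key=lambda kv: kv[0].id)]


class GffFileSource(AnnotationSource):
    """Annotation adapter backed by one GFF3 file, loaded fully in memory.

    Properties: ``file`` (required) — path to the GFF file. Entry points
    are synthesized from observed seqids; the stop bound is the larger of
    the ``##sequence-region`` directive and the maximum feature stop.
    """

    def __init__(self) -> None:
        self.store: GffStore = GffStore()
        self._version = "1.0"

    def init(self, properties: dict[str, str]) -> None:
        path = properties.get("file")
        if not path:
            raise AdapterError("gff adapter: missing required property 'file'")
        try:
            with open(path, "r", encoding="utf-8") as fh:
                self.store = parse_gff(fh)
        except OSError as exc:
            raise AdapterError(f"gff adapter: cannot read 'file' {path!r}: {exc}") from exc
        except ValueError as exc:
            raise AdapterError(f"gff adapter: parse error in {path!r}: {exc}") from exc
        self._version = properties.get("version", "1.0")

    def load_store(self, store: GffStore) -> None:
        """Bind a pre-built store directly (programmatic use)."""
        self.store = store

    def get_segment(self, segment_id: str) -> Optional[Segment]:
        seg = self.store.segments.get(segment_id)
        if seg is None:
            return None
        return Segment(id=segment_id, start=1, stop=max(seg.bound, 1), version=self._version)

    def get_entry_points(self, offset: int, limit: int) -> tuple[int, list[EntryPoint]]:
        ids = sorted(self.store.segments)
        page = [
            EntryPoint(id=sid, start=1, stop=max(self.store.segments[sid].bound, 1))
            for sid in ids[offset : offset + limit]
        ]
        return len(ids), page

    def get_features_by_segment(self, q: SegmentQuery):
        return query_interval_index(self.store, q)

    def get_features_by_id(self, feature_id: str) -> list[tuple[Segment, DasFeature]]:
        hit = self.store.feature_index.get(feature_id)
        if hit is None:
            return []
        seqid, feature = hit
        return [(self.get_segment(seqid), feature)]

    def get_types(self) -> list[TypeCount]:
        return [
            TypeCount(type=t, count=n)
            for t, n in sorted(self.store.types.items(), key=lambda kv: kv[0].id)
        ]

    def get_types_for_segment(self, q: SegmentQuery) -> list[TypeCount]:
        hits = query_interval_index(self.store, q)
        if hits is UNKNOWN_SEGMENT:
            return []
        return _tally(hits)


def get_sequence_builtin(
    sequences: dict[str, str], q: SegmentQuery, version: str = "1.0"
):
    """Slice a residue map by a segment query (1-based inclusive).

    Whole-segment query returns the full residues with start=1,
    stop=length. A ranged query past the end raises
    :class:`BadReferenceObject` rather than truncating.
    """
    residues = sequences.get(q.id)
    if residues is None:
        return UNKNOWN_SEGMENT
    length = len(residues)
    if not q.is_ranged:
        return SequenceRecord(
            segment_id=q.id, start=1, stop=length, version=version, residues=residues
        )
    if q.stop > length:
        raise BadReferenceObject(
            f"segment {q.id}: range {q.start},{q.stop} exceeds length {length}"
        )
    return SequenceRecord(
        segment_id=q.id,
        start=q.start,
        stop=q.stop,
        version=version,
        residues=residues[q.start - 1 : q.stop],
    )


class InMemoryReferenceSource(ReferenceSource):
    """Reference adapter serving residues from a plain-text TSV file.

    Properties: ``file`` (required) — path to a file with one
    ``segment_id<TAB>residues`` record per line; ``version`` (optional).
    """

    def __init__(self) -> None:
        self.sequences: dict[str, str] = {}
        self.version = "1.0"

    def init(self, properties: dict[str, str]) -> None:
        path = properties.get("file")
        if not path:
            raise AdapterError("reference adapter: missing required property 'file'")
        try:
            with open(path, "r", encoding="utf-8") as fh:
                for lineno, line in enumerate(fh, start=1):
                    line = line.rstrip("\n")
                    if not line:
                        continue
                    if "\t" not in line:
                        raise AdapterError(
                            f"reference adapter: line {lineno}: expected id<TAB>residues"
                        )
                    sid, _, residues = line.partition("\t")
                    self.sequences[sid] = residues
        except OSError as exc:
            raise AdapterError(
                f"reference adapter: cannot read 'file' {path!r}: {exc}"
            ) from exc
        self.version = properties.get("version", "1.0")

    def load_sequences(self, sequences: dict[str, str]) -> None:
        self.sequences = dict(sequences)

    def get_segment(self, segment_id: str) -> Optional[Segment]:
        residues = self.sequences.get(segment_id)
        if residues is None:
            return None
        return Segment(id=segment_id, start=1, stop=len(residues), version=self.version)

    def get_sequence(self, q: SegmentQuery):
        return get_sequence_builtin(self.sequences, q, version=self.version)

    def get_entry_points(self, offset: int, limit: int) -> tuple[int, list[EntryPoint]]:
        ids = sorted(self.sequences)
        page = [
            EntryPoint(id=sid, start=1, stop=len(self.sequences[sid]))
            for sid in ids[offset : offset + limit]
        ]
        return len(ids), page

    def get_features_by_segment(self, q: SegmentQuery):
        if q.id not in self.sequences:
            return UNKNOWN_SEGMENT
        return []

    def get_features_by_id(self, feature_id: str) -> list[tuple[Segment, DasFeature]]:
        return []

    def get_types(self) -> list[TypeCount]:
        return []

    def get_types_for_segment(self, q: SegmentQuery) -> list[TypeCount]:
        return []


# ---------------------------------------------------------------------------
# Adapter registry

_REGISTRY: dict[str, type[AnnotationSource]] = {}


def register_adapter(name: str, cls: type[AnnotationSource]) -> None:
    _REGISTRY[name] = cls


def adapter_registry() -> dict[str, frozenset[str]]:
    """Adapter name -> capability set, as consumed by config validation."""
    return {name: cls.capabilities for name, cls in _REGISTRY.items()}


def load_adapter(name: str, properties: dict[str, str]) -> AnnotationSource:
    """Instantiate and initialize a registered adapter.

    Raises :class:`AdapterError` for an unknown name or a failing init
    (e.g. a gff source without its ``file`` property).
    """
    cls = _REGISTRY.get(name)
    if cls is None:
        raise AdapterError(
            f"unknown adapter {name!r}; registered: {sorted(_REGISTRY)}"
        )
    handle = cls()
    handle.init(properties)
    return handle


register_adapter("gff", GffFileSource)
register_adapter("reference", InMemoryReferenceSource)
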