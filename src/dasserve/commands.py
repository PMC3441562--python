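"""Command engine: parse DAS request URLs, dispatch, assemble documents.

The controller of the framework. A URL like
``/das/demo/features?segment=chr1:100,200;type=exon`` is parsed into a
:class:`DasCommand`, routed to the configured source's adapter, filtered,
and assembled into one of the six typed documents that the XML layer
serializes. Errors are raised as the :mod:`dasserve.errors` taxonomy and
mapped to HTTP statuses by the frontend.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Union

from .config import DataSourceConfig, ServerConfig
from .errors import (
    UNKNOWN_SEGMENT,
    BadCommand,
    BadCommandArgs,
    BadDataSource,
    BadReferenceObject,
    BadStylesheet,
)
from .model import (
    DasFeature,
    EntryPoint,
    Segment,
    SegmentQuery,
    SequenceRecord,
    Stylesheet,
    TypeCount,
)
from .sources import AnnotationSource, ReferenceSource

COMMANDS = ("sources", "entry_points", "sequence", "types", "features", "stylesheet")


@dataclass(frozen=True)
class UnknownSegmentMarker:
    """Placeholder block for a segment id the annotation source does not cover."""

    id: str
    start: Optional[int] = None
    stop: Optional[int] = None


@dataclass
class DasCommand:
    command: str
    source_id: Optional[str] = None
    segments: list[SegmentQuery] = field(default_factory=list)
    type_filters: list[str] = field(default_factory=list)
    category_filters: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)
    rows: Optional[tuple[int, int]] = None


# -- typed documents --------------------------------------------------------

SegmentBlock = tuple[Union[Segment, UnknownSegmentMarker], list[DasFeature]]


@dataclass
class FeaturesDocument:
    blocks: list[SegmentBlock]
    href: str = ""


@dataclass
class SourceEntry:
    """Metadata of one source as advertised by the sources command."""

    uri: str
    title: str
    description: str
    maintainer_email: str
    version: str
    coordinate_authority: str
    coordinate_source_type: str
    organism_taxid: Optional[int]
    capabilities: list[tuple[str, str]]  # (capability, query URI)
    properties: list[tuple[str, str]]


@dataclass
class SourcesDocument:
    sources: list[SourceEntry]


TypeBlock = tuple[Union[Segment, UnknownSegmentMarker, None], list[TypeCount]]


@dataclass
class TypesDocument:
    blocks: list[TypeBlock]
    href: str = ""


@dataclass
class EntryPointsDocument:
    total: int
    first: int  # 1-based inclusive effective window; first > last when empty
    last: int
    entry_points: list[EntryPoint]
    href: str = ""
    version: str = ""


@dataclass
class SequenceDocument:
    records: list[SequenceRecord]


@dataclass
class StylesheetDocument:
    stylesheet: Stylesheet


# -- request parsing ---------------------------------------------------------

_SEGMENT_RE = re.compile(r"^([^:]+)(?::(\d+),(\d+))?$")
_ROWS_RE = re.compile(r"^(\d+)-(\d+)$")


def _parse_query_params(query: str) -> list[tuple[str, str]]:
    # DAS allows both ';' and '&' as separators
    pairs: list[tuple[str, str]] = []
    for chunk in re.split(r"[;&]", query):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        from urllib.parse import unquote_plus

        pairs.append((unquote_plus(key), unquote_plus(value)))
    return pairs


def parse_segment_arg(value: str) -> SegmentQuery:
    m = _SEGMENT_RE.match(value)
    if not m:
        raise BadCommandArgs(f"malformed segment argument {value!r}")
    sid, start_s, stop_s = m.groups()
    if not sid:
        raise BadCommandArgs(f"malformed segment argument {value!r}: empty id")
    if start_s is None:
        return SegmentQuery(id=sid)
    start, stop = int(start_s), int(stop_s)
    if not (1 <= start <= stop):
        raise BadCommandArgs(
            f"malformed segment range {value!r}: need 1 <= start <= stop"
        )
    return SegmentQuery(id=sid, start=start, stop=stop)


def parse_request(path: str, query: str = "") -> DasCommand:
    """Parse a DAS request path + raw query string into a command.

    Recognizes ``/das/sources`` and ``/das/{source}/{command}``; repeated
    ``segment=`` parameters accumulate in request order. ``maxbins`` is
    accepted and ignored (the built-in adapters do not bin).
    """
    parts = [p for p in path.split("/") if p]
    if not parts or parts[0] != "das":
        raise BadCommand(f"path {path!r} is not under the /das mount point")
    if len(parts) == 2 and parts[1] == "sources":
        cmd = DasCommand(command="sources")
    elif len(parts) == 3 and parts[1] == "sources":
        cmd = DasCommand(command="sources", source_id=parts[2])
    elif len(parts) == 3:
        if parts[2] not in COMMANDS:
            raise BadCommand(f"unknown command {parts[2]!r}")
        cmd = DasCommand(command=parts[2], source_id=parts[1])
    else:
        raise BadCommand(f"unrecognized DAS path {path!r}")

    for key, value in _parse_query_params(query):
        if key == "segment":
            cmd.segments.append(parse_segment_arg(value))
        elif key == "type":
            cmd.type_filters.append(value)
        elif key == "category":
            cmd.category_filters.append(value)
        elif key == "feature_id":
            cmd.feature_ids.append(value)
        elif key == "rows":
            m = _ROWS_RE.match(value)
            if not m:
                raise BadCommandArgs(f"malformed rows argument {value!r}")
            first, last = int(m.group(1)), int(m.group(2))
            if first < 1 or first > last:
                raise BadCommandArgs(
                    f"malformed rows window {value!r}: need 1 <= first <= last"
                )
            cmd.rows = (first, last)
        elif key == "maxbins":
            pass  # accepted and ignored; built-in adapters do not bin
        # unknown parameters are ignored (forward compatibility)
    return cmd


def render_request(cmd: DasCommand) -> str:
    """Canonical URL for a command (inverse of :func:`parse_request`)."""
    if cmd.command == "sources":
        path = "/das/sources" if cmd.source_id is None else f"/das/sources/{cmd.source_id}"
    else:
        path = f"/das/{cmd.source_id}/{cmd.command}"
    params: list[str] = []
    for q in cmd.segments:
        params.append(
            f"segment={q.id}" if not q.is_ranged else f"segment={q.id}:{q.start},{q.stop}"
        )
    params.extend(f"type={t}" for t in cmd.type_filters)
    params.extend(f"category={c}" for c in cmd.category_filters)
    params.extend(f"feature_id={f}" for f in cmd.feature_ids)
    if cmd.rows is not None:
        params.append(f"rows={cmd.rows[0]}-{cmd.rows[1]}")
    return path + (";".join(params) and "?" + ";".join(params))


# -- execution ---------------------------------------------------------------


def _segment_for_query(handle: AnnotationSource, q: SegmentQuery) -> Segment:
    seg = handle.get_segment(q.id)
    if seg is None:
        seg = Segment(id=q.id, start=q.start or 1, stop=q.stop or 1)
    if q.is_ranged:
        # the response block reports the queried window
        return Segment(id=seg.id, start=q.start, stop=q.stop, version=seg.version)
    return seg


def _matches_filters(
    f: DasFeature, type_filters: list[str], category_filters: list[str]
) -> bool:
    if type_filters and f.type.id not in type_filters:
        return False
    if category_filters and f.type.category not in category_filters:
        return False
    return True


def execute_features(
    handle: AnnotationSource,
    queries: list[SegmentQuery],
    type_filters: list[str],
    category_filters: list[str],
    feature_ids: list[str],
    href: str = "",
) -> FeaturesDocument:
    """Assemble the DASGFF feature response.

    One block per requested segment query, in request order; an unknown
    segment id becomes an in-document UNKNOWNSEGMENT block, not an error.
    Feature-id queries resolve via the adapter's id index and are wrapped
    in their own segment blocks.
    """
    if not queries and not feature_ids:
        raise BadCommandArgs("features command needs at least one segment or feature_id")
    blocks: list[SegmentBlock] = []
    for q in queries:
        result = handle.get_features_by_segment(q)
        if result is UNKNOWN_SEGMENT:
            blocks.append((UnknownSegmentMarker(id=q.id, start=q.start, stop=q.stop), []))
            continue
        feats = [f for f in result if _matches_filters(f, type_filters, category_filters)]
        blocks.append((_segment_for_query(handle, q), feats))
    for fid in feature_ids:
        hits = handle.get_features_by_id(fid)
        if not hits:
            blocks.append((UnknownSegmentMarker(id=fid), []))
            continue
        for seg, feat in hits:
            if _matches_filters(feat, type_filters, category_filters):
                blocks.append((seg, [feat]))
    return FeaturesDocument(blocks=blocks, href=href)


def execute_sequence(
    handle: AnnotationSource, queries: list[SegmentQuery]
) -> SequenceDocument:
    """One SequenceRecord per query; unknown ids and out-of-bounds ranges
    raise BAD_REFERENCE_OBJECT (reference sources treat them as errors)."""
    if not isinstance(handle, ReferenceSource):
        raise BadCommand("source does not serve sequence")
    if not queries:
        raise BadCommandArgs("sequence command needs at least one segment")
    records: list[SequenceRecord] = []
    for q in queries:
        rec = handle.get_sequence(q)
        if rec is UNKNOWN_SEGMENT:
            raise BadReferenceObject(f"unknown reference object {q.id!r}")
        records.append(rec)
    return SequenceDocument(records=records)


def execute_types(
    handle: AnnotationSource, queries: list[SegmentQuery], href: str = ""
) -> TypesDocument:
    """Source-wide type counts, or per-segment counts when queried."""
    if not queries:
        return TypesDocument(blocks=[(None, handle.get_types())], href=href)
    blocks: list[TypeBlock] = []
    for q in queries:
        if handle.get_features_by_segment(q) is UNKNOWN_SEGMENT:
            blocks.append((UnknownSegmentMarker(id=q.id, start=q.start, stop=q.stop), []))
            continue
        blocks.append((_segment_for_query(handle, q), handle.get_types_for_segment(q)))
    return TypesDocument(blocks=blocks, href=href)


def execute_entry_points(
    handle: AnnotationSource,
    rows: Optional[tuple[int, int]],
    page_size_default: int,
    href: str = "",
    version: str = "",
) -> EntryPointsDocument:
    """Paginated entry-point listing with a stable total.

    The window is 1-based inclusive and clipped to ``[1, total]``; a
    window entirely past the end yields an empty page, not an error.
    """
    total, _ = handle.get_entry_points(0, 0)
    if rows is None:
        first, last = 1, min(page_size_default, total)
    else:
        first, last = rows
        last = min(last, total)
    if first > total or first > last:
        return EntryPointsDocument(
            total=total, first=first, last=first - 1, entry_points=[],
            href=href, version=version,
        )
    _, page = handle.get_entry_points(first - 1, last - first + 1)
    return EntryPointsDocument(
        total=total, first=first, last=last, entry_points=page,
        href=href, version=version,
    )


def execute_stylesheet(
    handle: AnnotationSource, server_default: Optional[Stylesheet]
) -> StylesheetDocument:
    """The adapter's stylesheet if present, else the server default."""
    sheet = handle.get_stylesheet()
    if sheet is None:
        sheet = server_default
    if sheet is None:
        raise BadStylesheet("no stylesheet available for this source")
    return StylesheetDocument(stylesheet=sheet)


def source_entry(cfg: ServerConfig, src: DataSourceConfig) -> SourceEntry:
    base = cfg.base_url.rstrip("/")
    return SourceEntry(
        uri=f"{base}/{src.source_id}",
        title=src.title,
        description=src.description,
        maintainer_email=src.maintainer_email,
        version=src.version,
        coordinate_authority=src.coordinate_authority,
        coordinate_source_type=src.coordinate_source_type,
        organism_taxid=src.organism_taxid,
        capabilities=[
            (cap, f"{base}/{src.source_id}/{cap}")
            for cap in src.capabilities
            if cap != "sources"
        ],
        properties=sorted(src.properties.items()),
    )


def execute(
    cmd: DasCommand,
    cfg: ServerConfig,
    adapters: dict[str, AnnotationSource],
):
    """Dispatch a parsed command to the right source and capability.

    Raises BAD_DATA_SOURCE for an unknown source id and BAD_COMMAND when
    the source does not declare the requested capability.
    """
    if cmd.command == "sources":
        if cmd.source_id is not None:
            src = cfg.source(cmd.source_id)
            if src is None:
                raise BadDataSource(f"unknown data source {cmd.source_id!r}")
            return SourcesDocument(sources=[source_entry(cfg, src)])
        return SourcesDocument(sources=[source_entry(cfg, s) for s in cfg.sources])

    src = cfg.source(cmd.source_id or "")
    if src is None:
        raise BadDataSource(f"unknown data source {cmd.source_id!r}")
    if cmd.command not in src.capabilities:
        raise BadCommand(
            f"source {src.source_id!r} does not implement {cmd.command!r}"
        )
    handle = adapters[src.source_id]
    base = cfg.base_url.rstrip("/")
    href = f"{base}/{src.source_id}/{cmd.command}"

    if cmd.command == "features":
        return execute_features(
            handle, cmd.segments, cmd.type_filters, cmd.category_filters,
            cmd.feature_ids, href=href,
        )
    if cmd.command == "sequence":
        return execute_sequence(handle, cmd.segments)
    if cmd.command == "types":
        return execute_types(handle, cmd.segments, href=href)
    if cmd.command == "entry_points":
        return execute_entry_points(
            handle, cmd.rows, cfg.entry_points_page_size, href=href,
            version=src.version,
        )
    if cmd.command == "stylesheet":
        return execute_stylesheet(handle, _server_default_stylesheet(cfg))
    raise BadCommand(f"unknown command {cmd.command!r}")  # pragma: no cover


def _server_default_stylesheet(cfg: ServerConfig) -> Optional[Stylesheet]:
    if cfg.stylesheet_default_path is None:
        return None
    from .xml_io import parse_stylesheet

    with open(cfg.stylesheet_default_path, "rb") as fh:
        return parse_stylesheet(fh.read()).stylesheet
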