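"""DAS wire-format XML: serializers and parsers for the six document kinds.

Root elements follow the classical DAS wire format (UPPERCASE): DASGFF
(features), DASSEQUENCE, DASTYPES, DASEP (entry points), SOURCES and
DASSTYLE. The exact element grammar is documented in
``docs/wire-format.md``; DTD declarations are omitted and validation is
structural. Serialization is deterministic: equal documents produce
byte-identical payloads, and ``parse(serialize(d)) == d`` for every kind.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
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
    validate_feature,
)

CONTENT_TYPE = "text/xml"


@dataclass(frozen=True)
class XmlPayload:
    bytes: bytes
    content_type: str = CONTENT_TYPE


def _to_payload(root: ET.Element) -> XmlPayload:
    body = ET.tostring(root, encoding="UTF-8", xml_declaration=True)
    return XmlPayload(bytes=body)


def _req(el: ET.Element, attr: str) -> str:
    value = el.get(attr)
    if value is None:
        raise ValueError(f"element {el.tag}: missing required attribute {attr!r}")
    return value


def _root(xml: bytes, expected: str) -> ET.Element:
    root = ET.fromstring(xml)
    if root.tag != expected:
        raise ValueError(f"wrong document kind: expected root {expected}, got {root.tag}")
    return root


def _fmt_score(score: Optional[float]) -> str:
    return "-" if score is None else repr(float(score))


def _parse_score(text: str) -> Optional[float]:
    return None if text == "-" else float(text)


# ---------------------------------------------------------------------------
# features / DASGFF


def _segment_el(parent: ET.Element, seg: Segment) -> ET.Element:
    el = ET.SubElement(parent, "SEGMENT", id=seg.id, start=str(seg.start), stop=str(seg.stop))
    if seg.version is not None:
        el.set("version", seg.version)
    if seg.label is not None:
        el.set("label", seg.label)
    return el


def _parse_segment_attrs(el: ET.Element) -> Segment:
    return Segment(
        id=_req(el, "id"),
        start=int(_req(el, "start")),
        stop=int(_req(el, "stop")),
        version=el.get("version"),
        label=el.get("label"),
    )


def _unknown_el(parent: ET.Element, marker: UnknownSegmentMarker) -> None:
    el = ET.SubElement(parent, "UNKNOWNSEGMENT", id=marker.id)
    if marker.start is not None:
        el.set("start", str(marker.start))
    if marker.stop is not None:
        el.set("stop", str(marker.stop))


def _parse_unknown(el: ET.Element) -> UnknownSegmentMarker:
    start, stop = el.get("start"), el.get("stop")
    return UnknownSegmentMarker(
        id=_req(el, "id"),
        start=int(start) if start is not None else None,
        stop=int(stop) if stop is not None else None,
    )


def serialize_features(doc: FeaturesDocument) -> XmlPayload:
    """DASGFF -> GFF(href) -> SEGMENT / UNKNOWNSEGMENT blocks.

    Refuses to serialize a document whose features violate the model
    invariants; absent scores serialize as the literal ``-``.
    """
    root = ET.Element("DASGFF")
    gff = ET.SubElement(root, "GFF", href=doc.href)
    for block, features in doc.blocks:
        if isinstance(block, UnknownSegmentMarker):
            _unknown_el(gff, block)
            continue
        seg_el = _segment_el(gff, block)
        for f in features:
            problems = validate_feature(f)
            if problems:
                raise ValueError(
                    f"refusing to serialize invalid feature {f.feature_id!r}: "
                    + "; ".join(problems)
                )
            fe = ET.SubElement(seg_el, "FEATURE", id=f.feature_id)
            if f.label is not None:
                fe.set("label", f.label)
            te = ET.SubElement(fe, "TYPE", id=f.type.id)
            if f.type.cv_id is not None:
                te.set("cvId", f.type.cv_id)
            te.set("category", f.type.category)
            if f.type.description is not None:
                te.text = f.type.description
            me = ET.SubElement(fe, "METHOD", id=f.method.id)
            if f.method.cv_id is not None:
                me.set("cvId", f.method.cv_id)
            if f.method.label is not None:
                me.text = f.method.label
            ET.SubElement(fe, "START").text = str(f.start)
            ET.SubElement(fe, "END").text = str(f.stop)
            ET.SubElement(fe, "SCORE").text = _fmt_score(f.score)
            ET.SubElement(fe, "ORIENTATION").text = f.orientation
            ET.SubElement(fe, "PHASE").text = f.phase
            for note in f.notes:
                ET.SubElement(fe, "NOTE").text = note
            for href, label in f.links:
                le = ET.SubElement(fe, "LINK", href=href)
                le.text = label
            for tid, tstart, tstop in f.targets:
                ET.SubElement(fe, "TARGET", id=tid, start=str(tstart), stop=str(tstop))
            for pid in f.parents:
                ET.SubElement(fe, "PARENT", id=pid)
            for pid in f.parts:
                ET.SubElement(fe, "PART", id=pid)
    return _to_payload(root)


def parse_features(xml: bytes) -> FeaturesDocument:
    root = _root(xml, "DASGFF")
    gff = root.find("GFF")
    if gff is None:
        raise ValueError("DASGFF: missing GFF element")
    doc = FeaturesDocument(blocks=[], href=_req(gff, "href"))
    for el in gff:
        if el.tag == "UNKNOWNSEGMENT":
            doc.blocks.append((_parse_unknown(el), []))
            continue
        if el.tag != "SEGMENT":
            continue
        seg = _parse_segment_attrs(el)
        features = []
        for fe in el.findall("FEATURE"):
            te = fe.find("TYPE")
            me = fe.find("METHOD")
            if te is None or me is None:
                raise ValueError("FEATURE: missing TYPE or METHOD element")
            features.append(
                DasFeature(
                    feature_id=_req(fe, "id"),
                    label=fe.get("label"),
                    type=DasType(
                        id=_req(te, "id"),
                        category=_req(te, "category"),
                        cv_id=te.get("cvId"),
                        description=te.text if te.text else None,
                    ),
                    method=DasMethod(
                        id=_req(me, "id"),
                        cv_id=me.get("cvId"),
                        label=me.text if me.text else None,
                    ),
                    start=int(fe.findtext("START", "0").strip()),
                    stop=int(fe.findtext("END", "0").strip()),
                    score=_parse_score(fe.findtext("SCORE", "-").strip()),
                    orientation=fe.findtext("ORIENTATION", "0").strip(),
                    phase=fe.findtext("PHASE", "-").strip(),
                    notes=[n.text or "" for n in fe.findall("NOTE")],
                    links=[(_req(le, "href"), le.text or "") for le in fe.findall("LINK")],
                    targets=[
                        (_req(t, "id"), int(_req(t, "start")), int(_req(t, "stop")))
                        for t in fe.findall("TARGET")
                    ],
                    parents=[_req(p, "id") for p in fe.findall("PARENT")],
                    parts=[_req(p, "id") for p in fe.findall("PART")],
                )
            )
        doc.blocks.append((seg, features))
    return doc


# ---------------------------------------------------------------------------
# sequence / DASSEQUENCE


def serialize_sequence(doc: SequenceDocument) -> XmlPayload:
    root = ET.Element("DASSEQUENCE")
    for rec in doc.records:
        el = ET.SubElement(
            root,
            "SEQUENCE",
            id=rec.segment_id,
            start=str(rec.start),
            stop=str(rec.stop),
            version=rec.version,
        )
        el.text = rec.residues
    return _to_payload(root)


def parse_sequence(xml: bytes) -> SequenceDocument:
    root = _root(xml, "DASSEQUENCE")
    records = []
    for el in root.findall("SEQUENCE"):
        # residues never contain whitespace; tolerate reformatting
        residues = "".join((el.text or "").split())
        records.append(
            SequenceRecord(
                segment_id=_req(el, "id"),
                start=int(_req(el, "start")),
                stop=int(_req(el, "stop")),
                version=_req(el, "version"),
                residues=residues,
            )
        )
    return SequenceDocument(records=records)


# ---------------------------------------------------------------------------
# types / DASTYPES


def serialize_types(doc: TypesDocument) -> XmlPayload:
    root = ET.Element("DASTYPES")
    gff = ET.SubElement(root, "GFF", href=doc.href)
    for block, counts in doc.blocks:
        if isinstance(block, UnknownSegmentMarker):
            _unknown_el(gff, block)
            continue
        if block is None:
            seg_el = ET.SubElement(gff, "SEGMENT")  # source-wide block
        else:
            seg_el = _segment_el(gff, block)
        for tc in counts:
            te = ET.SubElement(seg_el, "TYPE", id=tc.type.id)
            if tc.type.cv_id is not None:
                te.set("cvId", tc.type.cv_id)
            te.set("category", tc.type.category)
            if tc.type.description is not None:
                te.set("description", tc.type.description)
            if tc.count is not None:
                te.text = str(tc.count)
    return _to_payload(root)


def parse_types(xml: bytes) -> TypesDocument:
    root = _root(xml, "DASTYPES")
    gff = root.find("GFF")
    if gff is None:
        raise ValueError("DASTYPES: missing GFF element")
    doc = TypesDocument(blocks=[], href=_req(gff, "href"))
    for el in gff:
        if el.tag == "UNKNOWNSEGMENT":
            doc.blocks.append((_parse_unknown(el), []))
            continue
        if el.tag != "SEGMENT":
            continue
        block = _parse_segment_attrs(el) if el.get("id") is not None else None
        counts = []
        for te in el.findall("TYPE"):
            text = (te.text or "").strip()
            counts.append(
                TypeCount(
                    type=DasType(
                        id=_req(te, "id"),
                        category=_req(te, "category"),
                        cv_id=te.get("cvId"),
                        description=te.get("description"),
                    ),
                    count=int(text) if text else None,
                )
            )
        doc.blocks.append((block, counts))
    return doc


# ---------------------------------------------------------------------------
# entry points / DASEP


def serialize_entry_points(doc: EntryPointsDocument) -> XmlPayload:
    root = ET.Element("DASEP")
    ep = ET.SubElement(
        root,
        "ENTRY_POINTS",
        href=doc.href,
        total=str(doc.total),
        start=str(doc.first),
        end=str(doc.last),
    )
    if doc.version:
        ep.set("version", doc.version)
    for e in doc.entry_points:
        el = ET.SubElement(
            ep,
            "SEGMENT",
            id=e.id,
            start=str(e.start),
            stop=str(e.stop),
            orientation=e.orientation,
            subparts="yes" if e.has_subparts else "no",
        )
        if e.type_label is not None:
            el.set("type", e.type_label)
        if e.description is not None:
            el.text = e.description
    return _to_payload(root)


def parse_entry_points(xml: bytes) -> EntryPointsDocument:
    root = _root(xml, "DASEP")
    ep = root.find("ENTRY_POINTS")
    if ep is None:
        raise ValueError("DASEP: missing ENTRY_POINTS element")
    entry_points = []
    for el in ep.findall("SEGMENT"):
        text = el.text
        entry_points.append(
            EntryPoint(
                id=_req(el, "id"),
                start=int(_req(el, "start")),
                stop=int(_req(el, "stop")),
                orientation=_req(el, "orientation"),
                type_label=el.get("type"),
                description=text if text and text.strip() else None,
                has_subparts=_req(el, "subparts") == "yes",
            )
        )
    return EntryPointsDocument(
        total=int(_req(ep, "total")),
        first=int(_req(ep, "start")),
        last=int(_req(ep, "end")),
        entry_points=entry_points,
        href=_req(ep, "href"),
        version=ep.get("version", ""),
    )


# ---------------------------------------------------------------------------
# sources / SOURCES


def serialize_sources(doc: SourcesDocument) -> XmlPayload:
    root = ET.Element("SOURCES")
    for s in doc.sources:
        se = ET.SubElement(root, "SOURCE", uri=s.uri, title=s.title, description=s.description)
        ET.SubElement(se, "MAINTAINER", email=s.maintainer_email)
        ve = ET.SubElement(se, "VERSION", uri=s.uri, version=s.version)
        ce = ET.SubElement(
            ve,
            "COORDINATES",
            authority=s.coordinate_authority,
            source=s.coordinate_source_type,
        )
        if s.organism_taxid is not None:
            ce.set("taxid", str(s.organism_taxid))
        for cap, query_uri in s.capabilities:
            ET.SubElement(ve, "CAPABILITY", type=f"das1:{cap}", query_uri=query_uri)
        for name, value in s.properties:
            ET.SubElement(ve, "PROP", name=name, value=value)
    return _to_payload(root)


def parse_sources(xml: bytes) -> SourcesDocument:
    root = _root(xml, "SOURCES")
    sources = []
    for se in root.findall("SOURCE"):
        maint = se.find("MAINTAINER")
        ve = se.find("VERSION")
        if maint is None or ve is None:
            raise ValueError("SOURCE: missing MAINTAINER or VERSION element")
        ce = ve.find("COORDINATES")
        if ce is None:
            raise ValueError("VERSION: missing COORDINATES element")
        taxid = ce.get("taxid")
        sources.append(
            SourceEntry(
                uri=_req(se, "uri"),
                title=_req(se, "title"),
                description=_req(se, "description"),
                maintainer_email=_req(maint, "email"),
                version=_req(ve, "version"),
                coordinate_authority=_req(ce, "authority"),
                coordinate_source_type=_req(ce, "source"),
                organism_taxid=int(taxid) if taxid is not None else None,
                capabilities=[
                    (_req(c, "type").removeprefix("das1:"), _req(c, "query_uri"))
                    for c in ve.findall("CAPABILITY")
                ],
                properties=[
                    (_req(p, "name"), _req(p, "value")) for p in ve.findall("PROP")
                ],
            )
        )
    return SourcesDocument(sources=sources)


# ---------------------------------------------------------------------------
# stylesheet / DASSTYLE


def serialize_stylesheet(doc: StylesheetDocument) -> XmlPayload:
    root = ET.Element("DASSTYLE")
    sheet = ET.SubElement(root, "STYLESHEET", version="1.0")
    for category_id, types in doc.stylesheet.categories:
        cat_el = ET.SubElement(sheet, "CATEGORY", id=category_id)
        for type_id, glyph in types:
            type_el = ET.SubElement(cat_el, "TYPE", id=type_id)
            glyph_el = ET.SubElement(type_el, "GLYPH")
            shape_el = ET.SubElement(glyph_el, glyph.name)
            for key, value in glyph.attributes:
                ET.SubElement(shape_el, key).text = value
    return _to_payload(root)


def parse_stylesheet(xml: bytes) -> StylesheetDocument:
    root = _root(xml, "DASSTYLE")
    sheet = root.find("STYLESHEET")
    if sheet is None:
        raise ValueError("DASSTYLE: missing STYLESHEET element")
    categories = []
    for cat_el in sheet.findall("CATEGORY"):
        types = []
        for type_el in cat_el.findall("TYPE"):
            glyph_el = type_el.find("GLYPH")
            if glyph_el is None or len(glyph_el) == 0:
                raise ValueError("TYPE: missing GLYPH shape element")
            shape = glyph_el[0]
            glyph = Glyph(
                name=shape.tag,
                attributes=tuple(
                    (child.tag, (child.text or "").strip()) for child in shape
                ),
            )
            types.append((_req(type_el, "id"), glyph))
        categories.append((_req(cat_el, "id"), tuple(types)))
    return StylesheetDocument(stylesheet=Stylesheet(categories=tuple(categories)))


# ---------------------------------------------------------------------------


def xsl_decorate(payload: XmlPayload, stylesheet_href: Optional[str]) -> XmlPayload:
    """Prepend an ``xml-stylesheet`` processing instruction.

    With no href the payload is returned unchanged; otherwise exactly one
    PI is inserted between the XML declaration and the root element, the
    body otherwise byte-identical.
    """
    if stylesheet_href is None:
        return payload
    pi = f"<?xml-stylesheet type=\"text/xsl\" href=\"{stylesheet_href}\"?>".encode()
    body = payload.bytes
    end = body.find(b"?>")
    if body.startswith(b"<?xml") and end != -1:
        insert_at = end + 2
        if body[insert_at : insert_at + 1] == b"\n":
            insert_at += 1
        decorated = body[:insert_at] + pi + body[insert_at:]
    else:
        decorated = pi + body
    return XmlPayload(bytes=decorated, content_type=payload.content_type)


SERIALIZERS = {
    FeaturesDocument: serialize_features,
    SequenceDocument: serialize_sequence,
    TypesDocument: serialize_types,
    EntryPointsDocument: serialize_entry_points,
    SourcesDocument: serialize_sources,
    StylesheetDocument: serialize_stylesheet,
}


def serialize_document(doc) -> XmlPayload:
    """Serialize any of the six typed documents by dispatch on its type."""
    try:
        return SERIALIZERS[type(doc)](doc)
    except KeyError:
        raise TypeError(f"no serializer for {type(doc).__name__}") from None
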