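# DAS wire-format reference

This document fixes the exact XML element grammar `dasserve` emits and
accepts, and the GFF dialect its built-in adapter reads. Responses carry
`Content-Type: text/xml`, are encoded UTF-8, and omit DOCTYPE
declarations; validation is structural against this grammar.

All coordinates on the wire are 1-based and fully inclusive.

## Common conventions

- Element and attribute names follow the classical DAS casing
  (UPPERCASE elements).
- Optional attributes are simply absent; optional text content is an
  empty element.
- An absent feature score is the literal text `-` (distinct from `0.0`).
- Orientation is one of `+`, `-`, `0` (`0` = not applicable/unknown);
  phase is one of `0`, `1`, `2`, `-`.

## features — root `DASGFF`

```xml
<DASGFF>
  <GFF href="http://host/das/SRC/features">
    <SEGMENT id="seg000" start="1" stop="100000" version="1.0">
      <FEATURE id="f0_1" label="...">
        <TYPE id="exon" category="transcription" cvId="SO:0000147">description</TYPE>
        <METHOD id="curation" cvId="ECO:...">label</METHOD>
        <START>1400</START>
        <END>1600</END>
        <SCORE>86.2</SCORE>        <!-- or "-" when absent -->
        <ORIENTATION>+</ORIENTATION>
        <PHASE>-</PHASE>
        <NOTE>free text</NOTE>                       <!-- 0..n -->
        <LINK href="http://...">label</LINK>         <!-- 0..n -->
        <TARGET id="..." start="1" stop="9"/>        <!-- 0..n -->
        <PARENT id="..."/>                           <!-- 0..n -->
        <PART id="..."/>                             <!-- 0..n -->
      </FEATURE>
    </SEGMENT>
    <UNKNOWNSEGMENT id="chrZZ" start="1" stop="50"/>
  </GFF>
</DASGFF>
```

A non-positional (whole-sequence) feature serializes with
`<START>0</START><END>0</END>`. A segment query whose id the annotation
source does not cover produces an `UNKNOWNSEGMENT` element in the
document, not an HTTP error.

## sequence — root `DASSEQUENCE`

```xml
<DASSEQUENCE>
  <SEQUENCE id="seg001" start="5" stop="10" version="1.0">KVLAHT</SEQUENCE>
</DASSEQUENCE>
```

Residues contain no whitespace; parsers discard any whitespace inside
the `SEQUENCE` text (tolerates re-indented documents).

## types — root `DASTYPES`

```xml
<DASTYPES>
  <GFF href="http://host/das/SRC/types">
    <SEGMENT id="seg000" start="1" stop="100000">   <!-- attrs absent for the
                                                         source-wide block -->
      <TYPE id="exon" category="transcription">35</TYPE>  <!-- text = count,
                                                               absent when unknown -->
    </SEGMENT>
  </GFF>
</DASTYPES>
```

## entry_points — root `DASEP`

```xml
<DASEP>
  <ENTRY_POINTS href="..." total="10" start="1" end="3" version="1.0">
    <SEGMENT id="seg000" start="1" stop="100000" orientation="0"
             subparts="no" type="chromosome">description</SEGMENT>
  </ENTRY_POINTS>
</DASEP>
```

`total` is the full listing size; `start`/`end` are the effective 1-based
inclusive window after clipping (`end < start` for an empty page).

## sources — root `SOURCES`

```xml
<SOURCES>
  <SOURCE uri="http://host/das/demo" title="..." description="...">
    <MAINTAINER email="..."/>
    <VERSION uri="http://host/das/demo" version="1.0">
      <COORDINATES authority="UniProt" source="Protein Sequence" taxid="9606"/>
      <CAPABILITY type="das1:features" query_uri="http://host/das/demo/features"/>
      <PROP name="..." value="..."/>
    </VERSION>
  </SOURCE>
</SOURCES>
```

## stylesheet — root `DASSTYLE`

```xml
<DASSTYLE>
  <STYLESHEET version="1.0">
    <CATEGORY id="transcription">
      <TYPE id="exon">             <!-- wildcard id "default" permitted -->
        <GLYPH>
          <box>                    <!-- glyph name -->
            <FGCOLOR>blue</FGCOLOR>
            <HEIGHT>10</HEIGHT>
          </box>
        </GLYPH>
      </TYPE>
    </CATEGORY>
  </STYLESHEET>
</DASSTYLE>
```

## Error documents

Error responses carry a minimal body and express the taxonomy entry in
the `X-DAS-Status` header (see README for the HTTP status mapping):

```xml
<ERROR status="BAD_DATA_SOURCE"/>
```

## XSL decoration

When enabled in the configuration, exactly one processing instruction is
inserted between the XML declaration and the root element:

```xml
<?xml-stylesheet type="text/xsl" href="..."?>
```

## GFF dialect read by the `gff` adapter

GFF3 column semantics: 9 tab-separated columns, `#` comments,
`##sequence-region SEQID START END` directives setting segment bounds.
Column mapping: seqid → segment id, source → method id, type → type id,
start/stop → positions, score (`.` → absent), strand (`.` → `0`), phase
(`.` → `-`). Recognized attributes: `ID` (feature id, autogenerated as
`line<N>` when absent), `Note`, `Parent`, `category` (the type's DAS
category — DAS needs a category and standard GFF3 has no column for it).

**Dialect extension:** a feature line with `start` and `stop` both `0`
encodes a whole-sequence (non-positional) feature, which standard GFF3
(1-based coordinates) cannot represent. Any other use of coordinate 0 is
a parse error. GFF2 group-column parsing is out of scope.
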