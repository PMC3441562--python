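# dasserve

An extensible server framework for publishing biological sequence
annotations over the Distributed Annotation System (DAS) 1.6 protocol.

DAS is a federated integration protocol: many independent HTTP servers
publish annotations against shared reference coordinates (a UniProt
accession, a chromosome), and clients such as genome browsers aggregate
them into one view. Every DAS server re-implements the same common
machinery — argument capture, segment/range query semantics, XML
creation, exception handling, HTTP. `dasserve` carries that machinery so
that a laboratory or database group publishing their data only writes a
small *adapter* mapping their backing store onto the DAS object model;
the framework answers the protocol's commands:

| command        | returns                                               |
|----------------|-------------------------------------------------------|
| `sources`      | the data sources available on the server              |
| `entry_points` | the accessions a source describes, with extents       |
| `sequence`     | residues for a segment (reference sources)            |
| `types`        | the annotation types available, with counts           |
| `features`     | the annotations overlapping a segment or range        |
| `stylesheet`   | rendering hints for the annotation types              |

Coordinates are 1-based and fully inclusive throughout (the DAS
convention): a feature `[s, e]` is returned for a query window `[a, b]`
iff `s ≤ b` and `e ≥ a`. Whole-sequence annotations (encoded
`start = stop = 0`) match every window. One server instance runs any
number of sources, each bound by the configuration file to a registered
adapter. Two adapters ship built in: `gff` (annotation source backed by
a GFF3 file, indexed with per-segment interval trees) and `reference`
(sequences from a plain-text TSV). Custom adapters subclass
`AnnotationSource` or `ReferenceSource` and register under a name.

See `docs/methods.md` for the semantics in detail, `docs/wire-format.md`
for the exact XML grammar and GFF dialect, and `docs/config-format.md`
for the configuration schema.

## Worked example

Generate a small synthetic annotation set and serve it:

```python
from dasserve.fixtures import FixtureSpec, generate_gff

spec = FixtureSpec(seed=11, n_segments=2, segment_length=5000,
                   n_features=60, feature_length_range=(20, 300))
open("demo.gff", "w").write(generate_gff(spec)[0])
```

with `config.yaml`:

```yaml
server:
  base_url: http://localhost:8080/das
sources:
  - id: demo
    title: Demo annotations
    adapter: gff
    capabilities: [features, types, entry_points]
    properties:
      file: demo.gff
```

Check the deployment, then query offline (no socket involved):

```console
$ dasserve validate --config config.yaml
configuration OK: 1 source(s)
$ dasserve query --config config.yaml "/das/demo/types"
<?xml version='1.0' encoding='UTF-8'?>
<DASTYPES><GFF href="http://localhost:8080/das/demo/types"><SEGMENT>
  <TYPE id="CDS" category="translation">14</TYPE>
  <TYPE id="binding_site" category="miscellaneous">10</TYPE>
  <TYPE id="exon" category="transcription">12</TYPE>
  <TYPE id="intron" category="transcription">11</TYPE>
  <TYPE id="repeat_region" category="structural">13</TYPE>
</SEGMENT></GFF></DASTYPES>
```

(output re-wrapped for readability): of the 60 generated features, 14
are CDS, 12 exons, and so on — the counts a client uses to decide which
tracks to draw. `dasserve serve --config config.yaml --port 8080` serves
the same answers over HTTP, byte-identical to `query`.

The bundled stress harness repeats one query under concurrency and
reports (never asserts) throughput:

```console
$ dasserve bench --config config.yaml --requests 50 --concurrency 5 \
    --url "/das/demo/features?segment=seg000:1,2000"
Requests:            50 (5 concurrent)
Successes:           50
Failures:            0
Bodies identical:    yes
Response size:       2137 bytes
Elapsed:             0.409 s
Requests per second: 122.18
Time per request:    40.466 ms
Transfer rate:       254.99 Kbytes/sec
```

`Bodies identical: yes` is the contract being checked — concurrent
identical requests must produce byte-identical documents; the rate
figures depend on the machine.

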