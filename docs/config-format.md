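# Configuration file format

One YAML document (UTF-8) describes the whole server: general options
under `server:` and an ordered list of data sources under `sources:`.

```yaml
server:
  base_url: http://localhost:8080/das   # absolute URL of the /das mount
  gzip: true                            # default false
  xslt: false                           # default false
  xslt_href: /static/das.xsl            # PI href when xslt is on
  stylesheet: /etc/dasserve/default-style.xml   # server default stylesheet
  entry_points_page_size: 1000          # default 1000, must be >= 1

sources:
  - id: demo                  # required; [A-Za-z0-9._-]+, unique
    title: Demo annotations   # required
    adapter: gff              # required; a registered adapter name
    description: Synthetic demonstration annotations
    maintainer: curator@example.org
    version: "1.0"
    coordinates:
      authority: GRCh38
      source_type: Chromosome
      taxid: 9606
    capabilities: [features, types, entry_points, stylesheet]
    properties:               # passed verbatim to the adapter
      file: /data/demo.gff
```

Rules:

- `id`, `title` and `adapter` are required per source; everything else
  has documented defaults (gzip off, page size 1000, no default
  stylesheet).
- Source ids must be pairwise distinct; a duplicate is a parse error
  naming the id.
- `capabilities` must be a subset of
  `{sources, entry_points, sequence, types, features, stylesheet}` and of
  what the named adapter can serve (checked by `dasserve validate` and at
  server startup).
- Adapter binding is by registered name (`gff`, `reference`, or any name
  registered via `dasserve.sources.register_adapter`), not by filesystem
  path — the portable contract.
- Unknown keys are ignored (forward compatibility).

Built-in adapter properties:

| adapter     | property  | meaning                                            |
|-------------|-----------|----------------------------------------------------|
| `gff`       | `file`    | required; path to the GFF3 file (see wire-format)  |
| `gff`       | `version` | segment version string (default `1.0`)             |
| `reference` | `file`    | required; TSV with `segment_id<TAB>residues` lines |
| `reference` | `version` | sequence version string (default `1.0`)            |
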