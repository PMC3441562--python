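# Methods

## What the package does

`dasserve` is a server framework for the Distributed Annotation System
(DAS) version 1.6, the federated protocol by which bioinformatics
clients aggregate annotations on genomic and protein sequences from many
independent HTTP servers sharing a coordinate system. The framework
carries all the protocol-generic work — request parsing and argument
capture, segment/range query semantics, XML document generation,
configuration, exception handling and HTTP — so that a data provider
only writes a small adapter mapping their backing store onto the DAS
object model.

The architecture is layered the way classical servlet-style annotation
servers are: an HTTP frontend receives requests and hands commands to a
controller (`dasserve.commands`), which learns which sources exist from
the configuration manager (`dasserve.config`), dispatches to adapters
behind a narrow interface (`dasserve.sources`), and assembles typed
documents that the wire layer (`dasserve.xml_io`) serializes. The object
model (`dasserve.model`) is the shared vocabulary of all layers.

## Coordinate and overlap semantics

All coordinates are 1-based and fully inclusive (the DAS convention);
the only conversion to half-open 0-based indexing is confined to Python
string slicing inside sequence retrieval. A feature interval `[s, e]`
overlaps a query window `[a, b]` iff `s <= b and e >= a`; adjacent
inclusive intervals (`[10,20]` vs `[21,30]`) do not overlap.

Non-positional features — annotations that apply to the whole sequence,
such as a related publication — are encoded as `start = stop = 0`. They
are returned for both whole-segment and ranged queries: a
whole-sequence annotation is relevant to any window, and ranged clients
can discard it. Validation rejects mixed coordinates (exactly one of
start/stop zero) and inverted ranges rather than clamping; clamping
would silently alter the provider's data.

Unknown segments are handled asymmetrically, per DAS practice: an
annotation source answers "no such segment here" as data (an
`UNKNOWNSEGMENT` element inside a 200 response), while a reference
source treats an unknown or out-of-bounds accession as an error
(`BAD_REFERENCE_OBJECT`, HTTP 404). This lets clients distinguish
"this source doesn't cover the accession" from "the accession is
invalid". Out-of-bounds sequence ranges always error; silent truncation
would corrupt client-side coordinate arithmetic.

## Query engine

The GFF-backed store keeps one interval tree per segment (the
`intervaltree` package; DAS inclusive intervals are stored half-open as
`[start, stop+1)`), plus a feature-id hash index and a type multiset.
The behavioural contract is set-equality with a linear scan applying the
model's overlap predicate, which the tests assert on stores of 10,000
features; the tree only buys the `O(log n + k)` lookup. Results are
ordered deterministically by `(start, feature_id)` so that repeated
executions of a command are byte-identical on the wire. Duplicate
feature ids in input GFF keep the last occurrence in the id index while
all occurrences remain queryable by position (a warning is logged).

Filters compose as intersections: a features request with both `type`
and `category` filters returns exactly the intersection of the two
singly-filtered results, and an empty filter list is the identity.
`rows` pagination applies to `entry_points` only (per DAS 1.6); the
window is clipped to `[1, total]`, a window past the end is an empty
page rather than an error, and the reported total is stable across
pages. The `maxbins` argument is accepted and ignored — the built-in
adapters do not density-bin features — and this is the documented
behaviour rather than an error so that binning-aware clients still work.

## Wire format and numerics

The six response kinds (DASGFF features, DASSEQUENCE, DASTYPES, DASEP
entry points, SOURCES, DASSTYLE stylesheet) are serialized with the
stdlib ElementTree against the element grammar fixed in
`docs/wire-format.md`. DOCTYPE declarations are omitted and validation
is structural, keeping the test suite hermetic. Every serializer has an
inverse parser and the pair satisfies `parse(serialize(d)) == d`
(structural equality) with byte-deterministic serialization; parsers
tolerate attribute reordering and re-indentation between elements.
Positions serialize as decimal integers; scores use Python's shortest
round-trip float representation, and an absent score is the literal
`-`, kept distinct from `0.0` throughout. Text and attribute values are
XML-escaped, so notes and labels containing `<&>` survive round-trip.

## Configuration and error transport

The configuration dialect is a single YAML document (schema in
`docs/config-format.md`) with the same information content as classical
DAS server configs: per-source metadata (title, organism, version,
coordinate system), an adapter binding, and server options (gzip, XSL
decoration, entry-point page size, default stylesheet). Adapters are
bound by registered name rather than filesystem class path — the
portable contract for a Python registry. Unknown keys are ignored for
forward compatibility; structural problems (duplicate ids, capabilities
an adapter cannot serve) are reported with names, and adapter
initialization happens eagerly at startup so a broken source refuses to
start instead of failing at first request.

Errors travel as real HTTP statuses (400 for malformed commands and
arguments, 404 for unknown sources/reference objects/stylesheets, 500
for internal failures) with a redundant `X-DAS-Status` header naming
the taxonomy entry (`BAD_COMMAND`, `BAD_DATA_SOURCE`,
`BAD_COMMAND_ARGS`, `BAD_REFERENCE_OBJECT`, `BAD_STYLESHEET`,
`SERVER_ERROR`) for clients that predate strict status handling. All
responses, including errors, carry `X-DAS-Version: DAS/1.6`,
`X-DAS-Server` and `X-DAS-Capabilities`. Adapter exceptions become 500
responses with the stack trace confined to the server log. gzip is
applied only when enabled in the configuration *and* the client sent
`Accept-Encoding: gzip`; compressed bodies are produced with a zeroed
mtime so identical documents stay byte-identical on the wire.

## Synthetic data and what it shows

The fixture generator emits GFF3 with controllable segment count,
segment length, feature count, feature-length distribution,
type/category vocabulary, and a fraction of whole-sequence features,
together with exact bookkeeping (per-type counts, per-segment sorted
feature lists) that serves as ground truth for parser and query
oracles. Defaults: 5 segments of 100 kb, 1,000 features of 50–2,000 bp
drawn from a five-type vocabulary, 2% non-positional — densities a
small annotation track would plausibly have, chosen so whole-segment
responses stay in the hundreds-of-kilobytes range. The PRNG is Python's
Mersenne Twister (`random.Random`), so a seed fixes the bytes across
platforms. Reference sequences are uniform draws from the 20-letter
amino-acid alphabet.

The generator emulates the *shape* of annotation data, not its
statistics: no clustering of features along the sequence, no realistic
type frequencies, no parent/part hierarchies in generated GFF.
Passing tests therefore demonstrate protocol and query correctness and
serving robustness, not biological plausibility of served content.

`size_targeted_fixture` searches the feature count whose whole-file
features response serializes closest to a byte target (doubling then
bisection on the monotone size–count relation), and errors — reporting
the best achieved size — when the target is below the minimal document.
It reproduces the benchmark document classes used throughout: small
(~1,500 B) and medium (~200,000 B) responses.

## The stress harness

`dasserve bench` re-enacts the classical server benchmark shape: the
same query repeated N times over C concurrent persistent connections
(defaults 1000 and 10) against an in-process server on an ephemeral
port. It verifies that every response succeeds and that all bodies are
byte-identical (read-path thread safety), and *reports* throughput,
mean latency and transfer rate without asserting them — absolute
figures are hardware-dependent and deliberately not part of any
contract. The default test run exercises the small and medium document
sizes; larger documents scale linearly and can be run manually via
`size_targeted_fixture`.

## Design choices that were genuinely open

- **GFF dialect**: GFF3 column semantics (current standard,
  self-describing); GFF2 group-column parsing is out of scope. A DAS
  category has no GFF3 column, so the adapter reads an optional
  `category` attribute; and since GFF3 cannot represent whole-sequence
  features, the `0 0` coordinate pair is a documented dialect extension
  for them.
- **Out-of-range feature coordinates** are rejected at validation, not
  clamped.
- **In-memory loading**: the GFF adapter loads the whole file; at the
  document sizes this framework targets (single-digit MB), an on-disk
  index would add complexity without benefit. A provider with larger
  data writes an adapter over an indexed store — that is what the SPI
  is for.
- **`get_features_by_id`** returns `(segment, feature)` pairs because a
  feature deliberately carries no back-pointer to its segment, and the
  response document needs the owning segment for the enclosing block.
- **Stylesheet precedence**: adapter-provided stylesheet wins over the
  server default; if neither exists the command errors
  (`BAD_STYLESHEET`) rather than inventing glyphs.

## Problem sizes used by the automated checks

Wire round-trips run 200 random documents per kind; the query-engine
comparison uses 10,000 features over 5 segments with 200 random ranged
queries; the sequence contract draws 1,000 random sub-ranges; the
protocol table has 31 request URLs; the stress harness runs 1,000
requests at concurrency 10 for each document size. These sizes keep a
full verification run in tens of seconds on one CPU while staying at
the scale the protocol semantics are exercised in practice.

## Known limitations

- No structure or alignment capabilities, no DAS 2.0 or JSON formats,
  no registry auto-registration, no TLS/authentication/caching — out of
  scope by design.
- The configuration schema is this package's own; it is not
  file-compatible with any Java DAS server's XML configuration.
- No hot-reload: configuration changes need a restart.
- `maxbins` is ignored (no feature binning), which can over-deliver
  features to zoomed-out genome-browser clients.
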