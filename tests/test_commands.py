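"""Command parsing, dispatch, filtering and document assembly."""

import random

import pytest

from dasserve.commands import (
    DasCommand,
    UnknownSegmentMarker,
    execute,
    execute_entry_points,
    execute_features,
    execute_stylesheet,
    execute_types,
    parse_request,
    render_request,
)
from dasserve.errors import (
    BadCommand,
    BadCommandArgs,
    BadDataSource,
    BadReferenceObject,
    BadStylesheet,
)
from dasserve.fixtures import default_stylesheet
from dasserve.model import SegmentQuery
from dasserve.xml_io import serialize_document


class TestParseRequest:
    def test_features_with_range_and_type_filter(self):
        cmd = parse_request("/das/demo/features", "segment=chr1:100,200;type=exon")
        assert cmd.command == "features" and cmd.source_id == "demo"
        assert cmd.segments == [SegmentQuery(id="chr1", start=100, stop=200)]
        assert cmd.type_filters == ["exon"]

    def test_repeated_segments_accumulate_in_order(self):
        cmd = parse_request(
            "/das/demo/features", "segment=a;segment=b:1,5&segment=c"
        )
        assert [q.id for q in cmd.segments] == ["a", "b", "c"]

    def test_sources_paths(self):
        assert parse_request("/das/sources").command == "sources"
        cmd = parse_request("/das/sources/demo")
        assert cmd.command == "sources" and cmd.source_id == "demo"

    def test_rows_window(self):
        assert parse_request("/das/d/entry_points", "rows=2-9").rows == (2, 9)

    @pytest.mark.parametrize(
        "query", ["segment=chr1:200,100", "segment=chr1:x,y", "segment=chr1:0,5", "rows=9-2"]
    )
    def test_malformed_arguments(self, query):
        with pytest.raises(BadCommandArgs):
            parse_request("/das/demo/features", query)

    @pytest.mark.parametrize(
        "path", ["/das/demo/nosuchcommand", "/notdas/demo/features", "/das/a/b/c"]
    )
    def test_bad_paths(self, path):
        with pytest.raises(BadCommand):
            parse_request(path)

    def test_maxbins_accepted_and_ignored(self):
        cmd = parse_request("/das/demo/features", "segment=chr1;maxbins=500")
        assert [q.id for q in cmd.segments] == ["chr1"]

    def test_url_round_trip_identity(self):
        rng = random.Random(31)
        for _ in range(500):
            cmd = _random_command(rng)
            rendered = render_request(cmd)
            path, _, query = rendered.partition("?")
            assert parse_request(path, query) == cmd
            assert render_request(parse_request(path, query)) == rendered


def _random_command(rng: random.Random) -> DasCommand:
    command = rng.choice(
        ["sources", "entry_points", "sequence", "types", "features", "stylesheet"]
    )
    if command == "sources":
        return DasCommand(command="sources", source_id=rng.choice([None, "demo"]))
    cmd = DasCommand(command=command, source_id=rng.choice(["demo", "ref", "src.1"]))
    for _ in range(rng.randrange(3)):
        if rng.random() < 0.5:
            a = rng.randint(1, 1000)
            cmd.segments.append(SegmentQuery(id=f"seg{rng.randrange(10)}", start=a, stop=a + rng.randrange(500)))
        else:
            cmd.segments.append(SegmentQuery(id=f"seg{rng.randrange(10)}"))
    if command == "features":
        cmd.type_filters = [f"t{i}" for i in range(rng.randrange(3))]
        cmd.category_filters = [f"c{i}" for i in range(rng.randrange(2))]
        cmd.feature_ids = [f"f{i}" for i in range(rng.randrange(2))]
    if command == "entry_points" and rng.random() < 0.5:
        first = rng.randint(1, 50)
        cmd.rows = (first, first + rng.randrange(50))
    return cmd


class TestExecute:
    def test_sources_lists_in_config_order(self, demo_config, demo_app):
        doc = execute(DasCommand(command="sources"), demo_config, demo_app.adapters)
        assert [s.uri.rsplit("/", 1)[1] for s in doc.sources] == ["demo", "ref"]
        for entry in doc.sources:
            for cap, uri in entry.capabilities:
                assert uri == f"{entry.uri}/{cap}"
                assert uri.startswith(demo_config.base_url)

    def test_single_source_document(self, demo_config, demo_app):
        doc = execute(
            DasCommand(command="sources", source_id="ref"), demo_config, demo_app.adapters
        )
        assert len(doc.sources) == 1 and doc.sources[0].title == "Demo reference"

    def test_unknown_source(self, demo_config, demo_app):
        with pytest.raises(BadDataSource):
            execute(
                DasCommand(command="features", source_id="nosuch"),
                demo_config,
                demo_app.adapters,
            )

    def test_command_without_capability(self, demo_config, demo_app):
        with pytest.raises(BadCommand):
            execute(
                DasCommand(command="sequence", source_id="demo",
                           segments=[SegmentQuery(id="seg000")]),
                demo_config,
                demo_app.adapters,
            )

    def test_execution_is_deterministic(self, demo_config, demo_app):
        cmd = parse_request("/das/demo/features", "segment=seg000:1,5000")
        first = serialize_document(execute(cmd, demo_config, demo_app.adapters))
        second = serialize_document(execute(cmd, demo_config, demo_app.adapters))
        assert first.bytes == second.bytes


class TestExecuteFeatures:
    def test_empty_filters_are_identity(self, demo_app):
        handle = demo_app.adapters["demo"]
        q = SegmentQuery(id="seg000")
        doc = execute_features(handle, [q], [], [], [])
        assert doc.blocks[0][1] == handle.get_features_by_segment(q)

    def test_blocks_preserve_request_order(self, demo_app):
        handle = demo_app.adapters["demo"]
        queries = [SegmentQuery(id="seg002"), SegmentQuery(id="nope"), SegmentQuery(id="seg000")]
        doc = execute_features(handle, queries, [], [], [])
        assert [b[0].id for b in doc.blocks] == ["seg002", "nope", "seg000"]
        assert isinstance(doc.blocks[1][0], UnknownSegmentMarker)

    def test_composed_filters_equal_intersection(self, demo_app):
        handle = demo_app.adapters["demo"]
        q = [SegmentQuery(id="seg001")]
        both = execute_features(handle, q, ["exon"], ["transcription"], [])
        only_type = execute_features(handle, q, ["exon"], [], [])
        only_cat = execute_features(handle, q, [], ["transcription"], [])
        ids = lambda d: {f.feature_id for f in d.blocks[0][1]}
        assert ids(both) == ids(only_type) & ids(only_cat)

    def test_random_filters_match_brute_force(self, demo_app):
        handle = demo_app.adapters["demo"]
        rng = random.Random(8)
        for _ in range(30):
            sid = f"seg{rng.randrange(3):03d}"
            a = rng.randint(1, 9000)
            q = SegmentQuery(id=sid, start=a, stop=a + rng.randrange(2000))
            tf = rng.sample(["exon", "intron", "CDS", "repeat_region"], rng.randrange(3))
            cf = rng.sample(["transcription", "translation"], rng.randrange(2))
            doc = execute_features(handle, [q], tf, cf, [])
            expected = [
                f
                for f in handle.get_features_by_segment(q)
                if (not tf or f.type.id in tf) and (not cf or f.type.category in cf)
            ]
            assert doc.blocks[0][1] == expected

    def test_feature_id_query_wraps_in_own_block(self, demo_app, demo_store):
        fid = sorted(demo_store.feature_index)[0]
        sid = demo_store.feature_index[fid][0]
        doc = execute_features(demo_app.adapters["demo"], [], [], [], [fid])
        (block, feats), = doc.blocks
        assert block.id == sid and [f.feature_id for f in feats] == [fid]

    def test_unknown_feature_id_becomes_unknown_block(self, demo_app):
        doc = execute_features(demo_app.adapters["demo"], [], [], [], ["nope"])
        assert isinstance(doc.blocks[0][0], UnknownSegmentMarker)

    def test_no_queries_at_all_is_an_argument_error(self, demo_app):
        with pytest.raises(BadCommandArgs):
            execute_features(demo_app.adapters["demo"], [], [], [], [])


class TestExecuteTypes:
    def test_source_wide_counts_match_bookkeeping(self, demo_app, demo_gff):
        _, book = demo_gff
        doc = execute_types(demo_app.adapters["demo"], [])
        (block, counts), = doc.blocks
        assert block is None
        assert {tc.type.id: tc.count for tc in counts} == book.type_counts

    def test_counts_over_all_segments_sum_to_source_wide(self, demo_app):
        handle = demo_app.adapters["demo"]
        queries = [SegmentQuery(id=f"seg{i:03d}") for i in range(3)]
        doc = execute_types(handle, queries)
        summed: dict[str, int] = {}
        for _, counts in doc.blocks:
            for tc in counts:
                summed[tc.type.id] = summed.get(tc.type.id, 0) + tc.count
        assert summed == {tc.type.id: tc.count for tc in execute_types(handle, []).blocks[0][1]}

    def test_per_segment_counts_match_brute_force_tally(self, demo_app):
        handle = demo_app.adapters["demo"]
        q = SegmentQuery(id="seg001", start=1000, stop=4000)
        doc = execute_types(handle, [q])
        tally: dict[str, int] = {}
        for f in handle.get_features_by_segment(q):
            tally[f.type.id] = tally.get(f.type.id, 0) + 1
        assert {tc.type.id: tc.count for tc in doc.blocks[0][1]} == tally


class TestExecuteEntryPoints:
    def test_window_and_total(self, demo_app):
        doc = execute_entry_points(demo_app.adapters["demo"], (1, 2), 1000)
        assert doc.total == 3 and (doc.first, doc.last) == (1, 2)
        assert [e.id for e in doc.entry_points] == ["seg000", "seg001"]

    def test_rows_absent_takes_default_page(self, demo_app):
        doc = execute_entry_points(demo_app.adapters["demo"], None, 2)
        assert (doc.first, doc.last) == (1, 2) and len(doc.entry_points) == 2

    def test_window_past_the_end_is_empty_not_error(self, demo_app):
        doc = execute_entry_points(demo_app.adapters["demo"], (10, 20), 1000)
        assert doc.entry_points == [] and doc.total == 3

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_page_concatenation_equals_full_listing(self, demo_app, k):
        handle = demo_app.adapters["demo"]
        full = execute_entry_points(handle, None, 1000).entry_points
        pages = []
        first = 1
        while True:
            doc = execute_entry_points(handle, (first, first + k - 1), 1000)
            if not doc.entry_points:
                break
            pages.extend(doc.entry_points)
            first += k
        assert pages == full


class TestExecuteStylesheet:
    def test_server_default_used_when_adapter_has_none(self, demo_app):
        doc = execute_stylesheet(demo_app.adapters["demo"], default_stylesheet())
        assert doc.stylesheet == default_stylesheet()

    def test_adapter_stylesheet_wins_over_default(self, demo_app):
        handle = demo_app.adapters["demo"]
        own = default_stylesheet()
        handle.get_stylesheet = lambda: own
        try:
            marker = object()
            assert execute_stylesheet(handle, marker).stylesheet is own
        finally:
            del handle.get_stylesheet

    def test_no_stylesheet_anywhere(self, demo_app):
        with pytest.raises(BadStylesheet):
            execute_stylesheet(demo_app.adapters["demo"], None)


class TestExecuteSequence:
    def test_unknown_segment_is_reference_error(self, demo_config, demo_app):
        cmd = parse_request("/das/ref/sequence", "segment=chrZZ")
        with pytest.raises(BadReferenceObject):
            execute(cmd, demo_config, demo_app.adapters)

    def test_out_of_bounds_is_reference_error(self, demo_config, demo_app):
        cmd = parse_request("/das/ref/sequence", "segment=seg000:1,99999")
        with pytest.raises(BadReferenceObject):
            execute(cmd, demo_config, demo_app.adapters)

    def test_document_matches_substring_oracle(self, demo_config, demo_app, demo_sequences):
        cmd = parse_request("/das/ref/sequence", "segment=seg002:10,40")
        doc = execute(cmd, demo_config, demo_app.adapters)
        (rec,) = doc.records
        assert rec.residues == demo_sequences["seg002"][9:40]
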