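"""GFF parsing, interval-index queries, adapters and the sequence contract."""

import random

import pytest

from dasserve.errors import UNKNOWN_SEGMENT, AdapterError, BadReferenceObject
from dasserve.fixtures import FixtureSpec, generate_gff, generate_reference
from dasserve.model import SegmentQuery, overlaps
from dasserve.sources import (
    GffFileSource,
    get_sequence_builtin,
    load_adapter,
    parse_gff,
    query_interval_index,
    serialize_gff,
)

GFF_SMALL = """\
##gff-version 3
##sequence-region chr1 1 5000
chr1\tcuration\texon\t100\t200\t4.5\t+\t0\tID=e1;category=transcription
chr1\tcuration\texon\t300\t450\t.\t.\t.\tID=e2;Note=second%20exon
chr1\tcuration\tintron\t201\t299\t0.0\t-\t1\tID=i1
"""


class TestParseGff:
    def test_counts_and_segments(self):
        store = parse_gff(GFF_SMALL)
        assert len(store.feature_index) == 3
        assert list(store.segments) == ["chr1"]
        assert store.segments["chr1"].bound == 5000
        by_id: dict[str, int] = {}
        for t, n in store.types.items():
            by_id[t.id] = by_id.get(t.id, 0) + n
        assert by_id == {"exon": 2, "intron": 1}

    def test_sentinel_mapping_for_dot_score_strand_phase(self):
        store = parse_gff(GFF_SMALL)
        _, e2 = store.feature_index["e2"]
        assert e2.score is None
        assert e2.orientation == "0"
        assert e2.phase == "-"
        assert e2.notes == ["second exon"]

    def test_zero_score_is_distinct_from_absent(self):
        _, i1 = parse_gff(GFF_SMALL).feature_index["i1"]
        assert i1.score == 0.0 and i1.score is not None

    def test_autogenerated_feature_id_uses_line_number(self):
        store = parse_gff("chr1\tsrc\texon\t1\t10\t.\t.\t.\t.\n")
        assert "line1" in store.feature_index

    @pytest.mark.parametrize(
        "line,message",
        [
            ("chr1\tsrc\texon\t1\t10\t.\t.\t.", "9 tab-separated columns"),
            ("chr1\tsrc\texon\t50\t10\t.\t.\t.\t.", "start 50 > stop 10"),
            ("chr1\tsrc\texon\tx\t10\t.\t.\t.\t.", "non-numeric"),
            ("chr1\tsrc\texon\t0\t10\t.\t.\t.\t.", "start=stop=0"),
        ],
    )
    def test_malformed_lines_report_line_number(self, line, message):
        with pytest.raises(ValueError, match="line 1") as err:
            parse_gff(line + "\n")
        assert message in str(err.value)

    def test_duplicate_ids_last_wins_in_index_all_in_tree(self):
        text = (
            "chr1\ts\texon\t1\t10\t.\t.\t.\tID=dup\n"
            "chr1\ts\tintron\t50\t60\t.\t.\t.\tID=dup\n"
        )
        store = parse_gff(text)
        assert store.feature_index["dup"][1].type.id == "intron"
        assert store.segments["chr1"].n_features == 2
        assert len(store.segments["chr1"].tree) == 2

    def test_generator_bookkeeping_matches_parsed_type_counts(self):
        spec = FixtureSpec(seed=3, n_features=5000)
        text, book = generate_gff(spec)
        store = parse_gff(text)
        assert {t.id: n for t, n in store.types.items()} == book.type_counts

    def test_round_trip_through_gff_serialization(self, demo_store):
        again = parse_gff(serialize_gff(demo_store))
        assert set(again.feature_index) == set(demo_store.feature_index)
        for fid, (sid, f) in demo_store.feature_index.items():
            sid2, f2 = again.feature_index[fid]
            assert sid2 == sid and f2 == f
        assert {sid: s.bound for sid, s in again.segments.items()} == {
            sid: s.bound for sid, s in demo_store.segments.items()
        }


class TestQueryIntervalIndex:
    def test_unknown_segment_signal(self, demo_store):
        assert query_interval_index(demo_store, SegmentQuery(id="chrZZ")) is UNKNOWN_SEGMENT

    def test_whole_segment_query_returns_all_sorted(self, demo_store):
        feats = query_interval_index(demo_store, SegmentQuery(id="seg000"))
        assert len(feats) == demo_store.segments["seg000"].n_features
        assert feats == sorted(feats, key=lambda f: (f.start, f.feature_id))

    def test_ranged_queries_match_linear_scan_oracle(self):
        spec = FixtureSpec(seed=13, n_segments=3, n_features=10_000)
        text, _ = generate_gff(spec)
        store = parse_gff(text)
        rng = random.Random(77)
        all_features = {
            sid: query_interval_index(store, SegmentQuery(id=sid))
            for sid in store.segments
        }
        for _ in range(200):
            sid = rng.choice(sorted(store.segments))
            a = rng.randint(1, spec.segment_length)
            q = SegmentQuery(id=sid, start=a, stop=min(a + rng.randint(0, 20_000), spec.segment_length))
            expected = [f for f in all_features[sid] if overlaps(f, q)]
            assert query_interval_index(store, q) == expected

    def test_range_monotonicity_with_nonpositional_features(self, demo_store):
        rng = random.Random(5)
        for _ in range(50):
            sid = rng.choice(sorted(demo_store.segments))
            a = rng.randint(1, 9000)
            inner = SegmentQuery(id=sid, start=a, stop=a + 200)
            outer = SegmentQuery(id=sid, start=max(1, a - 300), stop=a + 600)
            inner_ids = {f.feature_id for f in query_interval_index(demo_store, inner)}
            outer_ids = {f.feature_id for f in query_interval_index(demo_store, outer)}
            assert inner_ids <= outer_ids


class TestAdapters:
    def test_load_gff_adapter(self, demo_dir):
        handle = load_adapter("gff", {"file": str(demo_dir / "demo.gff")})
        assert handle.get_types()

    def test_unknown_adapter_name(self):
        with pytest.raises(AdapterError, match="nosuch"):
            load_adapter("nosuch", {})

    def test_gff_adapter_without_file_property_names_it(self):
        with pytest.raises(AdapterError, match="'file'"):
            load_adapter("gff", {})

    def test_gff_adapter_bad_path(self):
        with pytest.raises(AdapterError, match="cannot read"):
            load_adapter("gff", {"file": "/nonexistent/x.gff"})

    def test_entry_points_pagination_is_complete_and_stable(self, demo_dir):
        handle = load_adapter("gff", {"file": str(demo_dir / "demo.gff")})
        total, full = handle.get_entry_points(0, 10_000)
        assert [e.id for e in full] == sorted(e.id for e in full)
        for k in (1, 3, 7):
            pages = []
            offset = 0
            while True:
                t, page = handle.get_entry_points(offset, k)
                assert t == total  # totals stable across pages
                if not page:
                    break
                pages.extend(page)
                offset += k
            assert pages == full

    def test_entry_point_stop_is_max_of_bound_and_feature_stop(self):
        text = "chr1\ts\texon\t10\t950\t.\t.\t.\tID=a\n##sequence-region chr1 1 400\n"
        source = GffFileSource()
        source.load_store(parse_gff(text))
        _, (ep,) = source.get_entry_points(0, 10)
        assert ep.stop == 950

    def test_ranged_features_subset_of_whole_segment(self, demo_dir):
        handle = load_adapter("gff", {"file": str(demo_dir / "demo.gff")})
        whole = {f.feature_id for f in handle.get_features_by_segment(SegmentQuery(id="seg001"))}
        ranged = handle.get_features_by_segment(SegmentQuery(id="seg001", start=100, stop=800))
        assert {f.feature_id for f in ranged} <= whole


class TestGetSequence:
    SEQS = {"p1": "MKVL"}

    def test_ranged_slice(self):
        rec = get_sequence_builtin(self.SEQS, SegmentQuery(id="p1", start=2, stop=3))
        assert (rec.residues, rec.start, rec.stop) == ("KV", 2, 3)

    def test_full_range_equals_whole_segment(self):
        whole = get_sequence_builtin(self.SEQS, SegmentQuery(id="p1"))
        ranged = get_sequence_builtin(self.SEQS, SegmentQuery(id="p1", start=1, stop=4))
        assert whole == ranged

    def test_unknown_segment_signal(self):
        assert get_sequence_builtin(self.SEQS, SegmentQuery(id="p9")) is UNKNOWN_SEGMENT

    def test_out_of_bounds_raises_never_truncates(self):
        with pytest.raises(BadReferenceObject, match="exceeds length"):
            get_sequence_builtin(self.SEQS, SegmentQuery(id="p1", start=2, stop=9))

    def test_random_subranges_match_substring_oracle(self):
        rng = random.Random(2)
        spec = FixtureSpec(seed=21, n_segments=4, segment_length=3000, n_features=1)
        seqs = generate_reference(spec)
        for _ in range(300):
            sid = rng.choice(sorted(seqs))
            a = rng.randint(1, len(seqs[sid]))
            b = rng.randint(a, len(seqs[sid]))
            rec = get_sequence_builtin(seqs, SegmentQuery(id=sid, start=a, stop=b))
            assert rec.residues == seqs[sid][a - 1 : b]
            assert len(rec.residues) == rec.stop - rec.start + 1

    def test_reference_adapter_reads_tsv(self, demo_dir, demo_sequences):
        handle = load_adapter("reference", {"file": str(demo_dir / "ref.tsv")})
        rec = handle.get_sequence(SegmentQuery(id="seg000", start=5, stop=9))
        assert rec.residues == demo_sequences["seg000"][4:9]
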