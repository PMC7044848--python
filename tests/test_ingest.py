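"""Movement-record parsing, journey assembly and category agglomeration."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from careflow.errors import FormatError, InvalidParameterError
from careflow.ingest import (
    apply_category_map,
    assemble_journeys,
    compact_path,
    read_category_map,
    read_movement_records,
    write_movement_records,
)
from conftest import make_events, make_journeys


def parse(text: str):
    return read_movement_records(io.StringIO(text))


HEADER = "admission_id,location,entry_time,exit_time\n"


class TestReadMovementRecords:
    def test_well_formed(self):
        res = parse(
            HEADER
            + "A1,AE,2024-01-01T00:00,2024-01-01T02:00\n"
            + "A1,CT,2024-01-01T02:00,2024-01-01T03:00\n"
            + "A2,AE,2024-01-01T01:00,2024-01-01T05:00\n"
        )
        assert len(res.events) == 3
        assert res.rejects == []

    def test_inverted_interval_rejected(self):
        res = parse(HEADER + "A1,AE,2024-01-01T05:00,2024-01-01T02:00\n")
        assert len(res.events) == 0
        assert len(res.rejects) == 1
        assert "inverted interval" in res.rejects[0].reason

    def test_mixed_valid_invalid_counts(self):
        rows = [
            "A1,AE,2024-01-01T00:00,2024-01-01T01:00",  # ok
            "A1,CT,not-a-time,2024-01-01T02:00",  # bad entry
            "A1,W1,2024-01-01T02:00,2024-01-01T03:00",  # ok
            "A2,AE,2024-01-01T00:00,2024-01-01T01:00",  # ok
            "A2,,2024-01-01T01:00,2024-01-01T02:00",  # empty location
            "A2,W2,2024-01-01T02:00,",  # ok (open exit)
            "A3,AE,2024-01-01T00:00,2024-01-01T04:00",  # ok
        ]
        res = parse(HEADER + "\n".join(rows) + "\n")
        assert len(res.events) == 5
        assert len(res.rejects) == 2
        assert {r.row_number for r in res.rejects} == {3, 6}

    def test_missing_column_is_format_error(self):
        with pytest.raises(FormatError, match="exit_time"):
            parse("admission_id,location,entry_time\nA1,AE,2024-01-01T00:00\n")

    def test_empty_file_warns(self):
        with pytest.warns(UserWarning):
            res = parse("")
        assert res.events == []

    def test_timezone_aware_rejected(self):
        res = parse(HEADER + "A1,AE,2024-01-01T00:00+02:00,2024-01-01T01:00\n")
        assert len(res.events) == 0
        assert "timezone" in res.rejects[0].reason

    def test_round_trip_through_dialect(self, small_hospital):
        _, events = small_hospital
        buf = io.StringIO()
        write_movement_records(events, buf)
        buf.seek(0)
        res = read_movement_records(buf)
        assert res.events == events
        assert res.rejects == []


class TestAssembleJourneys:
    def test_ordered_events(self):
        events = make_events(
            [("A1", "AE", 0, 1), ("A1", "CT", 1, 2), ("A1", "Ward", 2, 3)]
        )
        res = assemble_journeys(events)
        assert [j.path for j in res.journeys] == [("AE", "CT", "Ward")]

    def test_out_of_order_events_sorted(self):
        events = make_events(
            [("A1", "Ward", 2, 3), ("A1", "AE", 0, 1), ("A1", "CT", 1, 2)]
        )
        res = assemble_journeys(events)
        assert res.journeys[0].path == ("AE", "CT", "Ward")

    def test_consecutive_duplicates_compacted(self):
        # a continued stay in the same location is not a transfer
        events = make_events(
            [("A1", "AE", 0, 1), ("A1", "AE", 1, 2), ("A1", "Ward", 2, 3)]
        )
        res = assemble_journeys(events)
        assert res.journeys[0].path == ("AE", "Ward")

    def test_simultaneous_records_flagged(self):
        events = make_events([("A1", "B", 0, 2), ("A1", "A", 0, 1), ("A1", "C", 3, 4)])
        res = assemble_journeys(events)
        assert res.ambiguous_admissions == ["A1"]
        # deterministic tie-break: exit_time then lexicographic
        assert res.journeys[0].path == ("A", "B", "C")

    def test_journey_count_equals_admissions(self, small_hospital):
        _, events = small_hospital
        res = assemble_journeys(events)
        assert len(res.journeys) == len({ev.admission_id for ev in events})

    def test_missing_exit_kept(self):
        events = make_events([("A1", "AE", 0, None), ("A1", "W", 1, 2)])
        res = assemble_journeys(events)
        assert res.journeys[0].path == ("AE", "W")

    @given(st.lists(st.sampled_from("ABCD"), min_size=1, max_size=30))
    @settings(deadline=None)
    def test_compaction_idempotent(self, path):
        once = compact_path(path)
        assert compact_path(once) == once
        assert all(a != b for a, b in zip(once, once[1:]))


class TestApplyCategoryMap:
    def test_agglomeration_and_recompaction(self):
        journeys = make_journeys([["AE", "WardA", "WardB"]])
        mapping = {"AE": "AE", "WardA": "surgical", "WardB": "surgical"}
        out = apply_category_map(journeys, mapping)
        assert out[0].path == ("AE", "surgical")

    def test_identity_map(self):
        journeys = make_journeys([["AE", "W1", "W2"]])
        mapping = {l: l for l in ("AE", "W1", "W2")}
        assert [j.path for j in apply_category_map(journeys, mapping)] == [
            ("AE", "W1", "W2")
        ]

    def test_hand_tabulated_category_transfers(self):
        # 4 journeys over 6 wards -> 3 categories; transfers counted by hand
        mapping = {
            "W1": "med", "W2": "med", "W3": "surg", "W4": "surg",
            "W5": "inv", "W6": "inv",
        }
        journeys = make_journeys(
            [
                ["W1", "W3", "W5", "W3"],  # med>surg, surg>inv, inv>surg
                ["W1", "W2", "W4"],        # (compacted med), med>surg
                ["W5", "W6", "W1"],        # (compacted inv), inv>med
                ["W3", "W1", "W2"],        # surg>med (compacted med)
            ]
        )
        from careflow.build import build_network

        net = build_network(apply_category_map(journeys, mapping))
        expected = {
            ("med", "surg"): 2,
            ("surg", "inv"): 1,
            ("inv", "surg"): 1,
            ("inv", "med"): 1,
            ("surg", "med"): 1,
        }
        got = {(u, v): d["weight"] for u, v, d in net.edges(data=True)}
        assert got == expected

    def test_unmapped_policies(self):
        journeys = make_journeys([["AE", "X"]])
        mapping = {"AE": "emergency"}
        with pytest.raises(FormatError, match="X"):
            apply_category_map(journeys, mapping, "error")
        assert apply_category_map(journeys, mapping, "passthrough")[0].path == (
            "emergency",
            "X",
        )
        assert apply_category_map(journeys, mapping, "other_bucket")[0].path == (
            "emergency",
            "OTHER",
        )
        with pytest.raises(InvalidParameterError):
            apply_category_map(journeys, mapping, "bogus")

    def test_map_then_build_equals_build_then_contract(self):
        """Category mapping before building equals node contraction after,
        when no consecutive same-category compaction occurs; when it does,
        the category self-transfers are removed."""
        from careflow.build import build_network

        mapping = {"A1": "a", "A2": "a", "B1": "b"}
        # no same-category adjacency: the two routes agree exactly
        journeys = make_journeys([["A1", "B1", "A2"], ["B1", "A1"]])
        direct = build_network(apply_category_map(journeys, mapping))
        contracted = {}
        for j in journeys:
            for u, v in zip(j.path, j.path[1:]):
                cu, cv = mapping[u], mapping[v]
                contracted[(cu, cv)] = contracted.get((cu, cv), 0) + 1
        assert {(u, v): d["weight"] for u, v, d in direct.edges(data=True)} == contracted

        # same-category adjacency: contraction would create a self-edge,
        # which the category network must not contain
        journeys2 = make_journeys([["A1", "A2", "B1"]])
        direct2 = build_network(apply_category_map(journeys2, mapping))
        assert {(u, v): d["weight"] for u, v, d in direct2.edges(data=True)} == {
            ("a", "b"): 1
        }


class TestCategoryMapCSV:
    def test_read(self):
        m = read_category_map(io.StringIO("location,category\nAE,emergency\nW1,med\n"))
        assert m == {"AE": "emergency", "W1": "med"}

    def test_bad_header(self):
        with pytest.raises(FormatError):
            read_category_map(io.StringIO("loc,cat\nAE,emergency\n"))
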