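"""Event-table parsing, class assignment, quality filters and strata."""

import pytest

from splicecnn.events import (
    EVENT_TSV_COLUMNS,
    FilterThresholds,
    TableSchemaError,
    apply_quality_filters,
    classify_event,
    classify_events,
    parse_event_table,
    stratify_by_frequency,
    write_event_table,
)

from conftest import make_event

HEADER = "\t".join(EVENT_TSV_COLUMNS)


def _write_tsv(path, rows):
    path.write_text(HEADER + "\n" + "\n".join("\t".join(map(str, r)) for r in rows) + "\n")


TOY_ROWS = [
    # event_id chrom strand start end l1 l3 incl u3 u5 ei ee e3 e5 (1-based inclusive coords)
    ["con1", "chr1", "+", 101, 200, 500, 500, 1.0, 1.0, 1.0, 50, 0, 0, 0],
    ["es1", "chr1", "+", 1101, 1220, 500, 500, 0.4, 1.0, 1.0, 20, 30, 0, 0],
    ["alt3_1", "chr2", "-", 101, 200, 300, 400, 1.0, 0.7, 1.0, 40, 0, 9, 0],
    ["alt5_1", "chr2", "+", 501, 640, 300, 400, 1.0, 1.0, 0.2, 40, 0, 0, 6],
]


class TestParse:
    def test_round_trip_of_documented_schema(self, tmp_path):
        p = tmp_path / "events.tsv"
        _write_tsv(p, TOY_ROWS)
        events, errors = parse_event_table(p)
        assert errors == []
        assert [e.event_id for e in events] == ["con1", "es1", "alt3_1", "alt5_1"]
        classes = [classify_event(e) for e in events]
        assert classes == ["CON", "ES", "ALT3", "ALT5"]
        e = events[0]
        # 1-based inclusive (101,200) -> 0-based half-open (100,200), len 100
        assert (e.exon_start, e.exon_end, e.exon_len) == (100, 200, 100)

    def test_malformed_row_collected_with_line_number(self, tmp_path):
        rows = [TOY_ROWS[0], ["bad", "chr1", "+", 10, 60, 100, 100, 1.2, 1, 1, 5, 0, 0, 0]]
        p = tmp_path / "events.tsv"
        _write_tsv(p, rows)
        events, errors = parse_event_table(p)
        assert len(events) == 1
        assert len(errors) == 1
        assert errors[0].line == 3  # header is line 1
        assert "incl_level" in errors[0].message

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "events.tsv"
        p.write_text("event_id\tchrom\nx\tchr1\n")
        with pytest.raises(TableSchemaError, match="strand"):
            parse_event_table(p)

    def test_write_read_round_trip(self, tmp_path):
        p = tmp_path / "events.tsv"
        _write_tsv(p, TOY_ROWS)
        events, _ = parse_event_table(p)
        events = classify_events(events)
        q = tmp_path / "out.tsv"
        write_event_table(events, q)
        again, errors = parse_event_table(q)
        assert errors == []
        for a, b in zip(events, again):
            assert (a.exon_start, a.exon_end, a.event_id) == (b.exon_start, b.exon_end, b.event_id)


class TestClassify:
    @pytest.mark.parametrize(
        "incl,u3,u5,expected",
        [
            (1.0, 1.0, 1.0, "CON"),
            (0.5, 1.0, 1.0, "ES"),
            (1.0, 0.7, 1.0, "ALT3"),
            (1.0, 1.0, 0.6, "ALT5"),
            (1.0, 0.7, 0.6, "EXCLUDED"),  # both alternative sites
            (0.5, 0.7, 1.0, "EXCLUDED"),  # skipping + alt site
            (0.0, 1.0, 1.0, "EXCLUDED"),  # never included is not a cassette exon
        ],
    )
    def test_label_assignment(self, incl, u3, u5, expected):
        e = make_event(incl_level=incl, usage3_level=u3, usage5_level=u5)
        assert classify_event(e) == expected

    def test_classification_is_total(self, small_synth):
        for e in small_synth.events:
            assert e.as_class in {"CON", "ES", "ALT3", "ALT5", "EXCLUDED"}


class TestFilters:
    def test_es_needs_twenty_supporting_ests(self):
        e = make_event(cls="ES", est_incl=10, est_excl=9)
        kept, rejected = apply_quality_filters([e])
        assert kept == [] and rejected[0].rule == "min_est_skipping"

    def test_alt3_with_exactly_four_ests_is_kept(self):
        e = make_event(cls="ALT3", est_alt3=4)
        kept, rejected = apply_quality_filters([e])
        assert len(kept) == 1 and rejected == []

    def test_short_exon_rejected(self):
        e = make_event(exon_end=1024)  # 24 nt
        kept, rejected = apply_quality_filters([e])
        assert rejected[0].rule == "min_exon_len"

    def test_intron_boundary_is_inclusive(self):
        e = make_event(upstream_intron_len=80)
        kept, rejected = apply_quality_filters([e])
        assert len(kept) == 1

    def test_first_failing_rule_order_est_before_lengths(self):
        # violates both the EST rule and the exon-length rule
        e = make_event(cls="ES", est_incl=5, est_excl=5, exon_end=1010)
        _, rejected = apply_quality_filters([e])
        assert rejected[0].rule == "min_est_skipping"

    def test_idempotent_and_partitioning(self):
        events = [
            make_event("a", "CON"),
            make_event("b", "ES", est_incl=3, est_excl=3),
            make_event("c", "ALT5"),
            make_event("d", "CON", downstream_intron_len=10),
        ]
        kept, rejected = apply_quality_filters(events)
        assert {e.event_id for e in kept} | {r.event.event_id for r in rejected} == {
            "a", "b", "c", "d"
        }
        assert [e.event_id for e in kept] == ["a", "c"]  # order stable
        kept2, rejected2 = apply_quality_filters(kept)
        assert kept2 == kept and rejected2 == []

    def test_unclassified_event_raises(self):
        e = make_event()
        e.as_class = ""
        with pytest.raises(ValueError, match="classified"):
            apply_quality_filters([e])

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            FilterThresholds(min_exon_len=0)


class TestStrata:
    def test_boundaries(self):
        hi = make_event("hi", "ES", incl_level=0.85)
        lo = make_event("lo", "ALT5", usage5_level=0.10)
        edge = make_event("edge", "ES", incl_level=0.80)
        strata = stratify_by_frequency([hi, lo, edge])
        assert strata == {"hi": "HEvents", "lo": "MREvents", "edge": "MREvents"}

    def test_con_has_no_stratum(self):
        with pytest.raises(ValueError):
            stratify_by_frequency([make_event()])

    def test_partition_is_exhaustive(self, small_synth):
        non_con = [e for e in small_synth.events if e.as_class != "CON"]
        strata = stratify_by_frequency(non_con)
        assert len(strata) == len(non_con)
        counts = {"HEvents": 0, "MREvents": 0}
        for s in strata.values():
            counts[s] += 1
        assert counts["HEvents"] + counts["MREvents"] == len(non_con)
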