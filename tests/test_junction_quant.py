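"""Junction extraction, filtering, psi metrics, event classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spliceamp.gene_model import parse_exon_relative_label
from spliceamp.junction_quant import (
    SpliceEvent,
    compute_exon_psi,
    compute_psi,
    compute_sj_usage,
    detect_events,
    event_usage_table,
    extract_junctions,
    filter_junctions,
)

from conftest import build_table


class TestExtraction:
    def test_single_junction_read(self, toy_plus, sam_writer):
        # read: 50M100N50M starting at 151 -> spans exon1/exon2 junction
        path = sam_writer(toy_plus, [("r1", 0, 151, "50M100N50M")])
        table = extract_junctions(path, toy_plus)
        assert table.counts.iloc[:, 0].to_dict() == {(201, 300): 1}
        assert table.annotated.all()

    def test_multi_junction_read_counts_both(self, toy_plus, sam_writer):
        path = sam_writer(toy_plus, [("r1", 0, 151, "50M100N100M100N50M")])
        table = extract_junctions(path, toy_plus)
        assert table.counts.iloc[:, 0].to_dict() == {(201, 300): 1, (401, 500): 1}

    def test_anchor_rule_drops_short_overhangs(self, toy_plus, sam_writer):
        path = sam_writer(
            toy_plus,
            [
                ("ok", 0, 151, "50M100N50M"),
                ("short_right", 0, 151, "50M100N5M"),
                ("short_left", 0, 194, "7M100N50M"),
            ],
        )
        table = extract_junctions(path, toy_plus, min_anchor=8)
        assert int(table.counts.iloc[0, 0]) == 1

    def test_minus_strand_orientation(self, toy_minus, sam_writer):
        # read spans the exon1-exon2 junction of the minus-strand gene:
        # genomic blocks 1651-1700 then 2001-2050, donor 2000, acceptor 1701
        path = sam_writer(toy_minus, [("r1", 16, 1651, "50M300N50M")])
        table = extract_junctions(path, toy_minus)
        assert list(table.counts.index) == [(2000, 1701)]
        donor, acceptor = table.counts.index[0]
        assert donor > acceptor

    def test_secondary_and_unmapped_skipped(self, toy_plus, sam_writer):
        path = sam_writer(
            toy_plus,
            [
                ("r1", 0, 151, "50M100N50M"),
                ("r2", 256, 151, "50M100N50M"),  # secondary
                ("r3", 4, 151, "50M100N50M"),  # unmapped
            ],
        )
        table = extract_junctions(path, toy_plus)
        assert int(table.counts.iloc[0, 0]) == 1

    def test_chromosome_mismatch_raises(self, toy_plus, toy_minus, sam_writer):
        path = sam_writer(toy_plus, [("r1", 0, 151, "50M100N50M")])
        with pytest.raises(ValueError, match="model is on"):
            extract_junctions(path, toy_minus)

    def test_multi_sample_columns(self, toy_plus, sam_writer):
        p1 = sam_writer(toy_plus, [("r1", 0, 151, "50M100N50M")], "s1.sam")
        p2 = sam_writer(
            toy_plus,
            [("r2", 0, 151, "50M100N50M"), ("r3", 0, 151, "50M100N50M")],
            "s2.sam",
        )
        table = extract_junctions({"s1": p1, "s2": p2}, toy_plus)
        assert table.counts.loc[(201, 300)].to_dict() == {"s1": 1, "s2": 2}


class TestFilter:
    def test_novel_junction_filter_worked_example(self, toy_plus):
        # three novel junctions with treated counts (5,0), (4,4), (0,12)
        table = build_table(
            toy_plus,
            {
                (211, 300): {"t1": 5, "t2": 0},
                (221, 300): {"t1": 4, "t2": 4},
                (231, 300): {"t1": 0, "t2": 12},
            },
        )
        kept = filter_junctions(table, ["t1", "t2"], min_reads=5)
        assert sorted(kept.junctions) == [(211, 300), (231, 300)]

    def test_annotated_junctions_exempt(self, toy_plus):
        table = build_table(
            toy_plus,
            {(201, 300): {"t1": 1}, (211, 300): {"t1": 1}},
        )
        kept = filter_junctions(table, ["t1"], min_reads=5)
        assert kept.junctions == [(201, 300)]
        assert kept.annotated.all()

    def test_unknown_treated_sample_raises(self, toy_plus):
        table = build_table(toy_plus, {(201, 300): {"t1": 1}})
        with pytest.raises(ValueError, match="not in table"):
            filter_junctions(table, ["nope"])


class TestPsi:
    def test_shared_donor_ratio(self, toy_plus):
        table = build_table(
            toy_plus,
            {(201, 300): {"s": 60}, (201, 500): {"s": 40}},
        )
        psi = compute_psi(table).set_index(["donor", "acceptor"])
        assert psi.loc[(201, 500), "psi5"] == pytest.approx(0.4)
        assert psi.loc[(201, 300), "psi5"] == pytest.approx(0.6)
        # unique acceptors -> psi3 = 1
        assert psi["psi3"].tolist() == pytest.approx([1.0, 1.0])

    def test_three_junctions_shared_acceptor(self, toy_plus):
        table = build_table(
            toy_plus,
            {(201, 500): {"s": 10}, (230, 500): {"s": 30}, (401, 500): {"s": 60}},
        )
        psi = compute_psi(table).set_index(["donor", "acceptor"])
        vals = psi["psi3"]
        assert vals[(201, 500)] == pytest.approx(0.1)
        assert vals[(230, 500)] == pytest.approx(0.3)
        assert vals[(401, 500)] == pytest.approx(0.6)
        assert vals.sum() == pytest.approx(1.0)

    def test_zero_denominator_is_undefined(self, toy_plus):
        table = build_table(
            toy_plus, {(201, 300): {"a": 10, "b": 0}}
        )
        psi = compute_psi(table).set_index("sample")
        assert psi.loc["a", "psi5"] == pytest.approx(1.0)
        assert np.isnan(psi.loc["b", "psi5"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(
            st.tuples(
                st.integers(0, 3), st.integers(0, 3), st.integers(0, 1000)
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_normalization_property(self, toy_plus, counts):
        # arbitrary junction tables: psi5 sums to 1 within each nonzero
        # donor group, psi3 within each nonzero acceptor group
        donors = [205, 215, 225, 235]
        acceptors = [295, 305, 315, 325]
        agg = {}
        for di, ai, n in counts:
            key = (donors[di], acceptors[ai])
            agg[key] = {"s": agg.get(key, {}).get("s", 0) + n}
        table = build_table(toy_plus, agg)
        psi = compute_psi(table)
        for col, group in (("psi5", "donor"), ("psi3", "acceptor")):
            sums = psi.dropna(subset=[col]).groupby(group)[col].sum()
            assert np.allclose(sums.values, 1.0, atol=1e-12)


class TestClassification:
    def test_single_exon_skip(self, dmd_model):
        j = (dmd_model.donor_site(70).pos, dmd_model.acceptor_site(72).pos)
        table = build_table(dmd_model, {j: {"s": 10}})
        (event,) = detect_events(table, dmd_model)
        assert event.kind == "single_ES"
        assert event.label == "exon71_skip"
        assert event.exons == (71,)

    def test_multi_exon_skip(self, dmd_model):
        j = (dmd_model.donor_site(70).pos, dmd_model.acceptor_site(75).pos)
        table = build_table(dmd_model, {j: {"s": 10}})
        (event,) = detect_events(table, dmd_model)
        assert event.kind == "multi_ES"
        assert event.exons == (71, 72, 73, 74)
        assert event.label == "exon71-74_skip"

    def test_pseudoexon_pair(self, dmd_model):
        # novel block inside intron 63: junction pair bracketing it
        lo, hi = dmd_model.intron_span(63)
        pe_hi = hi - 2500  # transcript-downstream boundary offsets
        pe_lo = pe_hi - 89
        ja = (dmd_model.donor_site(63).pos, pe_hi + 1)
        jb = (pe_lo - 1, dmd_model.acceptor_site(64).pos)
        table = build_table(dmd_model, {ja: {"s": 5}, jb: {"s": 5}})
        (event,) = detect_events(table, dmd_model)
        assert event.kind == "PI"
        assert event.label == "63x"
        assert event.junctions == (ja, jb)

    def test_intron1_pseudoexon_is_pe1a(self, dmd_model):
        start = dmd_model.exon(1).start
        ja = (dmd_model.donor_site(1).pos, start - 9000)
        jb = (start - 9121, dmd_model.acceptor_site(2).pos)
        table = build_table(dmd_model, {ja: {"s": 5}, jb: {"s": 5}})
        (event,) = detect_events(table, dmd_model)
        assert (event.kind, event.label) == ("PI", "PE1a")

    def test_intronic_alt5ss_label(self, dmd_model):
        site = parse_exon_relative_label(dmd_model, "E77+1619")
        j = (site, dmd_model.acceptor_site(78).pos)
        table = build_table(dmd_model, {j: {"s": 10}})
        (event,) = detect_events(table, dmd_model)
        assert event.kind == "alt5ss"
        assert event.label == "E77+1619"
        assert event.shared == "acceptor"

    def test_two_alt_donors_not_merged_into_pi(self, dmd_model):
        # two novel donors pairing with exon 78's acceptor stay alt5ss
        s1 = parse_exon_relative_label(dmd_model, "E77+1619")
        s2 = parse_exon_relative_label(dmd_model, "E78-94")
        acc = dmd_model.acceptor_site(78).pos
        table = build_table(dmd_model, {(s1, acc): {"s": 5}, (s2, acc): {"s": 5}})
        events = detect_events(table, dmd_model)
        assert sorted(e.label for e in events) == ["E77+1619", "E78-94"]
        assert all(e.kind == "alt5ss" for e in events)

    def test_exonic_alt3ss_label(self, dmd_model):
        # novel acceptor inside exon 72 (5 bases into the exon)
        ex = dmd_model.exon(72)
        site = ex.end - 5  # minus strand: 6th base from the exon's 5' end
        j = (dmd_model.donor_site(71).pos, site)
        table = build_table(dmd_model, {j: {"s": 10}})
        (event,) = detect_events(table, dmd_model)
        assert event.kind == "alt3ss"
        assert event.label == "E72.6"

    def test_unresolved_junction_excluded(self, dmd_model, caplog):
        # both ends novel and not a pairable pseudoexon
        lo1, hi1 = dmd_model.intron_span(10)
        lo2, hi2 = dmd_model.intron_span(20)
        table = build_table(dmd_model, {(hi1 - 3, lo2 + 3): {"s": 10}})
        with caplog.at_level("WARNING"):
            events = detect_events(table, dmd_model)
        assert events == []
        assert any("unresolved" in r.message for r in caplog.records)


class TestSjUsage:
    def test_es_mean_of_psi5_psi3(self, dmd_model):
        # skip 40 vs inclusion 60/60: psi5 = psi3 = 0.4 -> SJ_ES = 0.4;
        # asymmetric variant checked via direct frame
        psi = pd.DataFrame(
            {
                "donor": [1000],
                "acceptor": [900],
                "sample": ["s"],
                "count": [4],
                "psi5": [0.04],
                "psi3": [0.02],
            }
        )
        event = SpliceEvent("single_ES", "x", ((1000, 900),), exons=(2,))
        assert compute_sj_usage(event, psi)["s"] == pytest.approx(0.03)

    def test_altss_uses_shared_site_index(self):
        psi = pd.DataFrame(
            {
                "donor": [1000],
                "acceptor": [900],
                "sample": ["s"],
                "count": [4],
                "psi5": [1.0],
                "psi3": [0.02],
            }
        )
        event = SpliceEvent("alt5ss", "x", ((1000, 900),), shared="acceptor")
        assert compute_sj_usage(event, psi)["s"] == pytest.approx(0.02)

    def test_pi_mean_of_novel_flanks(self):
        psi = pd.DataFrame(
            {
                "donor": [1000, 940],
                "acceptor": [980, 900],
                "sample": ["s", "s"],
                "count": [5, 3],
                "psi5": [0.05, 1.0],
                "psi3": [1.0, 0.03],
            }
        )
        event = SpliceEvent("PI", "x", ((1000, 980), (940, 900)), intron=1)
        assert compute_sj_usage(event, psi)["s"] == pytest.approx(0.04)

    def test_undefined_components_propagate(self):
        psi = pd.DataFrame(
            {
                "donor": [1000],
                "acceptor": [900],
                "sample": ["s"],
                "count": [0],
                "psi5": [np.nan],
                "psi3": [np.nan],
            }
        )
        event = SpliceEvent("single_ES", "x", ((1000, 900),), exons=(2,))
        assert np.isnan(compute_sj_usage(event, psi)["s"])


class TestExonPsi:
    def _table(self, model, c_up, c_down, c_skip, exon=71):
        counts = {}
        if c_up:
            counts[(model.donor_site(exon - 1).pos, model.acceptor_site(exon).pos)] = {
                "s": c_up
            }
        if c_down:
            counts[(model.donor_site(exon).pos, model.acceptor_site(exon + 1).pos)] = {
                "s": c_down
            }
        if c_skip:
            counts[
                (model.donor_site(exon - 1).pos, model.acceptor_site(exon + 1).pos)
            ] = {"s": c_skip}
        if not counts:
            counts[(model.donor_site(1).pos, model.acceptor_site(2).pos)] = {"s": 0}
        return build_table(model, counts)

    @pytest.mark.parametrize(
        "c_up,c_down,c_skip,expected",
        [
            (100, 100, 0, 1.0),
            (0, 0, 50, 0.0),
            (30, 50, 10, 0.8),  # (30+50)/(30+50+2*10)
        ],
    )
    def test_psi_formula(self, dmd_model, c_up, c_down, c_skip, expected):
        table = self._table(dmd_model, c_up, c_down, c_skip)
        out = compute_exon_psi(71, table, dmd_model)
        assert out.loc[0, "psi"] == pytest.approx(expected)

    def test_undefined_when_no_informative_counts(self, dmd_model):
        table = self._table(dmd_model, 0, 0, 0)
        out = compute_exon_psi(71, table, dmd_model)
        assert not out.loc[0, "defined"]
        assert np.isnan(out.loc[0, "psi"])

    def test_multi_skip_bridges_count_against_inner_exons(self, dmd_model):
        # a junction over exons 71-74 lowers PSI of each bridged exon
        j = (dmd_model.donor_site(70).pos, dmd_model.acceptor_site(75).pos)
        inc = {
            (dmd_model.donor_site(71).pos, dmd_model.acceptor_site(72).pos): {"s": 90},
            (dmd_model.donor_site(72).pos, dmd_model.acceptor_site(73).pos): {"s": 90},
            j: {"s": 10},
        }
        table = build_table(dmd_model, inc)
        out = compute_exon_psi(72, table, dmd_model)
        assert out.loc[0, "psi"] == pytest.approx(180 / 200)

    def test_skip_monotonicity(self, dmd_model):
        # more skip reads -> strictly lower PSI and strictly higher SJ_ES
        last_psi, last_sj = 1.1, -0.1
        for c_skip in (0, 5, 20, 80):
            table = self._table(dmd_model, 100, 100, c_skip)
            psi_val = compute_exon_psi(71, table, dmd_model).loc[0, "psi"]
            assert psi_val < last_psi
            last_psi = psi_val
            if c_skip:
                events = detect_events(table, dmd_model)
                sj = compute_sj_usage(events[0], compute_psi(table))["s"]
                assert sj > last_sj
                last_sj = sj

    def test_es_consistency_symmetric_counts(self, dmd_model):
        # with symmetric inclusion counts, PSI + SJ_ES = 1 exactly
        table = self._table(dmd_model, 70, 70, 30)
        psi_val = compute_exon_psi(71, table, dmd_model).loc[0, "psi"]
        (event,) = detect_events(table, dmd_model)
        sj = compute_sj_usage(event, compute_psi(table))["s"]
        assert psi_val + sj == pytest.approx(1.0, abs=1e-12)


def test_event_usage_table_shape(dmd_model):
    skip_j = (dmd_model.donor_site(70).pos, dmd_model.acceptor_site(72).pos)
    up = (dmd_model.donor_site(70).pos, dmd_model.acceptor_site(71).pos)
    down = (dmd_model.donor_site(71).pos, dmd_model.acceptor_site(72).pos)
    table = build_table(
        dmd_model,
        {
            skip_j: {"a": 10, "b": 20},
            up: {"a": 90, "b": 80},
            down: {"a": 90, "b": 80},
        },
    )
    usage = event_usage_table(table, dmd_model)
    assert set(usage.columns) >= {"event", "kind", "sample", "sj", "psi", "exon"}
    row = usage.set_index(["event", "sample"]).loc[("exon71_skip", "a")]
    assert row["sj"] == pytest.approx(0.1)
    assert row["psi"] == pytest.approx(0.9)
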