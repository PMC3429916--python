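"""Mutation calling and spectrum statistics."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satmut.calling import (
    GenotypeTable,
    MarkerDef,
    MutationCall,
    OffLadderError,
    SchemaError,
    call_mutations,
    delta_units,
    spectrum,
    stratify,
)
from satmut.simulate import LocusSpec, SimConfig, simulate_ma_lines


def _marker(mid="MX", unit="ACAT", repeat=36.0, pm=100, prog=200):
    return MarkerDef(mid, "I", unit, repeat, pm, prog)


def _table(markers, data, t=142):
    return GenotypeTable(
        markers=markers, alleles=pd.DataFrame(data).T, n_generations=t
    )


# ---------------------------------------------------------------------------
# delta_units


@pytest.mark.parametrize(
    "allele,prog,unit_len,expected",
    [(204, 200, 4, 1), (164, 200, 4, -9), (200, 200, 4, 0), (194, 200, 2, -3)],
)
def test_delta_units(allele, prog, unit_len, expected):
    assert delta_units(allele, prog, unit_len) == expected


def test_delta_units_off_ladder():
    with pytest.raises(OffLadderError):
        delta_units(203, 200, 2)


@settings(derandomize=True, max_examples=100)
@given(
    prog=st.integers(100, 400),
    steps=st.integers(-20, 20),
    unit_len=st.integers(2, 6),
)
def test_delta_units_antisymmetric(prog, steps, unit_len):
    allele = prog + steps * unit_len
    if allele <= 0:
        return
    d = delta_units(allele, prog, unit_len)
    assert d == steps
    assert delta_units(prog, allele, unit_len) == -d


# ---------------------------------------------------------------------------
# call_mutations


def test_no_calls_when_all_lines_match_progenitor():
    m = _marker()
    table = _table([m], {m.marker_id: {"L1": 200, "L2": 200}})
    assert call_mutations(table) == []


def test_single_insertion_call():
    m = _marker()
    table = _table([m], {m.marker_id: {"L1": 204, "L2": 200}})
    calls = call_mutations(table)
    assert len(calls) == 1
    assert calls[0].delta_units == 1
    assert calls[0].kind == "insertion" and calls[0].step == "single"


def test_missing_genotypes_reduce_assessed_lines():
    m = _marker()
    table = _table([m], {m.marker_id: {"L1": 200.0, "L2": float("nan"), "L3": 204.0}})
    assert table.lines_assessed(m.marker_id) == 2
    assert len(call_mutations(table)) == 1


def test_off_ladder_allele_suppressed(caplog):
    m = _marker(unit="AC", prog=200)
    table = _table([m], {m.marker_id: {"L1": 203, "L2": 204}})
    with caplog.at_level("WARNING"):
        calls = call_mutations(table)
    assert [c.delta_units for c in calls] == [2]
    assert "off-ladder" in caplog.text


def test_unknown_marker_in_genotypes_is_schema_error():
    m = _marker()
    with pytest.raises(SchemaError):
        _table([m], {"NOPE": {"L1": 200}})


# ---------------------------------------------------------------------------
# spectrum on the packaged panel


def test_panel_spectrum_reproduces_published_statistics(panel):
    markers, calls = panel
    s = spectrum(calls, markers)
    assert s.total_events == 31
    assert s.n_loci_mutated == 11
    assert s.single_step_total == 26
    assert s.single_step_insertions == 21
    assert s.single_step_deletions == 5
    assert s.multi_step_total == 5
    assert s.insertion_events_total == 23
    assert s.deletion_events_total == 8


def test_panel_per_locus_trends(panel):
    markers, calls = panel
    s = spectrum(calls, markers)
    assert s.per_locus_net_units["M82"] == 3
    assert s.per_locus_trend["M82"] == "growth"
    assert s.per_locus_trend["M74"] == "none"
    assert s.per_locus_trend["M78"] == "decrease"
    growth = {m for m, t in s.per_locus_trend.items() if t == "growth"}
    assert growth == {"M34", "M77", "M79", "M80", "M82", "M83", "M84"}


def test_empty_spectrum_is_all_zero():
    s = spectrum([], [_marker()])
    assert s.total_events == 0 and s.n_loci_mutated == 0
    assert s.per_locus_net_units == {} and s.n_per_marker == {}


@settings(derandomize=True, max_examples=100)
@given(
    deltas=st.lists(
        st.tuples(
            st.integers(0, 4),  # marker index
            st.integers(0, 9),  # line index
            st.integers(-5, 5).filter(lambda d: d != 0),
        ),
        max_size=40,
    )
)
def test_spectrum_conservation_identities(deltas):
    """Step and direction tallies always partition the event total."""
    markers = [_marker(f"M{i}") for i in range(5)]
    calls = [MutationCall(f"M{i}", f"L{j}", d) for i, j, d in deltas]
    s = spectrum(calls, markers)
    assert s.single_step_total + s.multi_step_total == s.total_events
    assert s.insertion_events_total + s.deletion_events_total == s.total_events
    for mid, net in s.per_locus_net_units.items():
        assert net == sum(c.delta_units for c in calls if c.marker_id == mid)
        expected = "growth" if net > 0 else "decrease" if net < 0 else "none"
        assert s.per_locus_trend[mid] == expected
    for mid, n in s.n_per_marker.items():
        assert n == len({c.line_id for c in calls if c.marker_id == mid})


def test_spectrum_rejects_unknown_marker():
    with pytest.raises(SchemaError):
        spectrum([MutationCall("NOPE", "L1", 1)], [_marker()])


# ---------------------------------------------------------------------------
# stratification


def test_panel_stratification(panel):
    markers, calls = panel
    perfect_long = stratify(calls, markers, "perfect_long", repeat_count_threshold=3)
    assert perfect_long == {"perfect_long": 29, "other": 2}
    perfection = stratify(calls, markers, "perfection")
    assert perfection["imperfect"] == 1  # only M34 among the imperfect loci
    assert perfection["perfect"] == 30
    assert sum(1 for m in markers if m.is_perfect) == 19
    assert len(markers) == 41


def test_stratify_requires_threshold(panel):
    markers, calls = panel
    with pytest.raises(ValueError):
        stratify(calls, markers, "repeat_count")
    with pytest.raises(ValueError):
        stratify(calls, markers, "nonsense", repeat_count_threshold=3)


# ---------------------------------------------------------------------------
# round trip with the simulator


def test_pipeline_recovers_simulated_truth_without_homoplasy():
    cfg = SimConfig(
        loci=[LocusSpec("ACAT", 30, 5e-4), LocusSpec("AG", 40, 1e-3)],
        seed=42,
    )
    table, truth = simulate_ma_lines(cfg)
    calls = call_mutations(table)
    s = spectrum(calls, table.markers)
    truth_events = truth.events_per_marker()
    # pipeline can never see more events than happened
    assert s.total_events <= sum(truth_events.values())
    # lines with exactly one true event are always recovered with the right sign
    by_pair = {}
    for e in truth.events:
        by_pair.setdefault((e.marker_id, e.line_id), []).append(e.delta_units)
    single = {k: v[0] for k, v in by_pair.items() if len(v) == 1}
    called = {(c.marker_id, c.line_id): c.delta_units for c in calls}
    for pair, d in single.items():
        assert called.get(pair) == d
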