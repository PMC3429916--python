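"""Tandem-repeat scanner: detection, scoring, composition summaries."""

import pytest

from satmut.io import load_genome_survey_strict_perfect
from satmut.motifs import reverse_complement
from satmut.scanner import (
    LOOSE,
    STRICT,
    CompositionSummary,
    ScanConfigError,
    ScanParams,
    at_rich_share,
    missing_classes,
    scan,
    summarize_composition,
)
from satmut.simulate import PlantedRepeat, plant_repeats


def _planted_genome(plants, length=5000, seed=11):
    records, truth = plant_repeats(length, plants, seed=seed)
    return records[0][1], truth


def test_single_planted_perfect_dinucleotide():
    seq, truth = _planted_genome([PlantedRepeat("AG", 20)], length=1000, seed=3)
    loci = scan(seq, "s", STRICT)
    assert len(loci) == 1
    (loc,) = loci
    iv = truth.planted[0]
    assert loc.canonical_class == "AG"
    assert loc.percent_match == 100 and loc.percent_indels == 0
    assert abs(loc.copy_number - 20) <= 0.5
    overlap = min(loc.end, iv.end) - max(loc.start, iv.start)
    assert overlap >= 0.9 * (iv.end - iv.start)


def test_short_perfect_array_below_strict_threshold():
    # (ACGT)x3 spans 12 bp: perfect score 2*12 = 24, under the strict 50 cutoff
    assert scan("ACGTACGTACGT", "s", STRICT) == []
    loose = scan("ACGTACGTACGT", "s", LOOSE)
    assert len(loose) == 1 and loose[0].score == 24


def test_no_recurring_kmer_yields_nothing():
    assert scan("ACGT", "s", STRICT) == []
    assert scan("", "s", STRICT) == []


def test_perfect_array_scores_match_weight_times_span():
    for unit, copies in [("AT", 15), ("AAC", 12), ("TTCAA", 10)]:
        seq = unit * copies
        loci = scan(seq, "s", STRICT)
        assert len(loci) == 1
        assert loci[0].score == STRICT.match_weight * len(seq)
        assert loci[0].is_perfect


def test_nonprimitive_unit_reported_at_primitive_period():
    loci = scan("AC" * 20, "s", STRICT)
    assert len(loci) == 1
    assert loci[0].unit_length == 2 and loci[0].canonical_class == "AC"


def test_imperfect_array_detected_with_reduced_match():
    seq, _ = _planted_genome(
        [PlantedRepeat("AAT", 40, percent_match=90)], length=2000, seed=7
    )
    loci = scan(seq, "s", LOOSE)
    assert any(
        loc.canonical_class == "AAT" and loc.percent_match < 100 for loc in loci
    )


def test_n_runs_split_arrays():
    left, right = "AG" * 15, "AG" * 15
    loci = scan(left + "N" * 10 + right, "s", STRICT)
    assert len(loci) == 2
    assert all(loc.canonical_class == "AG" for loc in loci)
    assert loci[0].end <= 30 and loci[1].start >= 40


def test_planted_recall_and_truth_overlap():
    """Every planted array long enough to clear the threshold is recovered."""
    plants = [
        PlantedRepeat("AG", 20),
        PlantedRepeat("AAT", 15),
        PlantedRepeat("ACAT", 12),
        PlantedRepeat("TTCAA", 10),
        PlantedRepeat("CTCTTC", 9),
    ]
    seq, truth = _planted_genome(plants, length=8000, seed=23)
    loci = scan(seq, "s", STRICT)
    for iv in truth.planted:
        hits = [
            loc
            for loc in loci
            if min(loc.end, iv.end) - max(loc.start, iv.start)
            >= 0.9 * (iv.end - iv.start)
        ]
        assert hits, f"planted {iv.unit}x{iv.copies} at {iv.start} not recovered"


def test_min_score_monotonicity_and_strict_subset_of_loose():
    plants = [PlantedRepeat("AG", 20), PlantedRepeat("AAT", 18),
              PlantedRepeat("ACAT", 14, percent_match=95)]
    seq, _ = _planted_genome(plants, length=6000, seed=5)
    for base in (STRICT, LOOSE):
        low = scan(seq, "s", base)
        raised = ScanParams(
            base.match_weight, base.mismatch_weight, base.indel_weight,
            base.min_score * 2, base.min_copies, base.unit_lengths,
        )
        high = scan(seq, "s", raised)
        spans_low = {(l.start, l.end) for l in low}
        assert all(
            any(a <= h.start and h.end <= b or
                min(h.end, b) - max(h.start, a) > 0 for a, b in spans_low)
            for h in high
        )
        assert len(high) <= len(low)
    strict_loci = scan(seq, "s", STRICT)
    loose_loci = scan(seq, "s", LOOSE)
    for sl in strict_loci:
        assert any(
            min(sl.end, ll.end) - max(sl.start, ll.start) >= 0.5 * sl.span
            for ll in loose_loci
        )


def test_strand_symmetry_of_canonical_classes():
    plants = [PlantedRepeat("AG", 20), PlantedRepeat("AAT", 15),
              PlantedRepeat("TTCAA", 10)]
    seq, _ = _planted_genome(plants, length=5000, seed=13)
    fwd = sorted(loc.canonical_class for loc in scan(seq, "s", STRICT))
    rev = sorted(loc.canonical_class for loc in scan(reverse_complement(seq), "s", STRICT))
    assert fwd == rev


def test_invalid_params_rejected():
    with pytest.raises(ScanConfigError):
        ScanParams(match_weight=0)
    with pytest.raises(ScanConfigError):
        ScanParams(min_copies=2)
    with pytest.raises(ScanConfigError):
        ScanParams(unit_lengths=(7,))


# ---------------------------------------------------------------------------
# composition summaries


def test_loci_per_megabase():
    seq, _ = _planted_genome([PlantedRepeat("AG", 20)], length=1000, seed=3)
    loci = scan(seq, "s", STRICT)
    # the published screen's figure: 730 loci over a 169 Mb genome
    summary = summarize_composition(loci * 730, int(169e6))
    assert summary.loci_per_megabase == pytest.approx(730 / 169, abs=0.005)
    assert round(summary.loci_per_megabase, 2) == 4.32


def test_empty_composition():
    summary = summarize_composition([], 10_000)
    assert summary.n_loci == 0
    assert summary.loci_per_megabase == 0.0
    assert summary.genome_fraction_percent == 0.0


def test_out_of_bounds_locus_rejected():
    seq = "AG" * 20
    loci = scan(seq, "s", STRICT)
    with pytest.raises(ValueError):
        summarize_composition(loci, 10)


def test_genome_fraction_collapses_overlap():
    seq = "AG" * 20
    loci = scan(seq, "s", STRICT)
    doubled = loci + loci  # same interval twice must not double the fraction
    one = summarize_composition(loci, len(seq)).genome_fraction_percent
    two = summarize_composition(doubled, len(seq)).genome_fraction_percent
    assert one == pytest.approx(two)
    assert one == pytest.approx(100.0)


def test_trimer_at_rich_share_is_92_percent():
    """AT-rich trimer classes carry 123 of the 133 published perfect loci."""
    survey = load_genome_survey_strict_perfect()
    share = at_rich_share(survey[3])
    assert round(share) == 92


def test_missing_classes_from_published_counts():
    survey = load_genome_survey_strict_perfect()
    dimers = CompositionSummary.from_class_counts(survey[2])
    assert missing_classes(dimers, 2) == ["CG"]
    trimers = CompositionSummary.from_class_counts(survey[3])
    assert missing_classes(trimers, 3) == ["CCG"]
    tetramers = CompositionSummary.from_class_counts(survey[4])
    # 11 of the 33 tetramer classes have at least one perfect locus
    assert len(missing_classes(tetramers, 4)) == 33 - 11


def test_no_missing_classes_when_all_observed():
    full = CompositionSummary.from_class_counts({"AC": 1, "AG": 1, "AT": 1, "CG": 1})
    assert missing_classes(full, 2) == []
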