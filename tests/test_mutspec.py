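"""Column classification, the conservation invariant, AT-change categories,
and family categorization against a rule-table oracle."""

import dataclasses

import pytest
from hypothesis import given, strategies as st

from ripscan.mutspec import (ATChangeCategory, MutationSpectrum, at_change,
                             classify_alignment, family_category)
from ripscan.pairalign import PairwiseAlignment
from ripscan.seqio import ContentSummary
from ripscan.synthgen import SimulationConfig, simulate_repeat_pair


def aln(q, s):
    ident = sum(1 for a, b in zip(q, s) if a == b and a != "-")
    return PairwiseAlignment("q", "s", q, s, 0.0,
                             100.0 * ident / len(q), len(q))


def content(at_percent):
    return ContentSummary(counts={}, gc_percent=100 - at_percent,
                          at_percent=at_percent, denominator=100)


class TestClassifyAlignment:
    @pytest.mark.parametrize("q,s,field,n", [
        ("ACGT", "ATGT", "c_to_t", 1),
        ("ACGT", "ACAT", "g_to_a", 1),
        ("TTTT", "TCTT", "t_to_c", 1),
        ("AAAA", "AGAA", "a_to_g", 1),
        ("CCCC", "ACCC", "c_to_a", 1),
        ("GGGG", "GTGG", "g_to_t", 1),
        ("AATT", "CATT", "a_to_c", 1),
        ("TTAA", "GTAA", "t_to_g", 1),
        ("AT", "TA", "at_neutral_transversions", 2),
        ("CG", "GC", "gc_neutral_transversions", 2),
    ])
    def test_each_substitution_channel(self, q, s, field, n):
        spec = classify_alignment(aln(q, s))
        assert getattr(spec, field) == n
        assert spec.substitution_columns == n

    def test_deletion_run_counts_one_event(self):
        spec = classify_alignment(aln("AAAA", "A--A"))
        assert spec.deletion_events == 1
        assert spec.deletion_bases == 2
        assert spec.substitution_columns == 0

    def test_insertion_run(self):
        spec = classify_alignment(aln("A---A", "ACCCA"))
        assert spec.insertion_events == 1
        assert spec.insertion_bases == 3

    def test_ambiguity_column_not_a_substitution(self):
        spec = classify_alignment(aln("ACGT", "ANGT"))
        assert spec.ambiguous_columns == 1
        assert spec.substitution_columns == 0

    def test_conservation_over_random_simulations(self):
        # mismatch columns decompose exactly into the ten channels
        for seed in range(30):
            cfg = SimulationConfig(
                seed=seed, ancestor_length=400,
                substitution_rates={k: 0.01 for k in (
                    "c_to_t", "g_to_a", "t_to_c", "a_to_g",
                    "c_to_a", "g_to_t", "a_to_c", "t_to_g",
                    "at_neutral", "gc_neutral")},
                indel_rate=0.004)
            _, _, ledger = simulate_repeat_pair(cfg)
            spec = classify_alignment(ledger.true_alignment)
            ta = ledger.true_alignment
            mismatch_cols = sum(
                1 for a, b in zip(ta.aligned_query, ta.aligned_subject)
                if a != b and a != "-" and b != "-")
            assert spec.substitution_columns + spec.ambiguous_columns == \
                mismatch_cols

    def test_swap_involution(self):
        q, s = "ACGTACGTAC", "ATGTACATAC"
        fwd = classify_alignment(aln(q, s))
        rev = classify_alignment(aln(s, q))
        assert fwd.c_to_t == rev.t_to_c
        assert fwd.g_to_a == rev.a_to_g
        assert fwd.c_to_a == rev.a_to_c
        assert fwd.g_to_t == rev.t_to_g

    def test_rejects_protein(self):
        bad = PairwiseAlignment("q", "s", "MK", "MK", 0.0, 100.0, 2,
                                molecule="protein")
        with pytest.raises(ValueError):
            classify_alignment(bad)


class TestATChange:
    @pytest.mark.parametrize("q_at,s_at,category,delta", [
        (44.2, 42.1, "slight_decrease", -2.1),   # triose-phosphate family
        (35.0, 41.6, "large_increase", 6.6),     # lipase/esterase family
        (40.0, 40.0, "no_change", 0.0),
        (40.0, 41.0, "no_change", 1.0),          # boundary: exactly 1 point
        (40.0, 45.0, "slight_increase", 5.0),    # boundary: exactly 5 points
        (40.0, 45.01, "large_increase", 5.01),
        (40.0, 33.0, "large_decrease", -7.0),
    ])
    def test_categories(self, q_at, s_at, category, delta):
        atc = at_change(content(q_at), content(s_at))
        assert atc.category == category
        assert atc.delta == pytest.approx(delta)


class TestFamilyCategory:
    def _oracle(self, copies, threshold=97.0):
        cats = [c.category for c, _ in copies]
        ups = {"slight_increase", "large_increase"}
        downs = {"slight_decrease", "large_decrease"}
        has_up, has_down = bool(ups & set(cats)), bool(downs & set(cats))
        if has_up and has_down:
            return "bidirectional"
        if not has_up and not has_down:
            return ("homologous"
                    if all(s >= threshold for _, s in copies) else "no_change")
        pool = ups if has_up else downs
        big = "large_increase" if has_up else "large_decrease"
        return big if big in cats else next(iter(
            {"slight_increase"} if has_up else {"slight_decrease"}))

    def test_bidirectional(self):
        copies = [(ATChangeCategory("slight_decrease", -3.0), 70.0),
                  (ATChangeCategory("large_increase", 6.0), 70.0)]
        assert family_category(copies) == "bidirectional"

    def test_all_within_band(self):
        copies = [(ATChangeCategory("no_change", 0.2), 90.0)]
        assert family_category(copies) == "no_change"

    def test_homologous_requires_high_similarity(self):
        copies = [(ATChangeCategory("no_change", 0.0), 99.0),
                  (ATChangeCategory("no_change", -0.5), 97.0)]
        assert family_category(copies) == "homologous"

    def test_random_families_match_rule_table(self, rng):
        cats = ["no_change", "slight_decrease", "large_decrease",
                "slight_increase", "large_increase"]
        for _ in range(100):
            n = int(rng.integers(1, 6))
            copies = [(ATChangeCategory(cats[rng.integers(5)], 0.0),
                       float(rng.uniform(60, 100))) for _ in range(n)]
            assert family_category(copies) == self._oracle(copies)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            family_category([])
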