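"""Stay/Swap interaction screening."""

import dataclasses

import pytest

from psynet.baseline import BaselineResult, BetaParams, beta_posterior, prob_greater
from psynet.cohort import Cohort, Outcome
from psynet.interactions import (
    Seed,
    classify_interaction,
    dyad_scan,
    select_seeds,
    triad_scan,
    tuple_prevalence,
)


def _baseline_result(cid, p):
    from psynet.baseline import ContingencyTable, EpiStats

    return BaselineResult(
        cid, BetaParams(1, 1), BetaParams(1, 1), p,
        EpiStats(1.0, 0.0, 0.0, False), ContingencyTable(1, 1, 1, 1),
    )


class TestSelectSeeds:
    @pytest.mark.parametrize(
        "p,direction",
        [(0.95, "IMPV"), (0.05, "MC"), (0.9, "IMPV"), (0.1, "MC")],
    )
    def test_threshold_rule(self, p, direction):
        seeds = select_seeds([_baseline_result("A", p)])
        assert len(seeds) == 1 and seeds[0].direction == direction

    def test_middling_probability_not_a_seed(self):
        assert select_seeds([_baseline_result("A", 0.6)]) == []


class TestTuplePrevalence:
    def test_hand_count(self, small_catalog, rec_factory):
        sets = [{"A", "B"}, {"A", "B", "C"}, {"A"}, {"B"}]
        records = tuple(rec_factory(f"k{i}", s) for i, s in enumerate(sets))
        labels = {f"k{i}": Outcome.IMPV for i in range(4)}
        # one MC child so both groups are populated
        records += (rec_factory("m0", set()),)
        labels["m0"] = Outcome.MC
        cohort = Cohort(small_catalog, records, labels)
        counts = tuple_prevalence(cohort, ("A", "B"))
        assert counts["IMPV"] == (2, 4)
        assert counts["MC"] == (0, 1)

    def test_singleton_reduces_to_baseline_count(self, labeled_cohort):
        counts = tuple_prevalence(labeled_cohort, ("A",))
        impv = [r for r in labeled_cohort.records
                if labeled_cohort.outcome_labels[r.child_id] is Outcome.IMPV]
        assert counts["IMPV"] == (sum("A" in r.characteristics for r in impv), len(impv))

    def test_never_expressed_member_gives_zero(self, labeled_cohort):
        import dataclasses

        records = tuple(
            dataclasses.replace(r, characteristics=frozenset(r.characteristics - {"D"}))
            for r in labeled_cohort.records
        )
        cohort = dataclasses.replace(labeled_cohort, records=records)
        counts = tuple_prevalence(cohort, ("A", "D"))
        assert counts["IMPV"][0] == 0 and counts["MC"][0] == 0


class TestClassifyInteraction:
    SEED = Seed("A", "IMPV", 0.95)

    def test_stay_when_tuple_matches_seed_direction(self):
        counts = {"IMPV": (40, 128), "MC": (10, 372)}
        res = classify_interaction(self.SEED, ("A", "B"), counts)
        assert res.designation == "Stay"
        assert res.p_higher_impv >= 0.9

    def test_swap_when_tuple_opposes_seed_direction(self):
        counts = {"IMPV": (2, 128), "MC": (60, 372)}
        res = classify_interaction(self.SEED, ("A", "B"), counts)
        assert res.designation == "Swap"
        assert res.p_higher_impv <= 0.1

    def test_five_total_occurrences_discarded_for_rarity(self):
        counts = {"IMPV": (2, 128), "MC": (3, 372)}
        res = classify_interaction(self.SEED, ("A", "B"), counts)
        assert res.designation == "Discarded"
        assert res.discard_reason == "rarity"
        assert res.p_higher_impv is None

    def test_six_occurrences_survive_rarity(self):
        counts = {"IMPV": (3, 128), "MC": (3, 372)}
        res = classify_interaction(self.SEED, ("A", "B"), counts)
        assert res.discard_reason != "rarity"

    def test_indeterminate_tuple_discarded_distinctly(self):
        counts = {"IMPV": (10, 128), "MC": (25, 372)}
        res = classify_interaction(self.SEED, ("A", "B"), counts)
        assert res.designation == "Discarded"
        assert res.discard_reason == "indeterminate"

    def test_probability_matches_beta_comparison(self):
        """Internal consistency: the tuple entity's probability equals
        prob_greater on its per-group posteriors."""
        counts = {"IMPV": (12, 128), "MC": (9, 372)}
        res = classify_interaction(self.SEED, ("A", "B"), counts)
        expected = prob_greater(beta_posterior(12, 128), beta_posterior(9, 372))
        assert res.p_higher_impv == pytest.approx(expected, abs=1e-12)


class TestScans:
    def test_one_seed_enumerates_all_partners(self, labeled_cohort):
        baseline = [_baseline_result("A", 0.95)] + [
            _baseline_result(c, 0.5) for c in ("B", "C", "D")
        ]
        res = dyad_scan(labeled_cohort, baseline)
        assert len(res) == 3  # catalog size 4, seed excluded
        assert all(r.members[0] == "A" for r in res)
        assert all("A" != r.members[1] for r in res)

    def test_triads_enumerate_partner_pairs(self, labeled_cohort):
        baseline = [_baseline_result("A", 0.95)] + [
            _baseline_result(c, 0.5) for c in ("B", "C", "D")
        ]
        res = triad_scan(labeled_cohort, baseline)
        assert len(res) == 3  # C(3, 2)

    def test_no_seeds_empty_result(self, labeled_cohort):
        baseline = [_baseline_result(c, 0.5) for c in "ABCD"]
        assert dyad_scan(labeled_cohort, baseline) == []

    def test_duplicate_member_sets_flagged(self, labeled_cohort):
        baseline = [_baseline_result("A", 0.95), _baseline_result("B", 0.95)] + [
            _baseline_result(c, 0.5) for c in ("C", "D")
        ]
        res = dyad_scan(labeled_cohort, baseline)
        ab = [r for r in res if set(r.members) == {"A", "B"}]
        assert len(ab) == 2  # both reported
        assert sum(1 for r in ab if r.duplicate_of) == 1

    def test_designations_invariant_under_record_shuffle(self, default_cohort):
        import numpy as np

        from psynet.baseline import baseline_scan

        cohort, _ = default_cohort
        results, _ = baseline_scan(cohort)
        res_a = dyad_scan(cohort, results)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(cohort.records))
        shuffled = dataclasses.replace(
            cohort, records=tuple(cohort.records[i] for i in order)
        )
        res_b = dyad_scan(shuffled, results)
        key = lambda r: (r.members, r.designation)
        assert sorted(map(key, res_a)) == sorted(map(key, res_b))
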