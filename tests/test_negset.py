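import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2 as chi2_dist

from gutmet import negset
from gutmet.encoders import parse_ec
from gutmet.io_model import CONSUMPTION, InteractionRecord, MetaboliteRecord
from gutmet.negset import (
    build_negative_superset,
    build_reaction_classification_set,
    chi_square_two_sample,
    instance_score_summary,
    match_score_distributions,
)


def _met(mid, category):
    return MetaboliteRecord(mid, "CCCCO", category)


def _pos(b, m, label=CONSUMPTION):
    return InteractionRecord(b, m, label)


class TestNegativeSuperset:
    def test_category_exclusion(self):
        metabolites = [
            _met("M1", "carbohydrates"),
            _met("M2", "carbohydrates"),
            _met("M3", "fatty_acids"),
        ]
        result = build_negative_superset([_pos("B1", "M1")], metabolites, CONSUMPTION)
        assert [(c.bacterium, c.metabolite) for c in result.candidates] == [("B1", "M3")]
        assert result.excluded_category_map == {"B1": {"carbohydrates"}}

    def test_positives_spanning_all_categories_leave_no_candidates(self):
        metabolites = [_met("M1", "a"), _met("M2", "b")]
        result = build_negative_superset(
            [_pos("B1", "M1"), _pos("B1", "M2")], metabolites, CONSUMPTION
        )
        assert result.candidates == []

    def test_candidates_marked_negative_provenance(self):
        result = build_negative_superset(
            [_pos("B1", "M1")], [_met("M1", "a"), _met("M2", "b")], CONSUMPTION
        )
        assert all(c.provenance == "negative" for c in result.candidates)

    def test_missing_category_raises(self):
        with pytest.raises(ValueError, match="category"):
            build_negative_superset([_pos("B1", "MX")], [_met("M1", "a")], CONSUMPTION)

    @given(st.data())
    def test_matches_exhaustive_enumeration(self, data):
        """On small random worlds the construction equals brute force with both
        exclusion rules applied pair by pair."""
        n_b = data.draw(st.integers(1, 5))
        n_m = data.draw(st.integers(1, 10))
        categories = ["cat0", "cat1", "cat2"]
        metabolites = [
            _met(f"M{i}", data.draw(st.sampled_from(categories), label=f"cat{i}"))
            for i in range(n_m)
        ]
        pairs = data.draw(
            st.sets(
                st.tuples(st.integers(0, n_b - 1), st.integers(0, n_m - 1)),
                min_size=1,
                max_size=12,
            )
        )
        positives = [_pos(f"B{b}", f"M{m}") for b, m in sorted(pairs)]
        result = build_negative_superset(positives, metabolites, CONSUMPTION)

        category_of = {m.metabolite: m.category for m in metabolites}
        pos_pairs = {(p.bacterium, p.metabolite) for p in positives}
        expected = set()
        for b in {p.bacterium for p in positives}:
            banned = {category_of[m] for bb, m in pos_pairs if bb == b}
            for m in metabolites:
                if m.category not in banned and (b, m.metabolite) not in pos_pairs:
                    expected.add((b, m.metabolite))
        assert {(c.bacterium, c.metabolite) for c in result.candidates} == expected


class TestInstanceScoreSummary:
    def test_max_of_scores(self):
        scores = {("M1", "B1"): [("P1", 300), ("P2", 900), ("P3", 150)]}
        assert instance_score_summary(_pos("B1", "M1"), scores) == 900

    def test_mean_statistic_option(self):
        scores = {("M1", "B1"): [("P1", 100), ("P2", 300)]}
        assert instance_score_summary(_pos("B1", "M1"), scores, stat="mean") == 200

    def test_single_score(self):
        assert instance_score_summary(_pos("B1", "M1"), {("M1", "B1"): [("P", 500)]}) == 500

    def test_unscored_instance_is_none(self):
        assert instance_score_summary(_pos("B1", "M1"), {}) is None


class TestChiSquareTwoSample:
    def test_identical_counts_give_zero_stat(self):
        stat, p = chi_square_two_sample([5, 10, 5], [5, 10, 5])
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_two_by_two(self):
        # [[10,0],[0,10]]: expected 5 everywhere, stat = 4 * 25/5 = 20
        stat, p = chi_square_two_sample([10, 0], [0, 10])
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(chi2_dist.sf(20.0, 1))
        assert p < 0.001

    def test_zero_bins_dropped_before_dof(self):
        stat_with, p_with = chi_square_two_sample([5, 5, 0], [5, 5, 0])
        stat_2x2, p_2x2 = chi_square_two_sample([5, 5], [5, 5])
        assert (stat_with, p_with) == (stat_2x2, p_2x2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            chi_square_two_sample([0, 0], [0, 0])


def _scored_records(prefix, values, label=CONSUMPTION, provenance="experimental"):
    records, scores = [], {}
    for i, v in enumerate(values):
        r = InteractionRecord(f"{prefix}B{i}", f"{prefix}M{i}", label, provenance)
        records.append(r)
        scores[(r.metabolite, r.bacterium)] = [("P", int(v))]
    return records, scores


class TestMatchScoreDistributions:
    def test_quota_conservation(self, rng):
        pos, s1 = _scored_records("p", rng.integers(0, 1000, 97))
        cands, s2 = _scored_records("c", rng.integers(0, 1000, 400))
        match = match_score_distributions(pos, cands, {**s1, **s2}, target_n=83, seed=0)
        assert len(match.selected) == 83
        assert match.neg_bin_counts.sum() == 83

    def test_identical_distribution_candidates_match_closely(self, rng):
        pos_vals = np.clip(rng.normal(600, 150, 250), 0, 1000)
        cand_vals = np.clip(rng.normal(600, 150, 2500), 0, 1000)
        pos, s1 = _scored_records("p", pos_vals)
        cands, s2 = _scored_records("c", cand_vals)
        match = match_score_distributions(
            pos, cands, {**s1, **s2}, target_n=len(pos), seed=5
        )
        assert match.p_value >= 0.99

    def test_selected_counts_equal_pos_counts_when_possible(self, rng):
        pos, s1 = _scored_records("p", [100, 100, 500, 900])
        cands, s2 = _scored_records("c", [150, 120, 510, 950, 50, 450])
        match = match_score_distributions(pos, cands, {**s1, **s2}, target_n=4, seed=1)
        np.testing.assert_array_equal(match.pos_bin_counts, match.neg_bin_counts)
        assert match.chi2_stat == 0.0 and match.p_value == 1.0

    def test_target_exceeding_candidates_rejected(self):
        pos, s1 = _scored_records("p", [500])
        cands, s2 = _scored_records("c", [500])
        with pytest.raises(ValueError):
            match_score_distributions(pos, cands, {**s1, **s2}, target_n=5, seed=0)

    def test_zero_target_rejected(self):
        pos, s1 = _scored_records("p", [500])
        with pytest.raises(ValueError):
            match_score_distributions(pos, pos, s1, target_n=0, seed=0)

    def test_unscored_candidates_dropped_silently_but_counted(self):
        pos, s1 = _scored_records("p", [500, 600])
        cands, s2 = _scored_records("c", [550, 650])
        cands.append(InteractionRecord("cX", "mX", CONSUMPTION))
        match = match_score_distributions(pos, cands, {**s1, **s2}, target_n=2, seed=0)
        assert match.n_dropped_unscored == 1

    def test_matching_beats_uniform_selection(self, rng):
        """Over 20 seeded trials with skewed candidate scores, the matched
        selection is never further from the positives than a uniform draw."""
        pos_vals = np.clip(rng.normal(650, 100, 150), 0, 1000)
        # candidate pool skewed low, with enough high-score members to match
        cand_vals = np.concatenate(
            [np.clip(rng.normal(250, 120, 700), 0, 1000),
             np.clip(rng.normal(650, 100, 300), 0, 1000)]
        )
        pos, s1 = _scored_records("p", pos_vals)
        cands, s2 = _scored_records("c", cand_vals)
        scores = {**s1, **s2}
        edges = np.linspace(0, 1000, 11)
        pos_counts, _ = np.histogram(pos_vals, bins=edges)
        wins = 0
        for seed in range(20):
            match = match_score_distributions(
                pos, cands, scores, target_n=len(pos), seed=seed
            )
            uniform_rng = np.random.default_rng(seed)
            uniform_idx = uniform_rng.choice(len(cand_vals), len(pos), replace=False)
            uniform_counts, _ = np.histogram(cand_vals[uniform_idx], bins=edges)
            stat_uniform, _ = chi_square_two_sample(pos_counts, uniform_counts)
            if match.chi2_stat <= stat_uniform:
                wins += 1
        assert wins == 20

    def test_iterative_reseeding_config(self, rng):
        pos, s1 = _scored_records("p", np.clip(rng.normal(500, 200, 60), 0, 1000))
        cands, s2 = _scored_records("c", np.clip(rng.normal(500, 200, 600), 0, 1000))
        match = match_score_distributions(
            pos, cands, {**s1, **s2}, target_n=60, seed=0, max_retries=3
        )
        assert len(match.selected) == 60


class TestReactionClassificationSet:
    @pytest.fixture()
    def inputs(self):
        positives = [
            (parse_ec("1.1.1.1"), "M1"),
            (parse_ec("1.1.1.2"), "M2"),
            (parse_ec("2.7.7.7"), "M1"),
        ]
        pool = [parse_ec(f"3.5.1.{i}") for i in range(1, 9)] + [parse_ec("1.1.1.1")]
        return positives, pool, ["M1", "M2", "M3"]

    def test_balanced_classes(self, inputs):
        dataset = build_reaction_classification_set(*inputs, seed=0)
        labels = [i.label for i in dataset]
        assert len(dataset) == 6 and labels.count(1) == 3 and labels.count(0) == 3

    def test_no_negative_duplicates_a_positive_and_pool_excludes_positive_ecs(self, inputs):
        positives, pool, metabolites = inputs
        dataset = build_reaction_classification_set(positives, pool, metabolites, seed=3)
        pos_keys = {(str(ec), m) for ec, m in positives}
        pos_ecs = {str(ec) for ec, _ in positives}
        for inst in dataset:
            if inst.label == 0:
                assert (str(inst.ec), inst.metabolite) not in pos_keys
                assert str(inst.ec) not in pos_ecs

    def test_seed_reproducibility(self, inputs):
        a = build_reaction_classification_set(*inputs, seed=7)
        b = build_reaction_classification_set(*inputs, seed=7)
        assert a == b

    def test_insufficient_candidates_rejected(self):
        with pytest.raises(ValueError):
            build_reaction_classification_set(
                [(parse_ec("1.1.1.1"), "M1")], [], ["M1"], seed=0
            )
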