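"""MLP training, majority-vote combination, and mutation-load comparison."""

import itertools

import numpy as np
import pytest

from bdvp.classify import (
    LoadComparison,
    TuningSpace,
    majority_vote,
    mutation_load_compare,
    predict_cohort,
    train_default,
    tune_and_train,
)
from bdvp.discovery import SelectedVariant, SelectionResult
from bdvp.features import FeatureMatrix
from bdvp.genome_model import RegionClass
from bdvp.variant_store import VariantKey
from tests.conftest import make_cohort


def _toy_fm(stratum="coding", n=40, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    labels = np.array([1] * (n // 2) + [0] * (n // 2))
    if informative:
        x0 = np.where(labels == 1, rng.integers(2, 5, n), rng.integers(0, 2, n))
    else:
        x0 = rng.integers(0, 3, n)
    x1 = rng.integers(0, 3, n)
    return FeatureMatrix(
        stratum, ["G1", "G2"], [f"S{i}" for i in range(n)],
        np.column_stack([x0, x1]), labels,
    )


class TestTuneAndTrain:
    def test_budget_one_uses_single_configuration(self):
        model = tune_and_train(_toy_fm(), TuningSpace(budget=1, seed=0))
        assert len(model.history.trials) == 1

    def test_separable_data_training_accuracy_one(self):
        labels = np.array([1] * 20 + [0] * 20)
        load = np.column_stack([labels * 3, np.zeros(40, int)])
        fm = FeatureMatrix("coding", ["A", "B"], [f"S{i}" for i in range(40)], load, labels)
        model = tune_and_train(fm, TuningSpace(budget=3, seed=1))
        assert (model.predict(fm) == labels).all()

    def test_same_seed_same_best_params(self):
        fm = _toy_fm(seed=4)
        a = tune_and_train(fm, TuningSpace(budget=5, seed=9))
        b = tune_and_train(fm, TuningSpace(budget=5, seed=9))
        assert a.params == b.params and a.cv_loss == b.cv_loss

    def test_single_class_rejected(self):
        fm = _toy_fm()
        fm.labels[:] = 0
        with pytest.raises(ValueError):
            tune_and_train(fm, TuningSpace(budget=1))

    def test_gene_order_mismatch_rejected(self):
        model = train_default(_toy_fm(), seed=0)
        other = _toy_fm()
        other.genes = ["G2", "G1"]
        with pytest.raises(ValueError, match="gene order"):
            model.predict(other)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "votes, expected",
        [([1, 1, 0], 1), ([0, 0, 0], 0), ([1, 1, 1], 1), ([0, 1, 0], 0)],
    )
    def test_three_votes(self, votes, expected):
        assert majority_vote(votes) == expected

    def test_equals_median_of_three_votes(self):
        for votes in itertools.product([0, 1], repeat=3):
            assert majority_vote(list(votes)) == int(np.median(votes))

    def test_abstention_tie_breaks_toward_zero(self):
        assert majority_vote([1, 0, None]) == 0
        assert majority_vote([1, None, None]) == 1

    def test_combined_accuracy_bounds_given_stratum_marginals(self):
        # per-stratum correct counts (30, 31, 29) of 40: enumerate all
        # feasible correctness-pattern compositions; a sample's majority
        # label is correct iff >= 2 of its 3 votes are correct
        n, m1, m2, m3 = 40, 30, 31, 29
        lo, hi = n, 0
        r = np.arange(n + 1)
        a, b, c, d = np.meshgrid(r, r, r, r, indexing="ij", sparse=False)
        e = m1 - (a + b + c)
        f = m2 - (a + b + d)
        g = m3 - (a + c + d)
        h = n - (a + b + c + d + e + f + g)
        feasible = (e >= 0) & (f >= 0) & (g >= 0) & (h >= 0)
        combined = a + b + c + d
        lo = int(combined[feasible].min())
        hi = int(combined[feasible].max())
        # analytic check: 90 total correct votes; minimizing samples with
        # >= 2 correct puts 25 samples at 3 correct and 15 at 1 correct
        assert (lo, hi) == (25, 40)


class TestPredictCohort:
    def _models_and_fms(self, seed=0, drop=None):
        models, fms = {}, {}
        for stratum in ("coding", "noncoding", "intergenic"):
            fm = _toy_fm(stratum=stratum, seed=seed)
            models[stratum] = None if stratum == drop else train_default(fm, seed=seed)
            fms[stratum] = fm
        return models, fms

    def test_report_counts_and_votes_consistent(self):
        models, fms = self._models_and_fms()
        rep = predict_cohort(models, fms)
        df = rep.per_sample
        assert len(df) == 40
        for _, row in df.iterrows():
            votes = [row[f"vote_{s}"] for s in ("coding", "noncoding", "intergenic")]
            assert row["majority_label"] == majority_vote(votes)
        assert rep.summary["correct_combined"] == (
            df["majority_label"].to_numpy() == df["true_label"].to_numpy()
        ).sum()
        assert 0 <= rep.summary["accuracy_combined"] <= 1

    def test_missing_stratum_model_abstains(self):
        models, fms = self._models_and_fms(drop="intergenic")
        rep = predict_cohort(models, fms)
        assert rep.per_sample["vote_intergenic"].isna().all()
        # majority now runs on the two remaining votes, ties -> 0
        for _, row in rep.per_sample.iterrows():
            votes = [row["vote_coding"], row["vote_noncoding"]]
            assert row["majority_label"] == majority_vote(votes)


def rank_sum_enumeration_p(a, b):
    """Exact two-sided rank-sum p by enumerating all label permutations."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = {}

    def ustat(idx):
        sel = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        u = sum((x > rest).sum() + 0.5 * (x == rest).sum() for x in sel)
        return u

    u_obs = ustat(range(n1))
    center = n1 * (len(pooled) - n1) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ustat(idx) - center) >= abs(u_obs - center) - 1e-9:
            count += 1
    return count / total


class TestMutationLoadCompare:
    def _inputs(self, case_counts, bd_counts):
        sel = SelectionResult(
            selected=[
                SelectedVariant(VariantKey("chr1", 100 + j, "A", "T"), 3,
                                RegionClass.CODING, ("G1",))
                for j in range(max(case_counts + bd_counts))
            ]
        )
        n = len(case_counts) + len(bd_counts)
        m = len(sel.selected)
        carrier = np.zeros((n, m), dtype=np.uint8)
        for i, c in enumerate(case_counts + bd_counts):
            carrier[i, :c] = 1
        matrix, sheet = make_cohort(
            carrier, ["BD_CANCER"] * len(case_counts) + ["BD_ONLY"] * len(bd_counts)
        )
        return sel, matrix, sheet

    def test_identical_distributions_give_maximal_p(self):
        sel, matrix, sheet = self._inputs([2, 2, 2], [2, 2, 2])
        comp = mutation_load_compare(sel, matrix, sheet)
        assert comp.pvalue == 1.0
        assert comp.summaries["BD_CANCER"]["median"] == comp.summaries["BD_ONLY"]["median"]

    def test_exact_p_matches_permutation_enumeration(self):
        sel, matrix, sheet = self._inputs([5, 6, 7], [0, 0, 1])
        comp = mutation_load_compare(sel, matrix, sheet)
        a, b = comp.counts["BD_CANCER"], comp.counts["BD_ONLY"]
        assert list(a) == [5, 6, 7] and list(b) == [0, 0, 1]
        assert comp.summaries["BD_CANCER"]["median"] == 6
        assert comp.summaries["BD_ONLY"]["median"] == 0
        assert comp.pvalue == pytest.approx(rank_sum_enumeration_p(a, b))
        assert comp.pvalue == pytest.approx(0.1)

    def test_small_group_skips_test_with_warning(self):
        sel, matrix, sheet = self._inputs([3, 4], [2])
        with pytest.warns(UserWarning, match="rank-sum test skipped"):
            comp = mutation_load_compare(sel, matrix, sheet)
        assert comp.pvalue is None and comp.summaries["BD_ONLY"]["n"] == 1

    def test_discovery_disease_only_median_zero(self, tiny_cohort):
        from bdvp.discovery import select_variants

        sim = tiny_cohort
        sel = select_variants(sim.matrix, sim.sheet)
        comp = mutation_load_compare(sel, sim.matrix, sim.sheet)
        assert comp.summaries["BD_ONLY"]["median"] == 0
        assert comp.summaries["BD_ONLY"]["max"] == 0
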