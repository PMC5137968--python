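"""Kruskal–Wallis selection, centroid fitting, classification, agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mmse_groups.centroids import (
    KWResult,
    agreement,
    classify,
    classify_frame,
    compute_centroids,
    fleiss_kappa_two_raters,
    kruskal_wallis_by_category,
    paper_model,
    select_categories,
)
from mmse_groups.errors import ValidationError
from mmse_groups.scoring import CATEGORIES

from conftest import rates_frame


def _one_cat_frame(values_by_group):
    """Patients with a single informative category (attention); labels dict too."""
    rows, labels = {}, {}
    i = 0
    for g, values in values_by_group.items():
        for v in values:
            rows[f"p{i}"] = (0.0, 0.0, float(v), 0.0, 0.0)
            labels[f"p{i}"] = g
            i += 1
    return rates_frame(rows), labels


class TestKruskalWallis:
    def test_hand_computed_two_group_statistic(self):
        """{1,2,3} vs {10,11,12}: rank sums 6 and 15 give H = 27/7."""
        frame, labels = _one_cat_frame({"a": [1, 2, 3], "b": [10, 11, 12]})
        res = kruskal_wallis_by_category(frame, labels, categories=("attention",))
        assert res["attention"].statistic == pytest.approx(27 / 7, abs=1e-9)
        assert res["attention"].pvalue == pytest.approx(
            stats.chi2.sf(27 / 7, 1), rel=1e-12
        )

    def test_identical_groups_give_null_result(self):
        frame, labels = _one_cat_frame({"a": [5, 5, 5], "b": [5, 5, 5]})
        res = kruskal_wallis_by_category(frame, labels, categories=("attention",))
        assert res["attention"].statistic == 0.0
        assert res["attention"].pvalue == 1.0

    def test_single_group_rejected(self):
        frame, labels = _one_cat_frame({"a": [1, 2, 3]})
        with pytest.raises(ValidationError):
            kruskal_wallis_by_category(frame, labels, categories=("attention",))

    def test_chi_square_tail_matches_permutation_oracle(self):
        """The chi-square approximation to the KW null agrees with a
        30,000-permutation empirical tail within Monte-Carlo error."""
        rng = np.random.default_rng(42)
        g1 = np.repeat([1.0, 2, 3, 4, 5], 3)
        g2 = np.repeat([2.0, 3, 4, 5, 6], 3)
        g3 = np.repeat([2.0, 4, 5, 6, 7], 3)
        frame, labels = _one_cat_frame({"a": g1, "b": g2, "c": g3})
        res = kruskal_wallis_by_category(frame, labels, categories=("attention",))

        # independent oracle: rank-sum formula under label permutation
        data = np.concatenate([g1, g2, g3])
        n, sizes = len(data), [len(g1), len(g2), len(g3)]
        ranks = stats.rankdata(data)
        _, cnt = np.unique(data, return_counts=True)
        tie = 1 - (cnt**3 - cnt).sum() / (n**3 - n)

        def h_of(r):
            s, i = 0.0, 0
            for m in sizes:
                s += r[i:i + m].sum() ** 2 / m
                i += m
            return (12.0 / (n * (n + 1)) * s - 3 * (n + 1)) / tie

        assert h_of(ranks) == pytest.approx(res["attention"].statistic, abs=1e-9)
        B = 30_000
        perm = np.array([h_of(rng.permutation(ranks)) for _ in range(B)])
        p_perm = float((perm >= res["attention"].statistic - 1e-12).mean())
        mc_se = np.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(res["attention"].pvalue - p_perm) <= 4 * mc_se + 0.002

    def test_log_tail_finite_for_extreme_statistics(self):
        """Group separations yielding p-values past double-precision underflow
        still produce a finite, ordered log10 tail."""
        from mmse_groups.centroids import chi2_log10_sf

        log10p = chi2_log10_sf(1400.0, 4)
        assert np.isfinite(log10p) and log10p == pytest.approx(-300.9, abs=0.5)
        # past the subnormal range the plain tail is zero but the log tail still orders
        deeper = chi2_log10_sf(1600.0, 4)
        assert np.isfinite(deeper) and deeper < log10p
        # matches scipy where scipy is still finite
        assert chi2_log10_sf(100.0, 4) == pytest.approx(
            float(stats.chi2.logsf(100.0, 4)) / np.log(10), rel=1e-12
        )


class TestSelectCategories:
    def test_paper_pvalue_pattern_selects_signature(self):
        pvals = {"registration": 4.3e-302, "attention": 2e-294, "recall": 4.7e-270,
                 "orientation": 9.6e-117, "language": 1e-100}
        assert set(select_categories(pvals, 3)) == {"registration", "attention", "recall"}

    def test_keep_all(self):
        pvals = dict.fromkeys(CATEGORIES, 0.5)
        assert set(select_categories(pvals, 5)) == set(CATEGORIES)

    def test_ties_break_in_canonical_category_order(self):
        pvals = dict.fromkeys(CATEGORIES, 0.123)
        assert select_categories(pvals, 2) == ("orientation", "registration")

    def test_underflowed_pvalues_ranked_by_log_tail(self):
        kw = {
            "registration": KWResult(1450.0, 0.0, -310.0),
            "attention": KWResult(1400.0, 0.0, -300.0),
            "recall": KWResult(1300.0, 0.0, -280.0),
            "orientation": KWResult(550.0, 0.0, -117.0),
            "language": KWResult(470.0, 0.0, -100.0),
        }
        assert select_categories(kw, 3) == ("registration", "attention", "recall")


class TestCentroidsAndClassification:
    def test_singleton_groups_reproduce_their_members(self):
        frame, labels = _one_cat_frame({"a": [30], "b": [70]})
        model = compute_centroids(frame, labels, ("attention",))
        assert model.centroids["a"]["attention"] == 30.0
        assert model.centroids["b"]["attention"] == 70.0

    def test_mean_of_opposite_corners(self):
        frame = rates_frame({"p0": (0, 0, 0, 0, 0), "p1": (100, 100, 100, 100, 100)})
        model = compute_centroids(frame, {"p0": "g", "p1": "g"}, CATEGORIES)
        assert all(v == 50.0 for v in model.centroids["g"].values())

    def test_empty_group_rejected(self):
        frame, labels = _one_cat_frame({"a": [1, 2]})
        labels["p0"] = "a"
        with pytest.raises(ValidationError):
            compute_centroids(frame.iloc[:1], {"p0": "a", "zz": "b"}, ("attention",))

    def test_published_centroids_self_classify(self):
        model = paper_model()
        for g in model.groups:
            winner, dists = classify(model.centroids[g], model)
            assert winner == g and dists[g] == 0.0

    def test_absent_centroid_vector(self):
        winner, _ = classify({"registration": 43.3, "attention": 18.0, "recall": 0.0},
                             paper_model())
        assert winner == "absent"

    def test_derived_vector_against_brute_force(self):
        """(96, 70, 80) assigned by explicit minimisation over all centroids."""
        model = paper_model()
        x = {"registration": 96.0, "attention": 70.0, "recall": 80.0}
        oracle = min(
            model.groups,
            key=lambda g: sum((x[c] - model.centroids[g][c]) ** 2 for c in model.categories),
        )
        winner, _ = classify(x, model)
        assert winner == oracle == "inattentive"

    def test_tie_broken_by_model_group_order(self):
        from mmse_groups.centroids import CentroidModel
        model = CentroidModel(("attention",), {"first": {"attention": 40.0},
                                               "second": {"attention": 60.0}})
        winner, dists = classify({"attention": 50.0}, model)
        assert dists["first"] == dists["second"] and winner == "first"

    def test_missing_category_rejected(self):
        with pytest.raises(ValidationError):
            classify({"registration": 1.0}, paper_model())

    def test_frame_classification_matches_scalar(self):
        model = paper_model()
        frame = pd.DataFrame([
            {"patient_id": "p0", "registration": 96.0, "attention": 70.0, "recall": 80.0},
            {"patient_id": "p1", "registration": 43.3, "attention": 18.0, "recall": 0.0},
        ])
        out = classify_frame(frame, model)
        assert out["p0"] == "inattentive" and out["p1"] == "absent"


class TestAgreement:
    def test_perfect_agreement(self):
        labels = {"p0": "a", "p1": "b", "p2": "a", "p3": "c"}
        res = agreement(labels, dict(labels), categories=("a", "b", "c"))
        assert res.percent_agreement == 100.0 and res.kappa == 1.0

    def test_total_disagreement(self):
        a = {"p0": "A", "p1": "A", "p2": "B", "p3": "B"}
        b = {"p0": "B", "p1": "B", "p2": "A", "p3": "A"}
        res = agreement(a, b, categories=("A", "B"))
        assert res.percent_agreement == 0.0 and res.kappa < 0

    def test_hand_computed_fleiss_value(self):
        """One disagreement in four: P-bar 0.75, P-bar_e 0.53125, kappa 7/15."""
        a = {"p0": "A", "p1": "A", "p2": "B", "p3": "B"}
        b = {"p0": "A", "p1": "A", "p2": "B", "p3": "A"}
        res = agreement(a, b, categories=("A", "B"))
        assert res.percent_agreement == 75.0
        assert res.kappa == pytest.approx(7 / 15, abs=1e-12)

    def test_mismatched_patient_sets_rejected(self):
        with pytest.raises(ValidationError):
            agreement({"p0": "a"}, {"p1": "a"})

    def test_confusion_diagonal_consistency(self):
        a = {"p0": "a", "p1": "b", "p2": "b"}
        b = {"p0": "a", "p1": "a", "p2": "b"}
        res = agreement(a, b, categories=("a", "b"))
        assert np.diag(res.confusion.to_numpy()).sum() == 2
        assert res.n == 3

    def test_high_agreement_lands_in_almost_perfect_band(self):
        """Balanced five-class labels with >=93% agreement give kappa > 0.81."""
        rng = np.random.default_rng(17)
        groups = np.array(["cognisant", "inattentive", "forgetful", "distant", "absent"])
        a = rng.choice(groups, size=1000)
        b = a.copy()
        flip = rng.random(1000) < 0.06
        b[flip] = rng.choice(groups, size=int(flip.sum()))
        res = agreement(dict(enumerate(a)), dict(enumerate(b)), categories=groups)
        assert res.percent_agreement >= 93.0
        assert res.kappa > 0.81

    def test_kappa_never_exceeds_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.choice(["x", "y", "z"], size=30)
            b = rng.choice(["x", "y", "z"], size=30)
            res = agreement(dict(enumerate(a)), dict(enumerate(b)), categories=("x", "y", "z"))
            assert res.kappa <= 1.0 + 1e-12
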