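"""Proportion tests, APOE association, drug harmonization, medication tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mmse_groups.associations import (
    apoe_group_association,
    genotype_from_alleles,
    harmonize_drugs,
    medication_transition_scan,
    medication_transition_test,
    proportion_test,
)
from mmse_groups.errors import ValidationError


class TestProportionTest:
    def test_equal_proportions_are_null(self):
        stat, p = proportion_test([50, 50], [100, 100])
        assert stat == 0.0 and p == 1.0

    def test_extreme_difference(self):
        _, p = proportion_test([90, 10], [100, 100])
        assert p < 1e-15

    def test_group_order_invariance(self):
        a = proportion_test([30, 50, 20], [80, 90, 70])
        b = proportion_test([20, 30, 50], [70, 80, 90])
        assert a == pytest.approx(b)

    def test_two_by_two_agrees_with_exact_hypergeometric(self):
        """Yates-corrected chi-square approximates Fisher's exact test on a
        moderate 2x2 table (within ~5% on the log scale)."""
        stat, p = proportion_test([35, 20], [80, 80])
        p_fisher = stats.fisher_exact([[35, 45], [20, 60]])[1]
        assert abs(np.log10(p) - np.log10(p_fisher)) < 0.15

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            proportion_test([5], [10])
        with pytest.raises(ValidationError):
            proportion_test([5, 5], [10, 0])
        with pytest.raises(ValidationError):
            proportion_test([15, 5], [10, 10])

    def test_null_pvalues_are_uniform(self):
        """Under a common success rate the p-values follow Uniform(0,1)
        (Kolmogorov–Smirnov at alpha = 0.01, 10,000 replicates).  Group size
        2000 keeps the chi-square approximation error below what KS can
        detect at this replicate count; at a few hundred per group the
        approximation bias itself becomes KS-visible."""
        rng = np.random.default_rng(0)
        n, p0 = 2000, 0.3
        succ = rng.binomial(n, p0, size=(10_000, 3))
        pvals = [proportion_test(row, [n] * 3)[1] for row in succ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestApoeAssociation:
    def _genotypes(self, rates_by_group, n_per_group, seed=0):
        rng = np.random.default_rng(seed)
        genos, labels = {}, {}
        i = 0
        for g, risk_rate in rates_by_group.items():
            for _ in range(n_per_group):
                pid = f"p{i}"
                genos[pid] = "e3/e4" if rng.random() < risk_rate else "e3/e3"
                labels[pid] = g
                i += 1
        return genos, labels

    def test_identical_composition_is_null(self):
        genos = {f"p{i}": ("e3/e4" if i % 2 else "e3/e3") for i in range(40)}
        labels = {f"p{i}": ("a" if i < 20 else "b") for i in range(40)}
        res = apoe_group_association(genos, labels)
        assert res.pvalue == pytest.approx(1.0)

    def test_risk_enrichment_detected(self):
        """A distant group enriched for e4 genotypes yields a small p at n=1000."""
        genos, labels = self._genotypes(
            {"cognisant": 0.45, "inattentive": 0.47, "forgetful": 0.55, "distant": 0.70},
            n_per_group=250, seed=1,
        )
        res = apoe_group_association(genos, labels)
        assert res.pvalue < 0.01
        rates = res.rates.set_index("group")["risk_rate"]
        assert rates["distant"] > rates["cognisant"]

    def test_single_group_rejected(self):
        genos = {"p0": "e3/e4", "p1": "e3/e3"}
        labels = {"p0": "a", "p1": "a"}
        with pytest.raises(ValidationError):
            apoe_group_association(genos, labels)

    def test_genotype_from_alleles_sorts(self):
        apoe = pd.DataFrame(
            {"patient_id": ["p0", "p1"], "allele1": ["e4", "e2"], "allele2": ["e3", "e4"]}
        )
        geno = genotype_from_alleles(apoe)
        assert geno["p0"] == "e3/e4" and geno["p1"] == "e2/e4"


class TestHarmonizeDrugs:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "raw_name", "tags"])

    def test_brand_and_generic_merge(self):
        recs = self._records(
            [("p0", "Aricept", "donepezil"), ("p1", "donepezil", "donepezil")]
        )
        out = harmonize_drugs(recs)
        assert set(out["canonical_name"]) == {"aricept"}

    def test_chained_tags_form_one_component(self):
        recs = self._records(
            [("p0", "A", "t1"), ("p1", "B", "t1;t2"), ("p2", "C", "t2")]
        )
        out = harmonize_drugs(recs)
        assert set(out["canonical_name"]) == {"a"}

    def test_untagged_names_stay_singleton(self):
        recs = self._records([("p0", "Mystery Pill", None), ("p1", "other", "")])
        out = harmonize_drugs(recs)
        assert set(out["canonical_name"]) == {"mystery pill", "other"}

    def test_case_and_whitespace_folding(self):
        recs = self._records([("p0", "  Ginkgo   Biloba ", "herb"), ("p1", "ginkgo biloba", "herb")])
        out = harmonize_drugs(recs)
        assert set(out["canonical_name"]) == {"ginkgo biloba"}

    def test_empty_input_passes_through(self):
        out = harmonize_drugs(self._records([]))
        assert out.empty and "canonical_name" in out.columns

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="abcdef", min_size=1, max_size=4),
                st.sets(st.sampled_from(["t1", "t2", "t3"]), max_size=2),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_output_is_a_partition_of_names(self, rows):
        recs = pd.DataFrame(
            [{"patient_id": f"p{i}", "raw_name": name, "tags": ";".join(sorted(tags))}
             for i, (name, tags) in enumerate(rows)]
        )
        out = harmonize_drugs(recs)
        # every normalized name maps to exactly one canonical component
        mapping = out.groupby(out["raw_name"].str.strip().str.casefold())["canonical_name"].nunique()
        assert (mapping == 1).all()
        assert out["canonical_name"].notna().all()


class TestMedicationTransitionTest:
    def _fixture(self, n_focal, k_focal, n_comp, k_comp):
        trans, meds = [], []
        for i in range(n_focal):
            trans.append({"patient_id": f"f{i}", "first_group": "inattentive",
                          "last_group": "absent"})
            if i < k_focal:
                meds.append({"patient_id": f"f{i}", "canonical_name": "citalopram"})
        for i in range(n_comp):
            trans.append({"patient_id": f"c{i}", "first_group": "inattentive",
                          "last_group": "cognisant"})
            if i < k_comp:
                meds.append({"patient_id": f"c{i}", "canonical_name": "citalopram"})
        return (pd.DataFrame(meds, columns=["patient_id", "canonical_name"]),
                pd.DataFrame(trans))

    def test_identical_rates_are_null(self):
        meds, trans = self._fixture(40, 4, 40, 4)
        res = medication_transition_test(meds, trans, "citalopram",
                                         "inattentive", "absent", "others")
        assert res.pvalue > 0.9 and res.effect in ("none", "beneficial", "adverse")

    def test_absent_drug_not_testable(self):
        meds, trans = self._fixture(10, 0, 10, 0)
        res = medication_transition_test(meds, trans, "citalopram",
                                         "inattentive", "absent", "others")
        assert not res.testable and res.pvalue is None and res.effect == "not-testable"

    def test_empty_stratum_rejected(self):
        meds, trans = self._fixture(10, 1, 10, 1)
        with pytest.raises(ValidationError, match="worse"):
            # nothing ranks worse than 'absent'
            medication_transition_test(meds, trans, "citalopram",
                                       "inattentive", "absent", "worse")

    def test_higher_intake_on_deterioration_is_adverse(self):
        meds, trans = self._fixture(50, 15, 200, 10)
        res = medication_transition_test(meds, trans, "citalopram",
                                         "inattentive", "absent", "others")
        assert res.effect == "adverse" and res.pvalue < 0.01

    def test_generator_rate_structure_recovered(self):
        """Cohorts drawn with elevated citalopram intake on the
        inattentive-to-absent transition flag the drug as adverse.  A single
        published-scale cohort holds only ~15 such patients (underpowered),
        so the check runs at five times that size."""
        from mmse_groups.synthetic import generate_cohort, scaled_config

        cohort = generate_cohort(scaled_config(5.0, seed=0))
        meds = harmonize_drugs(cohort.medications)
        canonical = dict(zip(meds["raw_name"].str.casefold(), meds["canonical_name"]))
        trans = cohort.truth[["patient_id", "first_group", "last_group"]]
        expectations = [
            ("citalopram", "inattentive", "absent", "adverse"),
            ("multivitamins", "cognisant", "cognisant", "beneficial"),
            ("ginkgo biloba", "distant", "absent", "adverse"),
        ]
        for drug, f, t, effect in expectations:
            res = medication_transition_test(meds, trans, canonical[drug], f, t, "others")
            assert res.effect == effect and res.pvalue < 0.05, drug

    def test_scan_produces_tidy_table(self):
        meds, trans = self._fixture(50, 15, 200, 10)
        out = medication_transition_scan(meds, trans, min_stratum=5)
        assert {"from", "to", "treatment", "effect", "p_value"} <= set(out.columns)
        assert len(out) >= 1
        adj = medication_transition_scan(meds, trans, min_stratum=5, adjust=True)
        assert "p_adjusted" in adj.columns
        assert (adj["p_adjusted"] >= adj["p_value"] - 1e-12).all()
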