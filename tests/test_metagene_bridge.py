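"""Metagene aggregation, patient clustering and signature comparison."""

import numpy as np
import pandas as pd
import pytest

from micromet.metagenes import (
    CATEGORIES,
    CATEGORY_TO_PARAM,
    aggregate_metagenes,
    cluster_patients,
    compare_signatures,
    patient_profiles,
)
from micromet.signatures import (
    extract_subpopulations,
    hcluster,
    log_normalize,
    signature_table,
)
from micromet.synthetic import generate_expression


def tiny_cohort():
    genes = ["ap1", "ap2", "ia1", "ie1", "gi1"]
    annotation = pd.DataFrame({
        "gene_id": genes,
        "category": ["antigen_presentation", "antigen_presentation",
                     "immune_apoptosis", "immune_evasion", "general_immune"],
    })
    expr = pd.DataFrame(
        [[1.0, 3.0, 2.0, 5.0, 7.0],
         [2.0, 2.0, 4.0, 1.0, 3.0]],
        index=["s1", "s2"], columns=genes)
    return expr, annotation


class TestAggregateMetagenes:
    def test_category_average(self):
        expr, annotation = tiny_cohort()
        out = aggregate_metagenes(expr, annotation)
        assert out.loc["s1", "antigen_presentation"] == pytest.approx(2.0)
        assert out.loc["s1", "immune_apoptosis"] == pytest.approx(2.0)
        assert list(out.columns) == list(CATEGORIES)

    def test_constant_expression_gives_constant_metagenes(self):
        expr, annotation = tiny_cohort()
        out = aggregate_metagenes(expr * 0 + 4.2, annotation)
        assert np.allclose(out.to_numpy(), 4.2)

    def test_matches_independent_recomputation(self):
        cohort = generate_expression(n_benefit=5, n_nonbenefit=5, seed=4)
        out = aggregate_metagenes(cohort.expression, cohort.annotation)
        mapping = cohort.annotation.set_index("gene_id")["category"]
        for category in CATEGORIES:
            genes = mapping.index[mapping == category]
            expected = cohort.expression[genes].to_numpy().mean(axis=1)
            np.testing.assert_allclose(out[category], expected)

    def test_gene_column_order_irrelevant(self):
        cohort = generate_expression(n_benefit=4, n_nonbenefit=4, seed=5)
        shuffled = cohort.expression.sample(frac=1, axis=1, random_state=0)
        a = aggregate_metagenes(cohort.expression, cohort.annotation)
        b = aggregate_metagenes(shuffled, cohort.annotation)
        pd.testing.assert_frame_equal(a, b)

    def test_unannotated_gene_rejected(self):
        expr, annotation = tiny_cohort()
        with pytest.raises(ValueError, match="unannotated"):
            aggregate_metagenes(expr.rename(columns={"ap1": "mystery"}), annotation)

    def test_empty_category_rejected(self):
        expr, annotation = tiny_cohort()
        expr = expr.drop(columns=["gi1"])
        with pytest.raises(ValueError, match="general_immune"):
            aggregate_metagenes(expr, annotation)


class TestClusterPatients:
    def test_separated_groups_recovered_exactly(self):
        cohort = generate_expression(n_benefit=6, n_nonbenefit=8,
                                     noise_sd=0.05, seed=6)
        clusters = cluster_patients(cohort.expression, annotation=cohort.annotation)
        assert set(clusters.benefit) == set(cohort.labels.index[cohort.labels == "benefit"])

    def test_duplicates_pair_before_any_cross_merge(self):
        cohort = generate_expression(n_benefit=3, n_nonbenefit=3, seed=7)
        doubled = pd.concat([cohort.expression,
                             cohort.expression.set_axis(
                                 [f"{s}_dup" for s in cohort.expression.index])])
        clusters = cluster_patients(doubled, annotation=cohort.annotation)
        heights = clusters.linkage[:, 2]
        assert np.all(heights[:len(cohort.expression)] == 0.0)

    def test_membership_invariant_under_sample_permutation(self):
        cohort = generate_expression(n_benefit=5, n_nonbenefit=7, seed=8)
        permuted = cohort.expression.sample(frac=1, random_state=3)
        a = cluster_patients(cohort.expression, annotation=cohort.annotation)
        b = cluster_patients(permuted, annotation=cohort.annotation)
        assert set(a.benefit) == set(b.benefit)

    def test_labels_override_metagene_naming(self):
        cohort = generate_expression(n_benefit=5, n_nonbenefit=5, seed=9)
        clusters = cluster_patients(cohort.expression, labels=cohort.labels)
        assert set(clusters.benefit) == set(cohort.labels.index[cohort.labels == "benefit"])

    def test_too_few_samples_rejected(self):
        expr, annotation = tiny_cohort()
        with pytest.raises(ValueError):
            cluster_patients(pd.concat([expr, expr.iloc[:1]]), annotation=annotation)

    def test_naming_requires_labels_or_annotation(self):
        cohort = generate_expression(n_benefit=4, n_nonbenefit=4, seed=10)
        with pytest.raises(ValueError):
            cluster_patients(cohort.expression)


class TestCompareSignatures:
    def profiles(self):
        idx = list(CATEGORIES)
        x_bn = pd.Series([0.0, 0.0, 0.0, 0.0], index=idx)
        x_nbn = pd.Series([-0.5, 0.5, -0.5, 0.5], index=idx)
        return x_bn, x_nbn

    def test_zero_distance_to_identical_profile(self):
        x_bn, x_nbn = self.profiles()
        insilico = pd.DataFrame([x_nbn.to_numpy()], index=["a"],
                                columns=list(CATEGORY_TO_PARAM.values()))
        result = compare_signatures(insilico, x_bn, x_nbn)
        assert result.distances.loc["a", "D_Nbn"] == pytest.approx(0.0)
        assert result.nearest("a") == "nonbenefit"

    def test_unit_distance_example(self):
        x_bn, _ = self.profiles()
        insilico = pd.DataFrame([[1.0, 0.0, 0.0, 0.0]], index=["a"])
        result = compare_signatures(insilico, x_bn, self.profiles()[1])
        assert result.distances.loc["a", "D_Bn"] == pytest.approx(1.0)

    def test_hand_computed_opposite_profiles(self):
        x = np.array([0.5, -0.5, 0.5, -0.5])
        x_nbn = pd.Series(-x, index=list(CATEGORIES))
        result = compare_signatures(pd.DataFrame([x], index=["a"]),
                                    self.profiles()[0], x_nbn)
        assert result.distances.loc["a", "D_Nbn"] == pytest.approx(2.0)

    def test_distance_symmetric_in_roles(self):
        x_bn, x_nbn = self.profiles()
        insilico = pd.DataFrame([[0.2, -0.3, 0.4, 0.1]], index=["a"])
        forward = compare_signatures(insilico, x_bn, x_nbn).distances.loc["a", "D_Bn"]
        backward = compare_signatures(pd.DataFrame([x_bn.to_numpy()], index=["a"]),
                                      pd.Series(insilico.iloc[0].to_numpy(),
                                                index=list(CATEGORIES)),
                                      x_nbn).distances.loc["a", "D_Bn"]
        assert forward == pytest.approx(backward)

    def test_dimension_mismatch_rejected(self):
        x_bn, x_nbn = self.profiles()
        with pytest.raises(ValueError):
            compare_signatures(pd.DataFrame([[0.1, 0.2]]), x_bn, x_nbn)

    def test_joint_matrix_contains_all_profiles(self):
        x_bn, x_nbn = self.profiles()
        insilico = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["a"])
        result = compare_signatures(insilico, x_bn, x_nbn)
        assert list(result.merged.index) == ["a", "Nbn", "Bn"]
        assert len(result.order) == 3


class TestEndToEnd:
    def test_resistant_signature_matches_nonbenefit_profile(self, small_screen):
        """The vaccine-resistant mean signature must be closer to the
        synthetic non-benefit cluster than to the benefit cluster when the
        generator encodes the clinical contrast."""
        block = small_screen.parameters("vaccine_resistant")
        norm = log_normalize(block)
        clusters = extract_subpopulations(norm, hcluster(norm))
        assert clusters, "expected at least one resistant subpopulation"
        means = signature_table(clusters)[list(CATEGORY_TO_PARAM.values())]

        cohort = generate_expression(noise_sd=0.25, seed=12)
        x_bn, x_nbn = patient_profiles(cohort.expression, cohort.annotation,
                                       labels=cohort.labels)
        result = compare_signatures(means, x_bn, x_nbn)
        overall = compare_signatures(
            pd.DataFrame([norm[list(CATEGORY_TO_PARAM.values())].mean()],
                         index=["resistant_mean"]), x_bn, x_nbn)
        assert (overall.distances.loc["resistant_mean", "D_Nbn"]
                < overall.distances.loc["resistant_mean", "D_Bn"])
        assert (result.distances["D_Nbn"] <= result.distances["D_Bn"]).any()
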