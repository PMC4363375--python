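"""Phenotype transform, enrichment, allele-frequency BLUE, and the score test."""

from __future__ import annotations

import numpy as np
import pytest

from founderseq.association import (
    AssociationError,
    GenotypeVector,
    PrevalenceModel,
    association_scan,
    cohort_frequency_summary,
    enrich_phenotypes,
    estimate_allele_freq_blue,
    mqls_test,
    mqls_test_many,
    penetrance_phenocopy_summary,
    transform_phenotypes,
)
from founderseq.genedrop import FounderAssignment, drop_genotypes
from founderseq.pedigree import IndividualRecord, Pedigree, kinship_matrix

from conftest import ind, random_pedigree


class TestPhenotypeTransform:
    def test_values(self):
        ped = Pedigree(
            [
                ind("a", sex="male", affection="affected"),
                ind("u", sex="male", affection="unaffected"),
                ind("x", sex="female", affection="unknown"),
            ]
        )
        t = transform_phenotypes(ped, PrevalenceModel(k_male=0.25, k_female=0.27))
        assert t["a"] == 1.0
        assert t["u"] == pytest.approx(-1 / 3)
        assert t["x"] == 0.0

    def test_sex_specific_prevalence(self):
        ped = Pedigree([ind("f", sex="female", affection="unaffected")])
        t = transform_phenotypes(ped, PrevalenceModel(k_male=0.25, k_female=0.27))
        assert t["f"] == pytest.approx(-0.27 / 0.73)

    def test_invalid_prevalence(self):
        with pytest.raises(AssociationError):
            PrevalenceModel(k_male=0.0)


class TestEnrichment:
    def test_empty_ungenotyped_is_identity(self, nuclear_family):
        km = kinship_matrix(nuclear_family)
        w = {i: 1.0 for i in nuclear_family.ids}
        A = enrich_phenotypes(w, nuclear_family.ids, [], km)
        assert np.allclose(A, 1.0)

    def test_affected_ungenotyped_full_sib(self, nuclear_family):
        # genotyped c1 with affected ungenotyped full sib c2:
        # A = T + (1/2)^-1 * (1/4) * 1 = T + 1/2
        km = kinship_matrix(nuclear_family)
        w = {"c1": 1.0, "c2": 1.0}
        A = enrich_phenotypes(w, ["c1"], ["c2"], km)
        assert A[0] == pytest.approx(1.5)

    def test_length_unchanged_by_enrichment(self):
        ped = random_pedigree(np.random.default_rng(4), 3, 3)
        km = kinship_matrix(ped)
        w = {i: (1.0 if k % 3 == 0 else -0.3) for k, i in enumerate(ped.ids)}
        genotyped = ped.ids[:-11]
        ungenotyped = ped.ids[-11:]
        base = enrich_phenotypes(w, genotyped, [], km)
        enriched = enrich_phenotypes(w, genotyped, ungenotyped, km)
        assert enriched.shape == base.shape
        assert not np.allclose(enriched, base)


class TestAlleleFrequencyBlue:
    def test_identity_structure_is_sample_mean(self):
        y = np.array([1.0, 0.5, 0.0, 0.5])
        assert estimate_allele_freq_blue(y, np.eye(4)) == pytest.approx(y.mean())

    def test_all_zero(self):
        assert estimate_allele_freq_blue(np.zeros(3), np.eye(3)) == 0.0

    def test_parent_offspring_pair(self):
        # kinship 1/4 -> K = [[1, .5], [.5, 1]]; symmetric weights -> mean
        K = np.array([[1.0, 0.5], [0.5, 1.0]])
        y = np.array([0.5, 0.0])
        assert estimate_allele_freq_blue(y, K) == pytest.approx(0.25)


class TestScoreTest:
    def test_unrelated_closed_form(self):
        """Four unrelated individuals with genotype counts (2, 1, 0, 0)."""
        y = np.array([1.0, 0.5, 0.0, 0.0])
        A = np.array([1.0, 1.0, -1 / 3, -1 / 3])
        res = mqls_test(y, A, np.eye(4))
        assert res.allele_freq_estimate == pytest.approx(0.375)
        assert res.W == pytest.approx(4.8)
        assert res.p == pytest.approx(0.0285, abs=2e-4)
        assert res.df == 1

    def test_monomorphic_untestable(self):
        res = mqls_test(np.zeros(4), np.ones(4), np.eye(4))
        assert not res.testable and res.p == 1.0 and res.W == 0.0

    def test_allele_relabelling_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.choice([0, 0.5, 1.0], size=12)
        A = rng.normal(size=12)
        K = np.eye(12)
        assert mqls_test(y, A, K).W == pytest.approx(mqls_test(1 - y, A, K).W)

    def test_no_phenotype_contrast_untestable(self):
        y = np.array([1.0, 0.5, 0.0, 0.5])
        res = mqls_test(y, np.ones(4), np.eye(4))
        assert not res.testable and res.note == "no phenotype contrast"

    def test_ordering_invariance(self):
        ped = random_pedigree(np.random.default_rng(3), 2, 3)
        km = kinship_matrix(ped)
        ids = ped.ids
        rng = np.random.default_rng(5)
        y = rng.choice([0, 0.5, 1.0], size=len(ids))
        A = rng.normal(size=len(ids))
        K = km.correlation_structure(ids)
        res = mqls_test(y, A, K)
        perm = rng.permutation(len(ids))
        res_p = mqls_test(y[perm], A[perm], K[np.ix_(perm, perm)])
        assert res_p.W == pytest.approx(res.W)

    def test_vectorized_matches_single(self):
        rng = np.random.default_rng(8)
        ped = random_pedigree(rng, 2, 3)
        K = kinship_matrix(ped).correlation_structure(ped.ids)
        n = len(ped.ids)
        A = rng.normal(size=n)
        Y = rng.choice([0, 0.5, 1.0], size=(n, 25))
        W, p, p_hat, testable = mqls_test_many(Y, A, K)
        for j in range(25):
            single = mqls_test(Y[:, j], A, K)
            assert single.W == pytest.approx(W[j])
            assert single.p == pytest.approx(p[j])


class TestScan:
    @staticmethod
    def _cohort(seed=0, n_variants=8):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng, 3, 3)
        inds = [
            IndividualRecord(
                id=i.id, father_id=i.father_id, mother_id=i.mother_id, sex=i.sex,
                affection="affected" if rng.random() < 0.3 else "unaffected",
            )
            for i in ped.individuals
        ]
        ped = Pedigree(inds)
        genotypes = {}
        for v in range(n_variants):
            counts = drop_genotypes(
                ped, FounderAssignment(mode="random_frequency", founder_freq=0.3),
                1, rng=rng,
            )
            genotypes[f"chr{v + 1}:1000"] = GenotypeVector(
                ids=ped.ids, y=np.array([counts[i][0] / 2 for i in ped.ids])
            )
        return ped, genotypes

    def test_bonferroni_threshold(self):
        ped, genotypes = self._cohort()
        scan = association_scan(genotypes, ped, PrevalenceModel())
        assert scan.n_variants == 8
        assert scan.bonferroni_threshold == pytest.approx(0.05 / 8)

    def test_single_variant_threshold(self):
        ped, genotypes = self._cohort(n_variants=1)
        scan = association_scan(genotypes, ped, PrevalenceModel())
        assert scan.bonferroni_threshold == pytest.approx(0.05)

    def test_x_linked_skipped_by_default(self):
        ped, genotypes = self._cohort(n_variants=2)
        gv = next(iter(genotypes.values()))
        genotypes["chrX:500"] = gv
        scan = association_scan(genotypes, ped, PrevalenceModel())
        assert scan.n_variants == 2
        scan_x = association_scan(genotypes, ped, PrevalenceModel(), include_x=True)
        assert scan_x.n_variants == 3
        assert any("X-linked" in r.note for r in scan_x.results)

    def test_null_scan_nominal_rate(self):
        """~5% of null variants reach p < 0.05 (phenotypes independent of genotypes)."""
        rng = np.random.default_rng(42)
        ped, _ = self._cohort(seed=42, n_variants=0)
        counts = drop_genotypes(
            ped, FounderAssignment(mode="random_frequency", founder_freq=0.3),
            100, rng=rng,
        )
        genotypes = {
            f"chr1:{j + 1}": GenotypeVector(
                ids=ped.ids, y=np.array([counts[i][j] / 2 for i in ped.ids])
            )
            for j in range(100)
        }
        scan = association_scan(genotypes, ped, PrevalenceModel())
        n_sig = sum(r.p < 0.05 for r in scan.results)
        # binomial(100, 0.05): 99.9% of draws fall within 0..15
        assert n_sig <= 15


class TestCohortSummaries:
    def test_validation_cohort_frequencies(self):
        # 111 individuals, 25 heterozygous carriers, no homozygotes
        counts = {f"i{k}": (1 if k < 25 else 0) for k in range(111)}
        summary = cohort_frequency_summary(counts, {"all": list(counts)})[0]
        assert summary.allele_freq == pytest.approx(25 / 222)
        assert round(summary.allele_freq, 3) == 0.113
        assert summary.carrier_count == 25

    def test_affected_subgroup_frequencies(self):
        counts = {f"i{k}": (1 if k < 19 else 0) for k in range(49)}
        summary = cohort_frequency_summary(counts, {"affected": list(counts)})[0]
        assert summary.allele_freq == pytest.approx(0.194, abs=5e-4)
        assert summary.freq_het == pytest.approx(0.388, abs=5e-4)

    def test_no_carriers(self):
        counts = {"a": 0, "b": 0}
        summary = cohort_frequency_summary(counts, {"g": ["a", "b"]})[0]
        assert summary.allele_freq == 0.0 and summary.carrier_count == 0

    def test_empty_subgroup_flagged(self):
        summary = cohort_frequency_summary({}, {"none": []})[0]
        assert not summary.defined and summary.n == 0

    def test_genotype_freqs_sum_to_one(self):
        counts = {f"i{k}": k % 3 for k in range(30)}
        s = cohort_frequency_summary(counts, {"all": list(counts)})[0]
        assert s.freq_hom_ref + s.freq_het + s.freq_hom_var == pytest.approx(1.0)
        assert s.allele_freq == pytest.approx((s.freq_het + 2 * s.freq_hom_var) / 2)


class TestPenetrancePhenocopy:
    def test_study_arithmetic(self):
        # 25 carriers of whom 19 affected; 49 affected of whom 19 carriers
        carrier = {f"c{k}": True for k in range(25)}
        carrier.update({f"n{k}": False for k in range(86)})
        affection = {f"c{k}": "affected" if k < 19 else "unaffected" for k in range(25)}
        affection.update(
            {f"n{k}": "affected" if k < 30 else "unaffected" for k in range(86)}
        )
        s = penetrance_phenocopy_summary(carrier, affection)
        assert s.penetrance == pytest.approx(0.76)
        assert s.phenocopy_rate == pytest.approx(30 / 49)
        assert round(s.phenocopy_rate, 2) == 0.61

    def test_all_affected_are_carriers(self):
        carrier = {"a": True, "b": True, "c": False}
        affection = {"a": "affected", "b": "affected", "c": "unaffected"}
        assert penetrance_phenocopy_summary(carrier, affection).phenocopy_rate == 0.0

    def test_undefined_flags(self):
        s = penetrance_phenocopy_summary({"a": False}, {"a": "unaffected"})
        assert s.penetrance is None and s.phenocopy_rate is None
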