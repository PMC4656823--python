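from fractions import Fraction
from math import comb, factorial

import numpy as np
import pandas as pd
import pytest

from transfermap import synth
from transfermap.core import InvalidParameterError, stage_rng
from transfermap.qc import (
    QCThresholds,
    hwe_exact_test,
    ibd_pihat,
    pairwise_pihat,
    sample_qc,
    variant_qc,
)


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of the conditional het distribution."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n - n_a
    denom = comb(2 * n, n_a)
    probs = {}
    for het in range(n_a % 2, min(n_a, n_A) + 1, 2):
        hom_a = (n_a - het) // 2
        hom_A = n - het - hom_a
        if hom_A < 0:
            continue
        num = Fraction(
            Fraction(factorial(n), factorial(hom_A) * factorial(het) * factorial(hom_a))
            * 2**het,
            denom,
        )
        probs[het] = num
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHWEExact:
    def test_one_het_free_case(self):
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)

    def test_all_het_matches_oracle(self):
        assert hwe_exact_test(0, 4, 0) == pytest.approx(hwe_oracle(0, 4, 0), abs=1e-12)

    def test_perfect_hwe_large_counts(self):
        assert hwe_exact_test(2500, 5000, 2500) > 0.99

    def test_matches_oracle_small_totals(self):
        for n_AA in range(0, 7):
            for n_Aa in range(0, 7):
                for n_aa in range(0, 7):
                    if n_AA + n_Aa + n_aa == 0:
                        continue
                    got = hwe_exact_test(n_AA, n_Aa, n_aa)
                    want = hwe_oracle(n_AA, n_Aa, n_aa)
                    assert got == pytest.approx(want, abs=1e-10), (n_AA, n_Aa, n_aa)

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidParameterError):
            hwe_exact_test(0, 0, 0)

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            hwe_exact_test(-1, 2, 3)


class TestPiHat:
    def test_self_pair_is_one(self):
        rng = stage_rng(0, "pihat")
        dm = synth.simulate_genotypes_from_freqs(rng.uniform(0.1, 0.5, 500), 10, 1)
        ph = pairwise_pihat(dm.hard_calls())
        assert np.allclose(np.diag(ph), 1.0)

    def test_symmetric(self):
        rng = stage_rng(1, "pihat")
        dm = synth.simulate_genotypes_from_freqs(rng.uniform(0.1, 0.5, 500), 10, 2)
        ph = pairwise_pihat(dm.hard_calls())
        assert np.allclose(ph, ph.T, atol=1e-5)

    def test_duplicate_pair(self):
        rng = stage_rng(2, "pihat")
        dm = synth.simulate_genotypes_from_freqs(rng.uniform(0.1, 0.5, 500), 5, 3)
        g = np.vstack([dm.hard_calls(), dm.hard_calls()[0:1]])
        assert pairwise_pihat(g)[0, -1] >= 0.95

    def test_unrelated_pairs_below_threshold(self):
        hits = 0
        for rep in range(100):
            rng = stage_rng(rep, "unrel")
            g = rng.binomial(2, rng.uniform(0.1, 0.5, 5000), size=(2, 5000)).astype(float)
            if pairwise_pihat(g)[0, 1] < 0.1:
                hits += 1
        assert hits >= 95

    def test_ibd_pihat_requires_enough_variants(self, make_dosage_matrix):
        dm = make_dosage_matrix(np.random.default_rng(0).binomial(2, 0.3, (5, 50)))
        with pytest.raises(InvalidParameterError, match="200"):
            ibd_pihat(dm, (0, 1))

    def test_ibd_pihat_duplicate(self):
        rng = stage_rng(3, "pihat")
        dm = synth.simulate_genotypes_from_freqs(rng.uniform(0.1, 0.5, 400), 3, 4)
        dm.dosages[1] = dm.dosages[0]
        assert ibd_pihat(dm, (0, 1)) >= 0.95


def _flawed_cohort(n_base, flaws, seed, m=4000):
    # marker count keeps the null PiHat sd (~0.01) far below the 0.125
    # relatedness threshold, so no clean pair ever flags
    rng = stage_rng(seed, "cohort")
    dm = synth.simulate_genotypes_from_freqs(rng.uniform(0.1, 0.5, m), n_base, seed)
    covs = synth.draw_covariates(stage_rng(seed, "cov"), n_base)
    covs.insert(0, "status", (stage_rng(seed, "status").random(n_base) < 0.5).astype(int))
    covs.insert(0, "sample_id", dm.sample_ids)
    return synth.inject_flaws(dm, covs, flaws, seed)


class TestSampleQC:
    def test_clean_cohort_identity(self):
        dm, samples, _ = _flawed_cohort(120, synth.FlawSpec(), seed=1)
        retained, report = sample_qc(dm, samples)
        assert retained == dm.sample_ids
        assert len(report.samples_excluded) == 0

    def test_planted_cascade_counts(self):
        flaws = synth.FlawSpec(n_duplicates=1, n_sex_discordant=3, n_related=5)
        dm, samples, _ = _flawed_cohort(200, flaws, seed=2)
        retained, report = sample_qc(dm, samples)
        assert report.sample_counts() == {"related": 5, "sex_discordant": 3, "duplicate": 1}
        assert len(retained) == 201 - 9

    def test_idempotent(self):
        flaws = synth.FlawSpec(n_duplicates=1, n_sex_discordant=2, n_related=3)
        dm, samples, _ = _flawed_cohort(150, flaws, seed=3)
        retained, _ = sample_qc(dm, samples)
        dm2 = dm.take_samples([sid in set(retained) for sid in dm.sample_ids])
        retained2, report2 = sample_qc(dm2, samples)
        assert retained2 == retained
        assert len(report2.samples_excluded) == 0

    def test_excluded_plus_retained_partition(self):
        flaws = synth.FlawSpec(n_duplicates=2, n_sex_discordant=2, n_related=4)
        dm, samples, _ = _flawed_cohort(150, flaws, seed=4)
        retained, report = sample_qc(dm, samples)
        excluded = set(report.samples_excluded["id"])
        assert excluded.isdisjoint(retained)
        assert excluded | set(retained) == set(dm.sample_ids)
        assert report.samples_excluded["id"].is_unique


class TestVariantQC:
    def test_missingness_excluded(self, make_dosage_matrix):
        g = np.random.default_rng(0).binomial(2, 0.3, (100, 2)).astype(float)
        g[:6, 0] = np.nan  # missingness 0.06 > 0.05
        dm = make_dosage_matrix(g)
        retained, report = variant_qc(dm)
        assert ("v0", "missingness") in list(map(tuple, report.variants_excluded.values))
        assert "v0" not in retained

    def test_imputation_r2_boundary(self, make_dosage_matrix):
        g = np.random.default_rng(1).binomial(2, 0.3, (100, 2)).astype(float)
        dm = make_dosage_matrix(g, imputed=[True, True], imp_r2=[0.29, 0.30])
        retained, _ = variant_qc(dm)
        assert "v0" not in retained  # r2 < 0.3 excluded
        assert "v1" in retained  # r2 == 0.3 retained (strict inequality)

    def test_maf_filter(self, make_dosage_matrix):
        g = np.zeros((200, 1))
        g[0, 0] = 1  # MAF 0.0025 < 0.01
        dm = make_dosage_matrix(g)
        retained, report = variant_qc(dm)
        assert retained == []
        assert "maf" in set(report.variants_excluded["reason"])

    def test_hwe_filter_genotyped_only(self, make_dosage_matrix):
        g = np.ones((300, 2))  # all heterozygous: extreme HWE violation
        dm = make_dosage_matrix(g, imputed=[False, True], imp_r2=[np.nan, 0.9])
        retained, report = variant_qc(dm)
        failed = set(report.variants_excluded.loc[
            report.variants_excluded["reason"] == "hwe", "id"])
        assert failed == {"v0"}  # imputed variant exempt from HWE

    def test_clean_identity(self):
        rng = stage_rng(5, "clean")
        dm = synth.simulate_genotypes_from_freqs(rng.uniform(0.2, 0.5, 50), 300, 6)
        retained, report = variant_qc(dm)
        assert retained == list(dm.variants["id"])
        assert len(report.variants_excluded) == 0

    def test_reasons_evaluated_jointly(self, make_dosage_matrix):
        g = np.zeros((200, 1))
        g[0, 0] = 1
        g[1:13, 0] = np.nan  # missing 0.06 AND maf below threshold
        dm = make_dosage_matrix(g)
        _, report = variant_qc(dm)
        reasons = set(report.variants_excluded["reason"])
        assert {"missingness", "maf"} <= reasons


class TestThresholds:
    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            QCThresholds(maf_min=1.5)
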