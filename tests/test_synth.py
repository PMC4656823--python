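import numpy as np
import pandas as pd
import pytest

from transfermap import synth
from transfermap.core import InvalidParameterError, stage_rng
from transfermap.qc import pairwise_pihat


def hap_dprime(x, y):
    """|D'| computed directly from realized haplotype counts (oracle)."""
    pA, pB = x.mean(), y.mean()
    pAB = np.mean(x * y)
    d = pAB - pA * pB
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    return abs(d) / dmax if dmax > 0 else np.nan


class TestSimulatePanel:
    def test_perfect_ld_single_block(self):
        panel = synth.simulate_panel(1, 8, 150, 1.0, (0.2, 0.45), seed=1)
        h = panel.haplotypes.astype(float)
        for i in range(8):
            for j in range(i + 1, 8):
                assert hap_dprime(h[:, i], h[:, j]) == pytest.approx(1.0, abs=1e-12)

    def test_cross_block_r2_matches_independence(self):
        # cross-block pairs inside one panel share the block's latent
        # score vector, so independent replicates are needed for the
        # simulation oracle: one cross pair per simulated panel
        n_hap = 100
        r2 = []
        for seed in range(1000):
            panel = synth.simulate_panel(2, 1, n_hap, 1.0, (0.2, 0.45), seed=seed)
            h = panel.haplotypes.astype(float)
            r2.append(np.corrcoef(h[:, 0], h[:, 1])[0, 1] ** 2)
        r2 = np.array(r2)
        # E[r^2] for independent sites is ~1/n_haplotypes
        sem = r2.std() / np.sqrt(len(r2))
        assert abs(r2.mean() - 1.0 / n_hap) < 3 * sem + 2e-4

    def test_same_seed_identical(self):
        a = synth.simulate_panel(3, 5, 80, 0.8, (0.1, 0.4), seed=42)
        b = synth.simulate_panel(3, 5, 80, 0.8, (0.1, 0.4), seed=42)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.positions, b.positions)
        assert a.a1 == b.a1

    def test_degenerate_maf_range_rejected(self):
        with pytest.raises(InvalidParameterError, match="degenerate"):
            synth.simulate_panel(1, 5, 50, 0.5, (0.3, 0.3), seed=0)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.simulate_panel(0, 5, 50, 0.5, (0.1, 0.4), seed=0)

    def test_positions_strictly_increasing(self):
        panel = synth.simulate_panel(4, 6, 60, 0.5, (0.1, 0.4), seed=3)
        assert np.all(np.diff(panel.positions) > 0)


class TestSimulateGenotypes:
    def test_monomorphic_column_constant(self, small_panel):
        panel = small_panel
        panel.haplotypes[:, 0] = 1  # force monomorphic
        dm = synth.simulate_genotypes(panel, 50, seed=4)
        assert np.all(dm.dosages[:, 0] == 2.0)

    def test_frequency_matches_panel(self):
        panel = synth.simulate_panel(1, 1, 2000, 0.0, (0.28, 0.32), seed=5)
        f_panel = panel.allele_freq()[0]
        dm = synth.simulate_genotypes(panel, 5000, seed=6)
        f_sample = dm.allele_freq()[0]
        se = np.sqrt(f_panel * (1 - f_panel) / (2 * 5000))
        assert abs(f_sample - f_panel) < 4 * se

    def test_single_sample(self, small_panel):
        dm = synth.simulate_genotypes(small_panel, 1, seed=7)
        assert dm.dosages.shape[0] == 1
        assert set(np.unique(dm.dosages)) <= {0.0, 1.0, 2.0}

    def test_empty_panel_rejected(self, small_panel):
        small_panel.haplotypes = small_panel.haplotypes[:0]
        with pytest.raises(InvalidParameterError):
            synth.simulate_genotypes(small_panel, 10, seed=0)

    def test_determinism(self, small_panel):
        a = synth.simulate_genotypes(small_panel, 30, seed=11)
        b = synth.simulate_genotypes(small_panel, 30, seed=11)
        assert np.array_equal(a.dosages, b.dosages)


class TestSimulatePhenotypes:
    def test_ascertainment_exact_counts(self, small_panel):
        pool = synth.simulate_genotypes(small_panel, 500, seed=1)
        cfg = synth.CohortConfig(n_cases=80, n_controls=120, seed=2)
        tab = synth.simulate_phenotypes(pool, cfg)
        assert (tab["status"] == 1).sum() == 80
        assert (tab["status"] == 0).sum() == 120

    def test_zero_cases_rejected(self):
        with pytest.raises(InvalidParameterError):
            synth.CohortConfig(n_cases=0, n_controls=10)

    def test_pool_exhaustion_advises_intercept(self, small_panel):
        pool = synth.simulate_genotypes(small_panel, 50, seed=1)
        cfg = synth.CohortConfig(n_cases=49, n_controls=49, intercept=-8.0, seed=2)
        with pytest.raises(InvalidParameterError, match="intercept"):
            synth.simulate_phenotypes(pool, cfg)

    def test_effect_recovery_moderate_n(self):
        # per-allele OR 1.5 recovered within 3 SE (small-n version; the
        # n=20,000 check lives in the acceptance suite)
        panel = synth.simulate_panel(1, 1, 2000, 0.0, (0.28, 0.32), seed=3)
        pool = synth.simulate_genotypes(panel, 16000, seed=4)
        cfg = synth.CohortConfig(
            n_cases=2000, n_controls=2000,
            causal_loci=[(0, 1.5, panel.a1[0])], intercept=-0.6, seed=5,
        )
        dm, samples = synth.ascertain(pool, synth.simulate_phenotypes(pool, cfg))
        from transfermap.assoc import logistic_dosage_fit

        res = logistic_dosage_fit(dm.dosages[:, 0], None, samples["status"].to_numpy())
        assert abs(res.beta - np.log(1.5)) < 3 * res.se


class TestImputationNoise:
    def test_r2_one_is_identity(self, small_cohort):
        dm, _ = small_cohort
        noisy = synth.apply_imputation_noise(dm, 1.0, seed=1)
        assert np.array_equal(noisy.dosages, dm.dosages)
        assert noisy.variants["imputed"].all()

    def test_realized_r2(self):
        panel = synth.simulate_panel(1, 1, 2000, 0.0, (0.28, 0.32), seed=1)
        dm = synth.simulate_genotypes(panel, 10000, seed=2)
        noisy = synth.apply_imputation_noise(dm, 0.3, seed=3)
        r = np.corrcoef(noisy.dosages[:, 0], dm.dosages[:, 0])[0, 1]
        assert r**2 == pytest.approx(0.30, abs=0.03)

    def test_constant_column_unchanged(self, make_dosage_matrix):
        dm = make_dosage_matrix(np.ones((50, 2)))
        noisy = synth.apply_imputation_noise(dm, 0.5, seed=1)
        assert np.array_equal(noisy.dosages, dm.dosages)

    def test_invalid_r2_rejected(self, small_cohort):
        dm, _ = small_cohort
        with pytest.raises(InvalidParameterError):
            synth.apply_imputation_noise(dm, 0.0, seed=1)

    def test_dosages_stay_in_range(self, small_cohort):
        dm, _ = small_cohort
        noisy = synth.apply_imputation_noise(dm, 0.5, seed=2)
        assert np.nanmin(noisy.dosages) >= 0.0
        assert np.nanmax(noisy.dosages) <= 2.0


class TestInjectFlaws:
    def test_zero_spec_identity(self, small_cohort):
        dm, samples = small_cohort
        dm2, s2, ledger = synth.inject_flaws(dm, samples, synth.FlawSpec(), seed=1)
        assert np.array_equal(dm2.dosages, dm.dosages)
        assert len(ledger) == 0
        pd.testing.assert_frame_equal(s2, samples.reset_index(drop=True))

    def test_duplicate_pihat_near_one(self):
        rng = stage_rng(1, "flaws-test")
        dm = synth.simulate_genotypes_from_freqs(rng.uniform(0.1, 0.5, 1000), 30, 2)
        covs = synth.draw_covariates(rng, 30)
        covs.insert(0, "status", 0)
        covs.insert(0, "sample_id", dm.sample_ids)
        fs = synth.FlawSpec(n_duplicates=1)
        dm2, s2, ledger = synth.inject_flaws(dm, covs, fs, seed=3)
        dup_id, src_id = ledger.iloc[0][["entity_id", "partner_id"]]
        i = dm2.sample_ids.index(src_id)
        j = dm2.sample_ids.index(dup_id)
        pihat = pairwise_pihat(dm2.hard_calls())
        assert pihat[i, j] > 0.95

    def test_planted_relatedness_hits_target(self):
        ests = []
        for rep in range(20):
            rng = stage_rng(rep, "rel-test")
            dm = synth.simulate_genotypes_from_freqs(rng.uniform(0.1, 0.5, 2000), 4, rep)
            covs = synth.draw_covariates(rng, 4)
            covs.insert(0, "status", 0)
            covs.insert(0, "sample_id", dm.sample_ids)
            fs = synth.FlawSpec(n_related=1, related_pihat=0.5)
            dm2, _, ledger = synth.inject_flaws(dm, covs, fs, seed=rep)
            vid, pid = ledger.iloc[0][["entity_id", "partner_id"]]
            i, j = dm2.sample_ids.index(vid), dm2.sample_ids.index(pid)
            ests.append(pairwise_pihat(dm2.hard_calls())[i, j])
        assert np.mean(ests) == pytest.approx(0.5, abs=0.1)

    def test_flaw_counts_exceeding_samples_rejected(self, small_cohort):
        dm, samples = small_cohort
        fs = synth.FlawSpec(n_duplicates=60, n_sex_discordant=60)
        with pytest.raises(InvalidParameterError):
            synth.inject_flaws(dm, samples, fs, seed=1)

    def test_sex_flip_recorded(self, small_cohort):
        dm, samples = small_cohort
        fs = synth.FlawSpec(n_sex_discordant=3)
        _, s2, ledger = synth.inject_flaws(dm, samples, fs, seed=4)
        flipped = ledger.loc[ledger["category"] == "sex_discordant", "entity_id"]
        assert len(flipped) == 3
        for sid in flipped:
            before = samples.loc[samples["sample_id"] == sid, "sex"].iloc[0]
            after = s2.loc[s2["sample_id"] == sid, "sex"].iloc[0]
            assert before != after

    def test_determinism(self, small_cohort):
        dm, samples = small_cohort
        fs = synth.FlawSpec(n_duplicates=1, n_sex_discordant=2, n_related=1)
        a = synth.inject_flaws(dm, samples, fs, seed=9)
        b = synth.inject_flaws(dm, samples, fs, seed=9)
        assert np.array_equal(a[0].dosages, b[0].dosages, equal_nan=True)
        pd.testing.assert_frame_equal(a[2], b[2])
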