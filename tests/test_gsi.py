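import numpy as np
import pandas as pd
import pytest

from rivergsi import baseline as bl
from rivergsi import gsi
from rivergsi.riverscape import _hwe_genotypes

from conftest import codes_matrix


def make_units(freq_rows, n=40):
    """Units with allele counts implied by exact frequencies."""
    units = []
    for k, f in enumerate(freq_rows):
        f = np.asarray(f, float)
        alt = 2 * n * f
        counts = np.stack([2 * n - alt, alt], axis=1)
        units.append(bl.BaselineUnit(f"u{k + 1}", [f"u{k + 1}"], counts, n))
    return units


def hwe_mixture(freqs, origins, rng, section="A", year=2020):
    codes = np.vstack([_hwe_genotypes(freqs[o], 1, rng) for o in origins]).astype(np.int8)
    return codes_matrix(codes, ids=[f"m{i}" for i in range(len(origins))],
                        role="mixture", section=section, year=year)


class TestPosteriorFreqs:
    def test_prior_mean_with_no_observations(self):
        u = bl.BaselineUnit("u", ["u"], np.zeros((3, 2)), 0)
        assert np.allclose(gsi.unit_posterior_freqs(u), 0.5)

    def test_closed_form_counts(self):
        counts = np.array([[0.0, 10.0]])  # ref 0, alt 10
        u = bl.BaselineUnit("u", ["u"], counts, 5)
        p = gsi.unit_posterior_freqs(u)
        assert p[0] == pytest.approx(10.5 / 11, abs=1e-15)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(20, 2)).astype(float)
        u = bl.BaselineUnit("u", ["u"], counts, 25)
        p = gsi.unit_posterior_freqs(u)
        assert np.all((p > 0) & (p < 1))  # p + (1-p) = 1 by construction


class TestGenotypeLoglik:
    def test_single_het_locus_at_half(self):
        assert gsi.genotype_loglik(np.array([1], dtype=np.int8),
                                   np.array([0.5])) == pytest.approx(np.log(0.5))

    def test_two_locus_hand_enumeration(self):
        p = np.array([0.3, 0.8])
        g = np.array([2, 1], dtype=np.int8)
        expected = np.log(0.3**2) + np.log(2 * 0.8 * 0.2)
        assert gsi.genotype_loglik(g, p) == pytest.approx(expected, abs=1e-12)

    def test_missing_locus_leaves_value_unchanged(self):
        p = np.array([0.3, 0.8, 0.6])
        g = np.array([2, 1, -1], dtype=np.int8)
        g2 = np.array([2, 1], dtype=np.int8)
        assert gsi.genotype_loglik(g, p) == gsi.genotype_loglik(g2, p[:2])

    def test_all_missing_raises(self):
        with pytest.raises(ValueError, match="all loci missing"):
            gsi.genotype_loglik(np.array([-1, -1], dtype=np.int8), np.ones(2) / 2)


class TestMixtureFit:
    def test_disjoint_units_recover_70_30(self):
        rng = np.random.default_rng(1)
        L = 10
        freqs = np.array([np.full(L, 0.001), np.full(L, 0.999)])
        units = make_units([np.zeros(L) + 1e-3, np.ones(L) - 1e-3], n=40)
        origins = rng.choice(2, size=200, p=[0.7, 0.3])
        mix = hwe_mixture(freqs, origins, rng)
        fit = gsi.fit_mixture(units, mix, seed=2)
        assert np.abs(fit.pi_posterior_mean - [0.7, 0.3]).max() < 0.05

    def test_responsibilities_sum_to_one(self, theta04_baseline):
        cfg, freqs, G, units = theta04_baseline
        rng = np.random.default_rng(3)
        mix = hwe_mixture(freqs, rng.integers(0, 8, 50), rng)
        fit = gsi.fit_mixture(units, mix, sweeps=500, burn=100, seed=4)
        rows = fit.individual_posteriors[fit.unit_ids].sum(axis=1)
        assert np.allclose(rows, 1.0, atol=1e-8)

    def test_k3_recovery_at_theta008(self):
        rng = np.random.default_rng(5)
        from rivergsi.riverscape import SimulationConfig, generate_allele_frequencies, simulate_baseline

        cfg = SimulationConfig(seed=21, n_populations=3, n_loci=266,
                               theta_fst=0.08, n_per_collection=(40, 41),
                               n_split_populations=0, n_small_collections=0,
                               sib_family_rate=0.0, missing_rate=0.0,
                               connectivity_counts=None)
        freqs = generate_allele_frequencies(cfg)
        G, _ = simulate_baseline(freqs, cfg)
        units = bl.build_units(G)
        origins = rng.choice(3, size=1000, p=[0.6, 0.3, 0.1])
        mix = hwe_mixture(freqs, origins, rng)
        fit = gsi.fit_mixture(units, mix, seed=6)
        assert np.abs(fit.pi_posterior_mean - [0.6, 0.3, 0.1]).mean() <= 0.03

    def test_seed_stability(self, theta04_baseline):
        cfg, freqs, G, units = theta04_baseline
        rng = np.random.default_rng(7)
        origins = rng.choice(8, size=300)
        mix = hwe_mixture(freqs, origins, rng)
        a = gsi.fit_mixture(units, mix, seed=1).pi_posterior_mean
        b = gsi.fit_mixture(units, mix, seed=99).pi_posterior_mean
        assert np.abs(a - b).max() < 0.02

    def test_label_equivariance(self, theta04_baseline):
        cfg, freqs, G, units = theta04_baseline
        rng = np.random.default_rng(8)
        mix = hwe_mixture(freqs, rng.integers(0, 8, 120), rng)
        fit = gsi.fit_mixture(units, mix, seed=5)
        perm = list(reversed(units))
        fit_p = gsi.fit_mixture(perm, mix, seed=5)
        a = dict(zip(fit.unit_ids, fit.pi_posterior_mean))
        b = dict(zip(fit_p.unit_ids, fit_p.pi_posterior_mean))
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=0.02)

    def test_em_fixed_point_cross_check(self):
        """An independently coded EM estimate agrees with the Gibbs mean."""
        rng = np.random.default_rng(9)
        L = 60
        f1 = rng.uniform(0.05, 0.3, L)
        f2 = rng.uniform(0.7, 0.95, L)
        freqs = np.array([f1, f2])
        units = make_units(freqs, n=50)
        origins = rng.choice(2, size=300, p=[0.65, 0.35])
        mix = hwe_mixture(freqs, origins, rng)
        fit = gsi.fit_mixture(units, mix, seed=10)
        # EM oracle on the same likelihood matrix
        codes = mix.to_codes()
        ll = gsi.loglik_matrix(codes, units)
        Lmat = np.exp(ll - ll.max(axis=1, keepdims=True))
        pi = np.array([0.5, 0.5])
        for _ in range(500):
            resp = Lmat * pi
            resp /= resp.sum(axis=1, keepdims=True)
            pi = resp.mean(axis=0)
        assert np.abs(fit.pi_posterior_mean - pi).max() < 0.02


class TestBootstrap:
    def test_fully_differentiated_correction_is_noop(self):
        rng = np.random.default_rng(11)
        L = 20
        freqs = np.array([np.full(L, 0.01), np.full(L, 0.99)])
        units = make_units(freqs, n=40)
        mix = hwe_mixture(freqs, rng.choice(2, 150, p=[0.6, 0.4]), rng)
        fit = gsi.fit_mixture(units, mix, seed=12)
        corrected = gsi.bootstrap_correct(fit, units, B=30, seed=13)
        assert np.abs(corrected - fit.pi_posterior_mean).max() < 0.01

    def test_corrected_tracks_uncorrected(self, theta04_baseline):
        cfg, freqs, G, units = theta04_baseline
        rng = np.random.default_rng(14)
        pis, cors = [], []
        mix = hwe_mixture(freqs, rng.choice(8, 400, p=rng.dirichlet(np.ones(8))), rng)
        fit = gsi.fit_mixture(units, mix, sweeps=1000, burn=300, seed=15)
        corrected = gsi.bootstrap_correct(fit, units, B=40, seed=16)
        r = np.corrcoef(fit.pi_posterior_mean, corrected)[0, 1]
        assert r >= 0.95

    def test_bias_reduction_on_confusable_units(self):
        """With two weakly separated units and skewed truth, correction moves
        the estimate toward the truth more often than not."""
        rng = np.random.default_rng(17)
        L = 40
        base = rng.uniform(0.3, 0.7, L)
        f1 = np.clip(base + 0.02, 0.02, 0.98)
        f2 = np.clip(base - 0.02, 0.02, 0.98)
        freqs = np.array([f1, f2])
        units = make_units(freqs, n=60)
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            origins = rng.choice(2, size=30, p=[0.95, 0.05])
            mix = hwe_mixture(freqs, origins, rng)
            fit = gsi.fit_mixture(units, mix, sweeps=400, burn=100, seed=rep)
            corrected = gsi.bootstrap_correct(fit, units, B=60, seed=rep + 1,
                                              sweeps=250, burn=80)
            err_raw = abs(fit.pi_posterior_mean[0] - 0.95)
            err_cor = abs(corrected[0] - 0.95)
            wins += int(err_cor <= err_raw)
        assert wins / n_rep >= 0.7


class TestZScores:
    def test_single_locus_closed_form(self):
        """One het locus at p = 0.5: log-likelihood two-point distribution
        gives z = 1 exactly."""
        u = bl.BaselineUnit("u1", ["u1"], np.zeros((1, 2)), 0)  # prior -> p = 0.5
        u2 = bl.BaselineUnit("u2", ["u2"], np.array([[1.0, 1.0]]), 1)
        mix = codes_matrix(np.array([[1]], dtype=np.int8), ids=["m0"],
                           role="mixture")
        fit = gsi.fit_mixture([u, u2], mix, sweeps=200, burn=50, seed=0)
        # pin the assignment to u1 (p = 0.5 exactly)
        fit.individual_posteriors.loc[:, "u1"] = 1.0
        fit.individual_posteriors.loc[:, "u2"] = 0.0
        z = gsi.z_scores(fit, [u, u2], mix)
        assert z["z"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_calibration_from_own_unit(self, theta04_baseline):
        cfg, freqs, G, units = theta04_baseline
        rng = np.random.default_rng(18)
        ufreqs = np.array([gsi.unit_posterior_freqs(u) for u in units])
        origins = rng.integers(0, 8, 1000)
        mix = hwe_mixture(ufreqs, origins, rng)
        fit = gsi.fit_mixture(units, mix, sweeps=600, burn=150, seed=19)
        z = gsi.z_scores(fit, units, mix)
        assert -0.1 < z["z"].mean() < 0.1
        assert 0.85 < z["z"].std() < 1.15

    def test_unsampled_population_flagged_in_excess(self, theta04_baseline):
        cfg, freqs, G, units = theta04_baseline
        rng = np.random.default_rng(20)
        # strongly drifted ghost population absent from the baseline
        from rivergsi.riverscape import drift_frequencies

        ghost = drift_frequencies(freqs[0], 0.10, rng)
        ufreqs = np.array([gsi.unit_posterior_freqs(u) for u in units])
        n_own, n_ghost = 900, 100
        codes_own = np.vstack([_hwe_genotypes(ufreqs[o], 1, rng)
                               for o in rng.integers(0, 8, n_own)])
        codes_ghost = _hwe_genotypes(ghost, n_ghost, rng)
        codes = np.vstack([codes_own, codes_ghost]).astype(np.int8)
        mix = codes_matrix(codes, ids=[f"m{i}" for i in range(len(codes))],
                           role="mixture")
        fit = gsi.fit_mixture(units, mix, sweeps=600, burn=150, seed=21)
        z = gsi.z_scores(fit, units, mix)
        ghost_flag = z["flagged_missing_source"].iloc[n_own:].mean()
        own_flag = z["flagged_missing_source"].iloc[:n_own].mean()
        # unsampled-source fish are flagged far in excess of the null rate
        assert ghost_flag > 2.5 * max(own_flag, 0.01)


class TestDispersal:
    def _net(self):
        from rivergsi.riverscape import SimulationConfig, generate_network

        cfg = SimulationConfig(seed=30, n_populations=4, n_sections=2,
                               connectivity_counts=None)
        return generate_network(cfg)

    def _fit_with_assignments(self, units, assigned, section="A"):
        n = len(assigned)
        P = pd.DataFrame(0.0, index=[f"m{i}" for i in range(n)],
                         columns=[u.unit_id for u in units])
        for i, u in enumerate(assigned):
            P.iloc[i][u] = 1.0
        return gsi.MixtureFit((section, 2020), [u.unit_id for u in units],
                              np.ones(len(units)) / len(units),
                              np.zeros((1, len(units))), P)

    def test_known_origins_match_network_distances(self):
        net = self._net()
        units = [bl.BaselineUnit(p, [p], np.zeros((2, 2)), 10,
                                 network_point=f"pop_{p}")
                 for p in ["P01", "P02"]]
        fit = self._fit_with_assignments(units, ["P01", "P02", "P01"])
        summary = gsi.dispersal_summary([fit], units, net)
        from rivergsi.spatial import watercourse_distance

        for t in summary.distances.itertuples():
            expected = watercourse_distance(net, net.section_midpoints["A"],
                                            f"pop_{t.unit}")
            assert t.distance_km == pytest.approx(expected)

    def test_threshold_one_gives_empty_summary(self):
        net = self._net()
        units = [bl.BaselineUnit("P01", ["P01"], np.zeros((2, 2)), 10,
                                 network_point="pop_P01")]
        fit = self._fit_with_assignments(units, ["P01", "P01"])
        summary = gsi.dispersal_summary([fit], units, net, prob_threshold=1.0)
        assert len(summary.distances) == 0
        assert np.isnan(summary.median_km)

    def test_zero_adjusted_contributions_simplex(self, theta04_baseline):
        cfg, freqs, G, units = theta04_baseline
        rng = np.random.default_rng(31)
        mix = hwe_mixture(freqs, rng.integers(0, 3, 60), rng)  # units 4-8 absent
        fit = gsi.fit_mixture(units, mix, sweeps=500, burn=100, seed=32)
        contrib = gsi.zero_adjusted_contributions(fit)
        assert contrib.sum() == pytest.approx(1.0)
        assert (contrib >= 0).all()
        # absent units with negligible mass are recorded as exact zeros
        assert (contrib == 0).sum() >= 1
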