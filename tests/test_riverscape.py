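import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rivergsi import baseline as bl
from rivergsi.riverscape import (
    SimulationConfig,
    generate_allele_frequencies,
    generate_covariates,
    generate_network,
    simulate_baseline,
    simulate_mixture,
    simulate_true_contributions,
    section_distance_table,
    simulate_riverscape,
    _hwe_genotypes,
)
from rivergsi.spatial import watercourse_distance
from rivergsi.zib_model import ZIBCoefficients


class TestNetwork:
    def test_single_tributary_distance_is_path_length(self):
        cfg = SimulationConfig(seed=5, n_populations=1, n_sections=1,
                               connectivity_counts={"connected": 1})
        net = generate_network(cfg)
        mouth = net.tributary_mouths["P01"]
        mid = net.section_midpoints[net.sections[0]]
        import networkx as nx

        path = nx.shortest_path(net.graph, mouth, mid)
        total = sum(net.graph[a][b]["length"] for a, b in zip(path, path[1:]))
        assert watercourse_distance(net, mouth, mid) == pytest.approx(total)

    def test_tree_invariant(self):
        for seed in (0, 1, 2):
            net = generate_network(SimulationConfig(seed=seed, n_populations=15,
                                                    n_sections=5,
                                                    connectivity_counts=None))
            g = net.graph
            assert g.number_of_edges() == g.number_of_nodes() - 1
            import networkx as nx

            assert nx.is_connected(g)

    def test_default_52_populations_6_sections(self):
        net = generate_network(SimulationConfig(seed=1))
        assert len(net.tributary_mouths) == 52
        assert len(net.sections) == 6
        assert all(net.section_midpoints[s] in net.graph for s in net.sections)


class TestCovariates:
    def test_connectivity_counts_match_study(self):
        cfg = SimulationConfig(seed=2)
        cov = generate_covariates(generate_network(cfg), cfg)
        counts = cov["C"].value_counts().to_dict()
        assert counts == {"connected": 39, "low_flow": 7,
                          "culvert_diversion": 3, "waterfall": 3}

    def test_count_mismatch_rejected(self):
        cfg = SimulationConfig(seed=2, connectivity_counts={"connected": 10})
        with pytest.raises(ValueError, match="sum to n_populations"):
            cfg.resolved_connectivity_counts()

    def test_all_connected_single_level(self):
        cfg = SimulationConfig(seed=2, n_populations=10,
                               connectivity_counts={"connected": 10})
        cov = generate_covariates(generate_network(cfg), cfg)
        assert set(cov["C"]) == {"connected"}

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=9, n_populations=10, connectivity_counts=None)
        net = generate_network(cfg)
        a = generate_covariates(net, cfg)
        b = generate_covariates(net, cfg)
        c = generate_covariates(net, cfg, seed=123)
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["G"], c["G"])


class TestAlleleFrequencies:
    def test_vanishing_theta_pins_frequencies_to_ancestral(self):
        cfg = SimulationConfig(seed=4, n_populations=20, n_loci=1000, theta_fst=1e-6)
        f = generate_allele_frequencies(cfg)
        spread = f.max(axis=0) - f.min(axis=0)
        assert spread.max() < 0.01

    def test_among_population_variance_matches_theta(self):
        cfg = SimulationConfig(seed=5, n_populations=200, n_loci=400, theta_fst=0.04)
        f = generate_allele_frequencies(cfg)
        mean = f.mean(axis=0)
        var = f.var(axis=0)
        expected = cfg.theta_fst * mean * (1 - mean)
        ratio = var.mean() / expected.mean()
        assert 0.85 < ratio < 1.15

    def test_wc_estimate_recovers_simulated_theta(self):
        ests = []
        for seed in range(3):
            cfg = SimulationConfig(seed=seed, n_populations=8, n_loci=266,
                                   n_per_collection=(50, 51), n_split_populations=0,
                                   n_small_collections=0, sib_family_rate=0.0,
                                   missing_rate=0.0, theta_fst=0.04)
            G, _ = simulate_baseline(generate_allele_frequencies(cfg), cfg)
            ests.append(bl.weir_cockerham_fst(G).global_theta)
        assert abs(np.mean(ests) - 0.04) < 0.01

    def test_realized_fst_increases_with_theta(self):
        realized = []
        for theta in (0.01, 0.04, 0.10):
            cfg = SimulationConfig(seed=7, n_populations=6, n_loci=200,
                                   n_per_collection=(40, 41), n_split_populations=0,
                                   n_small_collections=0, sib_family_rate=0.0,
                                   missing_rate=0.0, theta_fst=theta)
            G, _ = simulate_baseline(generate_allele_frequencies(cfg), cfg)
            realized.append(bl.weir_cockerham_fst(G).global_theta)
        assert realized[0] < realized[1] < realized[2]


class TestGenotypeSimulation:
    def test_hwe_heterozygosity_at_half(self):
        rng = np.random.default_rng(0)
        codes = _hwe_genotypes(np.array([0.5]), 10_000, rng)
        assert abs((codes == 1).mean() - 0.5) < 0.02

    def test_no_sib_labels_at_zero_rate(self):
        cfg = SimulationConfig(seed=1, n_populations=3, n_loci=30,
                               sib_family_rate=0.0, n_split_populations=0,
                               n_small_collections=0, connectivity_counts=None)
        _, table = simulate_baseline(generate_allele_frequencies(cfg), cfg)
        assert table.attrs["family_of"] == {}

    def test_frequency_estimate_converges(self):
        cfg = SimulationConfig(seed=2, n_populations=1, n_loci=200,
                               n_per_collection=(500, 501), n_split_populations=0,
                               n_small_collections=0, sib_family_rate=0.0,
                               missing_rate=0.0, connectivity_counts=None)
        freqs = generate_allele_frequencies(cfg)
        G, _ = simulate_baseline(freqs, cfg)
        est = G.to_codes([["1", "2"]] * cfg.n_loci).mean(axis=0) / 2
        assert np.max(np.abs(est - freqs[0])) < 0.06
        assert np.mean(np.abs(est - freqs[0])) < 0.02

    def test_sib_families_raise_relatedness(self):
        cfg = SimulationConfig(seed=3, n_populations=1, n_loci=120,
                               n_per_collection=(30, 31), sib_family_rate=0.4,
                               n_split_populations=0, n_small_collections=0,
                               missing_rate=0.0, connectivity_counts=None)
        _, table = simulate_baseline(generate_allele_frequencies(cfg), cfg)
        fams = table.attrs["family_of"]
        assert len(fams) >= 8
        assert len(set(fams.values())) >= 2


class TestContributions:
    @pytest.fixture(scope="class")
    def net_cov(self):
        cfg = SimulationConfig(seed=6, n_populations=20, n_sections=4,
                               connectivity_counts=None)
        net = generate_network(cfg)
        return cfg, net, generate_covariates(net, cfg)

    def test_intercept_only_symmetry(self, net_cov):
        cfg, net, cov = net_cov
        coef = ZIBCoefficients(
            beta_mu_distance=0, beta_mu_area=0, beta_mu_groundwater=0.0,
            beta_mu_connectivity={}, sigma_section=0.0, sigma_unit=0.0,
            beta_omega_distance=0, beta_omega_area=0, beta_omega_groundwater=0,
            beta_phi_distance=0, beta_phi_area=0, beta_phi_groundwater=0,
            beta_phi_connectivity={},
        )
        cfg2 = SimulationConfig(**{**cfg.__dict__, "lat_effect": 0.0,
                                   "region_sd": 0.0, "zib_coefficients": coef})
        df = simulate_true_contributions(cov, net, cfg2)
        for _, grp in df.groupby("s"):
            assert grp["mu"].std() < 1e-12

    def test_negative_distance_slope_gives_negative_rank_correlation(self, net_cov):
        cfg, net, cov = net_cov
        coef = ZIBCoefficients(
            beta_mu_distance=-0.8, beta_mu_area=0, beta_mu_groundwater=0.0,
            beta_mu_connectivity={}, sigma_section=0.0, sigma_unit=0.0)
        cfg2 = SimulationConfig(**{**cfg.__dict__, "lat_effect": 0.0,
                                   "region_sd": 0.0, "zib_coefficients": coef})
        df = simulate_true_contributions(cov, net, cfg2)
        for _, grp in df.groupby("s"):
            rho = stats.spearmanr(grp["D"], grp["mu"]).statistic
            assert rho < 0

    def test_study_sign_pattern_distance_area_groundwater(self, net_cov):
        # distance -, area +, groundwater + : nearby, large, groundwater-fed
        # tributaries dominate, the qualitative pattern of the real system;
        # recovered exactly from the noise-free linear predictor
        cfg, net, cov = net_cov
        coef = ZIBCoefficients(beta_mu_connectivity={}, sigma_section=0.0,
                               sigma_unit=0.0)
        cfg2 = SimulationConfig(**{**cfg.__dict__, "lat_effect": 0.0,
                                   "region_sd": 0.0, "zib_coefficients": coef})
        df = simulate_true_contributions(cov, net, cfg2)
        eta = np.log(df["mu"] / (1 - df["mu"]))
        import statsmodels.api as sm

        dfz = df.copy()
        for c in "DAG":
            dfz[c] = (df[c] - df[c].mean()) / df[c].std(ddof=0)
        X = sm.add_constant(dfz[["D", "A", "G"]])
        fitted = sm.OLS(eta, X).fit()
        assert fitted.params["D"] == pytest.approx(-0.8)
        assert fitted.params["A"] == pytest.approx(0.5)
        assert fitted.params["G"] == pytest.approx(0.3)

    def test_contributions_are_exact_simplex(self, net_cov):
        cfg, net, cov = net_cov
        df = simulate_true_contributions(cov, net, cfg)
        sums = df.groupby("s")["contribution"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestMixture:
    def test_point_mass_contributions_give_single_origin(self, small_cfg):
        cfg = SimulationConfig(**{**small_cfg.__dict__, "missing_source_fraction": 0.0})
        net = generate_network(cfg)
        cov = generate_covariates(net, cfg)
        df = section_distance_table(net, cov)
        df["contribution"] = np.where(df["r"] == "P03", 1.0, 0.0)
        freqs = generate_allele_frequencies(cfg)
        _, labels = simulate_mixture(df, freqs, cfg)
        assert set(labels["origin"]) == {"P03"}

    def test_multinomial_origin_counts_within_bounds(self):
        cfg = SimulationConfig(seed=8, n_populations=3, n_loci=20, n_sections=1,
                               n_years=1, mixture_size_per_year=1000,
                               missing_source_fraction=0.0,
                               connectivity_counts=None)
        net = generate_network(cfg)
        cov = generate_covariates(net, cfg)
        df = section_distance_table(net, cov)
        pi = {"P01": 0.6, "P02": 0.3, "P03": 0.1}
        df["contribution"] = df["r"].map(pi)
        freqs = generate_allele_frequencies(cfg)
        _, labels = simulate_mixture(df, freqs, cfg)
        counts = labels["origin"].value_counts()
        for pop, p in pi.items():
            lo, hi = stats.binom.ppf([0.005, 0.995], 1000, p)
            assert lo <= counts[pop] <= hi

    def test_default_strata_structure(self):
        cfg = SimulationConfig(seed=9, n_loci=24, mixture_size_per_year=60)
        rs = simulate_riverscape(cfg)
        strata = rs.mixture.meta.groupby(["section", "year"]).size()
        assert len(strata) == 18  # 6 sections x 3 years
        assert sorted(rs.mixture.meta["section"].unique()) == list("ABCDEF")

    def test_bit_reproducibility(self):
        cfg = SimulationConfig(seed=10, n_populations=6, n_loci=30,
                               mixture_size_per_year=60, connectivity_counts=None)
        a = simulate_riverscape(cfg)
        b = simulate_riverscape(cfg)
        assert np.array_equal(a.baseline.alleles, b.baseline.alleles)
        assert np.array_equal(a.mixture.alleles, b.mixture.alleles)
        pd.testing.assert_frame_equal(a.contributions, b.contributions)
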