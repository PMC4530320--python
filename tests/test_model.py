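import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from causalsupport import (
    CauseConfig,
    CausalSupportModel,
    ContingencyDataset,
    ModelConfig,
    ParamVector,
    PosteriorGrid,
    causal_support,
    dataset_log_likelihood,
    effect_probability,
    extract_pair_dataset,
    fit_scale_gamma,
    marginal_likelihood,
    posterior_entropy,
    posterior_mean,
    posterior_target_strength,
    scale_support,
)
from causalsupport.model import GRAPH0, GRAPH1, GRAPH2, GRAPH3, GRAPHS, log_marginal_likelihood

EMPTY = ContingencyDataset(cells=())

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestEffectProbability:
    @pytest.mark.parametrize(
        "parameterization, params, config, expected",
        [
            ("noisy_or", (0.0, 0.8, 0.0), (1, 0), 0.8),
            ("noisy_or", (0.5, 0.5, 0.0), (1, 0), 0.75),
            ("noisy_or", (0.5, 0.5, 0.5), (1, 1), 0.875),
            ("noisy_or", (0.5, 0.5, 0.5), (0, 0), 0.5),
            ("linear", (0.7, 0.7, 0.0), (1, 0), 1.0),
            ("linear", (0.2, 0.3, 0.1), (1, 1), 0.6),
        ],
    )
    def test_examples(self, parameterization, params, config, expected):
        p = effect_probability(
            CauseConfig(*config), ParamVector(*params), parameterization
        )
        assert p == pytest.approx(expected)

    def test_strengths_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ParamVector(w_B=1.2)

    @given(w_b=unit, w_c=unit, w_a=unit, c=st.integers(0, 1), a=st.integers(0, 1))
    def test_probability_in_unit_interval(self, w_b, w_c, w_a, c, a):
        for parameterization in ("noisy_or", "linear"):
            p = effect_probability(
                CauseConfig(c, a), ParamVector(w_b, w_c, w_a), parameterization
            )
            assert 0.0 <= p <= 1.0

    @given(w_b=unit, w_c=unit)
    def test_noisy_or_single_candidate_reduction(self, w_b, w_c):
        """With no alternative cause present the three-cause noisy-OR reduces to
        w_B + w_C c - w_B w_C c."""
        p = effect_probability(CauseConfig(1, 0), ParamVector(w_b, w_c, 0.77), "noisy_or")
        assert p == pytest.approx(w_b + w_c - w_b * w_c)


class TestDatasetLogLikelihood:
    def test_empty_dataset_is_zero(self):
        assert dataset_log_likelihood(EMPTY, GRAPH0, ParamVector(0.5)) == 0.0

    def test_bernoulli_value(self):
        ds = ContingencyDataset.from_counts({(0, 0): (16, 4)})
        expected = 16 * math.log(0.8) + 4 * math.log(0.2)
        assert dataset_log_likelihood(ds, GRAPH0, ParamVector(0.8)) == pytest.approx(expected)

    def test_impossible_outcome_is_minus_infinity(self):
        ds = ContingencyDataset.from_counts({(0, 0): (1, 0)})
        assert dataset_log_likelihood(ds, GRAPH0, ParamVector(0.0)) == -math.inf

    def test_absent_link_strengths_ignored(self):
        ds = ContingencyDataset.from_counts({(1, 1): (16, 4)})
        ll0 = dataset_log_likelihood(ds, GRAPH0, ParamVector(0.8, 0.0, 0.0))
        ll1 = dataset_log_likelihood(ds, GRAPH0, ParamVector(0.8, 0.9, 0.3))
        assert ll0 == ll1


class TestMarginalLikelihood:
    def test_empty_dataset_integrates_prior_to_one(self, default_config):
        for graph in GRAPHS:
            assert marginal_likelihood(EMPTY, graph, default_config) == pytest.approx(1.0)

    def test_beta_integrals(self, default_config):
        ds = ContingencyDataset.from_counts({(0, 0): (1, 1)})
        assert marginal_likelihood(ds, GRAPH0, default_config) == pytest.approx(1 / 6, abs=1e-6)
        ds = ContingencyDataset.from_counts({(0, 0): (1, 0)})
        assert marginal_likelihood(ds, GRAPH0, default_config) == pytest.approx(0.5, abs=1e-6)

    def test_target_link_marginals_match_fine_grid_oracle(self, designs, default_config):
        ds = extract_pair_dataset(designs["C_strong_I_weak"], "confounded_CD", "phase1")
        for graph in (GRAPH1, GRAPH3):
            value = marginal_likelihood(ds, graph, default_config)
            oracle = oracles.trapezoid_grid_marginal(ds, graph, 1001)
            assert value == pytest.approx(oracle, rel=1e-4)

    def test_all_scenario_marginals_match_exact_oracle(self, scenario_datasets, default_config):
        for dataset in scenario_datasets:
            for graph in GRAPHS:
                value = marginal_likelihood(dataset, graph, default_config)
                assert value == pytest.approx(
                    oracles.exact_marginal(dataset, graph), rel=1e-6
                ), (dataset.label, graph.name)

    def test_grid_refinement_converges(self, scenario_datasets):
        coarse = ModelConfig(grid_points_per_dim=101)
        fine = ModelConfig(grid_points_per_dim=201)
        for dataset in scenario_datasets[:4]:
            for graph in GRAPHS:
                a = log_marginal_likelihood(dataset, graph, coarse)
                b = log_marginal_likelihood(dataset, graph, fine)
                assert a == pytest.approx(b, abs=1e-3)

    def test_rational_oracle_agrees_with_dense_brute_force(self, designs):
        """The expansion-based grid oracle reproduces a literal mesh evaluation."""
        ds = extract_pair_dataset(designs["C_strong_I_weak"], "interacting_IJ", "phase1")
        for graph in GRAPHS:
            rational = oracles.trapezoid_grid_marginal(ds, graph, 201)
            brute = oracles.brute_force_grid_marginal(ds, graph, 201)
            assert rational == pytest.approx(brute, rel=1e-12)


class TestCausalSupport:
    def test_empty_dataset_gives_zero_support(self, default_config):
        res = causal_support(EMPTY, default_config)
        assert res.support == pytest.approx(0.0, abs=1e-9)

    def test_support_recomputable_from_log_marginals(self, designs, default_config):
        ds = extract_pair_dataset(designs["C_strong_I_weak"], "confounded_CD", "phase2", True)
        res = causal_support(ds, default_config)
        lm = res.per_graph_log_marginals
        recomputed = np.logaddexp(lm["Graph1"], lm["Graph3"]) - np.logaddexp(
            lm["Graph0"], lm["Graph2"]
        )
        assert res.support == pytest.approx(recomputed, abs=1e-9)

    def test_elemental_strong_cause_matches_oracle(self, default_config):
        ds = ContingencyDataset.from_counts({(0, 0): (0, 20), (1, 0): (16, 4)})
        res = causal_support(ds, default_config)
        expected = math.log(
            (oracles.exact_marginal(ds, GRAPH1) + oracles.exact_marginal(ds, GRAPH3))
            / (oracles.exact_marginal(ds, GRAPH0) + oracles.exact_marginal(ds, GRAPH2))
        )
        assert res.support > 5.0
        assert res.support == pytest.approx(expected, rel=1e-9)

    def test_confounded_phase1_support_near_zero(self, designs, default_config):
        """Perfect confounding leaves the existence of the target link undecided."""
        ds1 = extract_pair_dataset(designs["C_strong_I_weak"], "confounded_CD", "phase1")
        ds2 = extract_pair_dataset(
            designs["C_strong_I_weak"], "confounded_CD", "phase2", cumulative=True
        )
        s1 = causal_support(ds1, default_config).support
        s2 = causal_support(ds2, default_config).support
        assert abs(s1) < abs(s2) / 10


class TestPosteriorTargetStrength:
    def test_empty_dataset_returns_uniform_prior(self, default_config):
        post = posterior_target_strength(EMPTY, default_config)
        assert np.allclose(post.density, 1.0)

    def test_elemental_posterior_has_beta_shape(self, default_config):
        """With the background pinned near zero by many background-only trials,
        the target-strength posterior approaches Beta(k+1, n-k+1)."""
        from scipy.stats import beta

        ds = ContingencyDataset.from_counts({(0, 0): (0, 400), (1, 0): (12, 8)})
        post = posterior_target_strength(ds, default_config)
        shape = beta.pdf(post.grid, 13, 9)
        assert np.max(np.abs(post.density - shape)) < 0.05 * shape.max()

    def test_density_matches_brute_force_oracle(self, designs, default_config):
        ds = extract_pair_dataset(designs["C_strong_I_weak"], "confounded_CD", "phase2", True)
        lm = {g.name: log_marginal_likelihood(ds, g, default_config) for g in GRAPHS}
        chosen = GRAPH1 if lm["Graph1"] >= lm["Graph3"] else GRAPH3
        grid, dens = oracles.brute_force_posterior_density(ds, chosen, 501)
        post = posterior_target_strength(ds, default_config)
        interp = np.interp(post.grid, grid, dens)
        assert np.max(np.abs(post.density - interp)) < 1e-3 * dens.max()

    def test_normalization_invariant(self, scenario_datasets, default_config):
        for dataset in scenario_datasets:
            post = posterior_target_strength(dataset, default_config)
            assert post.trapezoid_integral == pytest.approx(1.0, abs=1e-6)

    def test_tied_marginals_prefer_simpler_graph_with_warning(self):
        config = ModelConfig(prior="sparse_strong")
        with pytest.warns(UserWarning, match="tied"):
            post = posterior_target_strength(EMPTY, config)
        assert post.trapezoid_integral == pytest.approx(1.0, abs=1e-6)

    def test_graph_average_mode_accounts_for_no_link_graphs(self, designs):
        config = ModelConfig(strength_mode="graph_average")
        ds = extract_pair_dataset(designs["C_strong_I_weak"], "confounded_CD", "phase1")
        post = posterior_target_strength(ds, config)
        assert post.zero_mass > 0
        assert post.trapezoid_integral + post.zero_mass == pytest.approx(1.0, abs=1e-6)
        assert posterior_mean(post) < posterior_mean(
            posterior_target_strength(ds, ModelConfig())
        )


class TestPosteriorSummaries:
    def test_uniform_mean_is_half(self):
        grid = np.linspace(0, 1, 101)
        post = PosteriorGrid(grid=grid, density=np.ones(101))
        assert posterior_mean(post) == pytest.approx(0.5)

    def test_linear_density_mean_two_thirds(self):
        grid = np.linspace(0, 1, 101)
        dens = 2 * grid
        dens = dens / np.trapezoid(dens, grid)
        assert posterior_mean(PosteriorGrid(grid=grid, density=dens)) == pytest.approx(
            2 / 3, abs=1e-4
        )

    def test_unnormalized_density_rejected(self):
        grid = np.linspace(0, 1, 101)
        post = PosteriorGrid(grid=grid, density=np.full(101, 2.0))
        with pytest.raises(ValueError, match="not normalized"):
            posterior_mean(post)

    def test_phase2_mean_matches_exact_oracle(self, designs, default_config):
        ds = extract_pair_dataset(designs["C_strong_I_weak"], "confounded_CD", "phase2", True)
        lm = {g.name: log_marginal_likelihood(ds, g, default_config) for g in GRAPHS}
        chosen = GRAPH1 if lm["Graph1"] >= lm["Graph3"] else GRAPH3
        post = posterior_target_strength(ds, default_config)
        assert posterior_mean(post) == pytest.approx(
            oracles.exact_posterior_mean(ds, chosen), abs=0.02
        )

    def test_uniform_entropy_is_exactly_zero(self):
        grid = np.linspace(0, 1, 101)
        post = PosteriorGrid(grid=grid, density=np.ones(101))
        assert posterior_entropy(post) == pytest.approx(0.0, abs=1e-12)

    def test_beta22_entropy_matches_closed_form(self):
        grid = np.linspace(0, 1, 101)
        dens = 6 * grid * (1 - grid)
        dens = dens / np.trapezoid(dens, grid)
        h = posterior_entropy(PosteriorGrid(grid=grid, density=dens))
        assert h == pytest.approx(oracles.beta_differential_entropy(2, 2), abs=1e-4)

    def test_negative_density_rejected(self):
        grid = np.linspace(0, 1, 101)
        dens = np.ones(101)
        dens[3] = -0.1
        with pytest.raises(ValueError, match="negative"):
            posterior_entropy(PosteriorGrid(grid=grid, density=dens))

    @given(
        values=st.lists(
            st.floats(min_value=0.05, max_value=5.0, allow_nan=False), min_size=31, max_size=31
        )
    )
    def test_entropy_nonpositive_for_any_density(self, values):
        grid = np.linspace(0, 1, 31)
        dens = np.asarray(values)
        dens = dens / np.trapezoid(dens, grid)
        h = posterior_entropy(PosteriorGrid(grid=grid, density=dens))
        assert h <= 1e-12

    def test_entropy_strictly_negative_for_concentrated_density(self):
        from scipy.stats import beta

        grid = np.linspace(0, 1, 101)
        dens = beta.pdf(grid, 8, 3)
        dens = dens / np.trapezoid(dens, grid)
        assert posterior_entropy(PosteriorGrid(grid=grid, density=dens)) < -0.1


class TestScaleSupport:
    def test_zero_maps_to_zero(self):
        assert scale_support(0.0, ModelConfig(scale_gamma=0.3)) == 0.0

    def test_gamma_one_is_identity(self):
        assert scale_support(-2.5, ModelConfig(scale_gamma=1.0)) == -2.5

    @given(
        s1=st.floats(min_value=-50, max_value=50, allow_nan=False),
        s2=st.floats(min_value=-50, max_value=50, allow_nan=False),
        gamma=st.floats(min_value=0.1, max_value=3.0, allow_nan=False),
    )
    def test_monotone_and_sign_preserving(self, s1, s2, gamma):
        config = ModelConfig(scale_gamma=gamma)
        if s1 < s2:
            assert scale_support(s1, config) < scale_support(s2, config)
        assert math.copysign(1, scale_support(s1, config) or 1) == math.copysign(1, s1 or 1)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError, match="scale_gamma"):
            ModelConfig(scale_gamma=0.0)

    def test_fit_scale_gamma_recovers_exponent(self):
        supports = np.array([-8.0, -2.0, -0.5, 0.5, 2.0, 8.0])
        targets = np.sign(supports) * np.abs(supports) ** 0.45
        assert fit_scale_gamma(supports, targets) == pytest.approx(0.45, abs=1e-3)


class TestModelConfig:
    def test_defaults(self):
        config = ModelConfig()
        assert config.parameterization == "noisy_or"
        assert config.prior == "uniform"
        assert config.grid_points_per_dim == 101
        assert config.strength_mode == "most_likely_graph"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"parameterization": "noisyor"},
            {"prior": "jeffreys"},
            {"grid_points_per_dim": 11},
            {"strength_mode": "map"},
            {"sparse_strong_alpha": -1.0},
        ],
    )
    def test_invalid_options_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        config = ModelConfig(parameterization="linear", grid_points_per_dim=41)
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(config.to_dict()))
        assert ModelConfig.from_yaml(path) == config


class TestModelResultsApi:
    def test_fit_is_deterministic_and_consistent(self, designs, default_config):
        model = CausalSupportModel.from_design(
            "C_strong_I_weak", "confounded_CD", "phase2", cumulative=True, config=default_config
        )
        r1, r2 = model.fit(), model.fit()
        assert r1.support == r2.support
        assert r1.strength_scaled == pytest.approx(100 * posterior_mean(r1.posterior))
        assert r1.selected_graph in ("Graph1", "Graph3")
        assert sum(r1.graph_probabilities.values()) == pytest.approx(1.0)

    def test_summary_reports_key_quantities(self, designs, default_config):
        res = CausalSupportModel.from_design(
            "C_strong_I_weak", "confounded_CD", "phase2", config=default_config
        ).fit()
        text = res.summary()
        for needle in ("causal support", "strength", "entropy", "Graph3"):
            assert needle in text

    def test_from_csv_round_trip(self, tmp_path, designs, default_config):
        from causalsupport import write_contingency_csv

        ds = extract_pair_dataset(designs["C_strong_I_weak"], "confounded_CD", "phase1")
        path = tmp_path / "ds.csv"
        write_contingency_csv(ds, path)
        res = CausalSupportModel.from_csv(path, config=default_config).fit()
        direct = CausalSupportModel(ds, config=default_config).fit()
        assert res.support == pytest.approx(direct.support)

    def test_plot_posterior_returns_axes(self, designs, default_config):
        import matplotlib

        matplotlib.use("Agg")
        res = CausalSupportModel.from_design(
            "C_strong_I_weak", "confounded_CD", "phase1", config=default_config
        ).fit()
        ax = res.plot_posterior()
        assert ax.get_xlabel().startswith("target strength")
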