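import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nitrialsim import (
    ConfigurationError,
    EffectParams,
    enumerate_scenarios,
    parse_scenario_id,
    scenario_id,
)
from nitrialsim.scenarios import Destination, Mechanism
from nitrialsim.simulate import (
    A_ALTERNATIVE,
    A_CONTROL,
    A_EXPERIMENTAL,
    adherence_status,
    counterfactual_probs,
    draw_outcomes,
    draw_population,
    received_treatment,
    simulate_trial,
)


class TestEffectParams:
    def test_defaults_give_canonical_treatment_means(self, default_params):
        # control 0.4, experimental 0.5, alternative worse than both by 0.1
        assert default_params.treatment_means() == (0.4, 0.5, 0.6)

    def test_null_effect_alternative_inferior_to_both_by_penalty(self, null_params):
        assert null_params.treatment_means() == (0.4, 0.4, 0.5)

    def test_invalid_mean_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            EffectParams(p_fail_control=0.95, true_effect=0.1)
        with pytest.raises(ConfigurationError):
            EffectParams(p_fail_control=-0.1)

    def test_beta_mean(self):
        assert EffectParams(beta_shape_a=2, beta_shape_b=6).confounder_mean == 0.25


class TestDrawPopulation:
    def test_allocation_is_balanced_and_confounders_in_unit_interval(self, default_params):
        rng = np.random.default_rng(0)
        conf, z = draw_population(1010, default_params, rng)
        se = np.sqrt(0.25 / 1010)
        assert abs(z.mean() - 0.5) < 4 * se
        assert conf.shape == (1010, 1)
        assert np.all((conf >= 0) & (conf <= 1))

    def test_allocation_independent_of_confounder(self, default_params):
        rng = np.random.default_rng(1)
        corrs = []
        for _ in range(50):
            conf, z = draw_population(400, default_params, rng)
            corrs.append(np.corrcoef(conf[:, 0], z)[0, 1])
        assert abs(np.mean(corrs)) < 4 / np.sqrt(400 * 50)

    def test_seed_determinism(self, default_params):
        a = draw_population(10, default_params, np.random.default_rng(7))
        b = draw_population(10, default_params, np.random.default_rng(7))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_too_small_population_rejected(self, default_params):
        with pytest.raises(ValueError):
            draw_population(1, default_params, np.random.default_rng(0))


class TestAdherence:
    def test_full_adherence_everywhere(self, default_params):
        rng = np.random.default_rng(0)
        conf, z = draw_population(200, default_params, rng)
        for spec in enumerate_scenarios():
            adh = adherence_status(conf, z, spec, 1.0, default_params, "threshold", rng)
            assert np.all(adh == 1)

    def test_threshold_mode_selects_extreme_confounders_exactly(self, default_params):
        # discordant: confounder lowers experimental uptake, so the highest
        # values in the experimental arm are the non-adherent ones
        spec = parse_scenario_id("exp-cross-conf-disc")
        rng = np.random.default_rng(3)
        conf, z = draw_population(400, default_params, rng)
        adh = adherence_status(conf, z, spec, 0.9, default_params, "threshold", rng)
        exp = np.flatnonzero(z == 1)
        n_arm = exp.size
        expected = int(np.ceil(0.1 * n_arm))
        nonadh = exp[adh[exp] == 0]
        assert nonadh.size == expected
        cutoff = np.sort(conf[exp, 0])[::-1][expected - 1]
        assert np.all(conf[nonadh, 0] >= cutoff)
        assert np.all(adh[z == 0] == 1)  # control arm untouched

    def test_concordant_targets_opposite_tail(self, default_params):
        spec = parse_scenario_id("exp-cross-conf-conc")
        rng = np.random.default_rng(3)
        conf, z = draw_population(400, default_params, rng)
        adh = adherence_status(conf, z, spec, 0.8, default_params, "threshold", rng)
        exp = np.flatnonzero(z == 1)
        nonadh_scores = conf[exp[adh[exp] == 0], 0]
        adh_scores = conf[exp[adh[exp] == 1], 0]
        assert nonadh_scores.max() <= adh_scores.min()

    @pytest.mark.parametrize("mode", ["threshold", "stochastic"])
    def test_nonconfounded_nonadherence_independent_of_confounder(self, default_params, mode):
        spec = parse_scenario_id("both-cross-nonconf")
        rng = np.random.default_rng(11)
        diffs = []
        for _ in range(40):
            conf, z = draw_population(500, default_params, rng)
            adh = adherence_status(conf, z, spec, 0.6, default_params, mode, rng)
            diffs.append(conf[adh == 1, 0].mean() - conf[adh == 0, 0].mean())
        assert abs(np.mean(diffs)) < 4 * np.std(diffs) / np.sqrt(len(diffs))

    def test_stochastic_calibration_within_binomial_error(self, default_params):
        spec = parse_scenario_id("both-cross-nonconf")
        rng = np.random.default_rng(5)
        conf, z = draw_population(2000, default_params, rng)
        adh = adherence_status(conf, z, spec, 0.6, default_params, "stochastic", rng)
        for arm in (0, 1):
            members = z == arm
            n_arm = members.sum()
            se = np.sqrt(0.6 * 0.4 / n_arm)
            assert abs(adh[members].mean() - 0.6) < 4 * se

    def test_stochastic_confounded_calibrated_and_monotone(self, default_params):
        spec = parse_scenario_id("both-cross-conf-disc")
        rng = np.random.default_rng(6)
        conf, z = draw_population(4000, default_params, rng)
        adh = adherence_status(conf, z, spec, 0.7, default_params, "stochastic", rng)
        for arm in (0, 1):
            members = z == arm
            se = np.sqrt(0.7 * 0.3 / members.sum())
            assert abs(adh[members].mean() - 0.7) < 4 * se
        # discordant: in the experimental arm non-adherents have higher scores
        exp = z == 1
        assert conf[exp & (adh == 0), 0].mean() > conf[exp & (adh == 1), 0].mean()

    def test_invalid_rho_rejected(self, default_params):
        spec = parse_scenario_id("both-cross-nonconf")
        conf, z = draw_population(10, default_params, np.random.default_rng(0))
        with pytest.raises(ValueError):
            adherence_status(conf, z, spec, 1.2, default_params, "threshold",
                             np.random.default_rng(0))


class TestReceivedTreatment:
    def test_adherent_receive_allocation(self):
        spec = parse_scenario_id("both-cross-nonconf")
        a = received_treatment(np.array([1, 0]), np.array([1, 1]), spec)
        assert list(a) == [A_EXPERIMENTAL, A_CONTROL]

    def test_crossover_swaps_arms(self):
        spec = parse_scenario_id("both-cross-nonconf")
        a = received_treatment(np.array([1, 0]), np.array([0, 0]), spec)
        assert list(a) == [A_CONTROL, A_EXPERIMENTAL]

    def test_alternative_destination(self):
        spec = parse_scenario_id("both-alt-nonconf")
        a = received_treatment(np.array([1, 0]), np.array([0, 0]), spec)
        assert list(a) == [A_ALTERNATIVE, A_ALTERNATIVE]


class TestCounterfactualProbs:
    def test_at_mean_confounder_probs_are_treatment_means(self, default_params):
        p0, p1, p2 = counterfactual_probs(np.full((3, 1), 0.5), default_params)
        assert np.allclose(p0, 0.4) and np.allclose(p1, 0.5) and np.allclose(p2, 0.6)

    def test_zero_slope_removes_confounding(self):
        params = EffectParams(confounder_outcome_slope=0.0)
        c = np.random.default_rng(0).random((50, 1))
        p0, _, _ = counterfactual_probs(c, params)
        assert np.allclose(p0, 0.4)

    def test_clipping_at_boundaries(self):
        params = EffectParams(confounder_outcome_slope=5.0)
        p0, p1, p2 = counterfactual_probs(np.array([[1.0]]), params)
        # 0.4 + 5 * 0.5 = 2.9, clipped
        assert p0[0] == p1[0] == p2[0] == 1.0

    def test_average_contrast_equals_true_effect_without_clipping(self):
        # slope small enough that no individual is clipped
        params = EffectParams(true_effect=0.1, confounder_outcome_slope=0.3)
        c = np.random.default_rng(1).beta(2, 2, size=(20000, 1))
        p0, p1, _ = counterfactual_probs(c, params)
        assert np.allclose(p1 - p0, 0.1)


class TestOutcomesAndTrial:
    def test_consistency_under_each_received_treatment(self, default_params):
        rng = np.random.default_rng(0)
        probs = counterfactual_probs(np.full((30, 1), 0.5), default_params)
        received = np.array([A_CONTROL, A_EXPERIMENTAL, A_ALTERNATIVE] * 10, dtype=np.int8)
        y0, y1, y2, obs = draw_outcomes(probs, received, rng)
        expect = np.where(received == A_CONTROL, y0,
                          np.where(received == A_EXPERIMENTAL, y1, y2))
        assert np.array_equal(obs, expect)

    def test_degenerate_probability_gives_constant_outcome(self, default_params):
        rng = np.random.default_rng(0)
        n = 100
        probs = (np.zeros(n), np.ones(n), np.full(n, 0.5))
        _, y1, _, _ = draw_outcomes(probs, np.full(n, A_EXPERIMENTAL, dtype=np.int8), rng)
        assert np.all(y1 == 1)

    def test_baseline_failure_rate(self, nonconf_cross, default_params):
        trial = simulate_trial(nonconf_cross, 505, 1.0, default_params, seed=4)
        se = np.sqrt(0.4 * 0.6 / trial.n)
        assert abs(trial.y_control.mean() - 0.4) < 4 * se

    def test_full_adherence_trial(self, nonconf_cross, default_params):
        trial = simulate_trial(nonconf_cross, 505, 1.0, default_params, seed=1)
        assert np.all(trial.adherent == 1)
        allocated = np.where(trial.allocation == 1, A_EXPERIMENTAL, A_CONTROL)
        assert np.array_equal(trial.received, allocated)

    def test_seed_reproducibility(self, nonconf_cross, default_params):
        a = simulate_trial(nonconf_cross, 100, 0.8, default_params, seed=42)
        b = simulate_trial(nonconf_cross, 100, 0.8, default_params, seed=42)
        assert np.array_equal(a.observed, b.observed)
        assert np.array_equal(a.confounder, b.confounder)
        assert np.array_equal(a.received, b.received)

    def test_randomization_balances_confounders_across_replicates(self, nonconf_cross,
                                                                  default_params):
        diffs = []
        for it in range(1000):
            rng = np.random.default_rng([21, it])
            conf, z = draw_population(200, default_params, rng)
            diffs.append(conf[z == 1, 0].mean() - conf[z == 0, 0].mean())
        assert abs(np.mean(diffs)) < 4 * np.std(diffs) / np.sqrt(len(diffs))

    def test_to_frame_round_trips_column_count(self, default_params):
        spec = parse_scenario_id("both-alt-conf-conc")
        params = EffectParams(n_confounders=3)
        trial = simulate_trial(spec, 20, 0.7, params, seed=0)
        df = trial.to_frame()
        assert list(df.columns) == ["id", "z", "c1", "c2", "c3", "adherent",
                                    "received", "y0", "y1", "y2", "y"]
        assert len(df) == trial.n


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    scenario_idx=st.integers(min_value=0, max_value=17),
    rho=st.floats(min_value=0.0, max_value=1.0),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
    mode=st.sampled_from(["threshold", "stochastic"]),
)
def test_trial_invariants_hold_for_any_scenario(scenario_idx, rho, seed, mode):
    """Consistency, adherence->allocated-treatment and a2-only-for-alternative
    hold on every generated trial; threshold mode calibrates exactly."""
    spec = enumerate_scenarios()[scenario_idx]
    params = EffectParams()
    trial = simulate_trial(spec, 50, rho, params, seed=seed, mode=mode)
    trial.validate()  # raises on any invariant breach
    if mode == "threshold":
        targeted = {"exp": [1], "ctrl": [0], "both": [0, 1]}[spec.nonadherent_arms.value]
        for arm in targeted:
            members = trial.allocation == arm
            n_arm = int(members.sum())
            if n_arm == 0:
                continue
            expected_nonadh = int(np.ceil((1 - rho) * n_arm - 1e-12))
            assert int((trial.adherent[members] == 0).sum()) == expected_nonadh
    untargeted = {"exp": [0], "ctrl": [1], "both": []}[spec.nonadherent_arms.value]
    for arm in untargeted:
        assert np.all(trial.adherent[trial.allocation == arm] == 1)
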