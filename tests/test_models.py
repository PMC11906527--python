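"""Model family M0-M5: elementary operations, likelihood, nesting, simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pavbias import (
    MODELS,
    TaskDesign,
    action_weight,
    go_probability,
    select_learning_rate,
    sequence_log_likelihood,
    simulate_agent,
    update_q,
)
from conftest import (
    M3_MEANS,
    brute_force_log_likelihood,
    random_inbox_params,
    random_trial_table,
)


class TestModelSpecs:
    EXPECTED_K = {"M0": 2, "M1": 3, "M2": 4, "M3": 5, "M4": 5, "M5": 6}

    @pytest.mark.parametrize("mid,k", EXPECTED_K.items())
    def test_parameter_counts(self, mid, k):
        assert MODELS[mid].k == k

    def test_m3_parameter_names(self):
        assert MODELS["M3"].free_parameters == ("alpha", "tau", "xi", "b", "pi")

    def test_out_of_box_rejected(self):
        with pytest.raises(ValueError):
            MODELS["M0"].validate({"alpha": 1.3, "tau": 5})
        with pytest.raises(ValueError):
            MODELS["M3"].validate({"alpha": 0.2, "tau": 51, "xi": 0, "b": 0, "pi": 0})


class TestUpdateQ:
    @pytest.mark.parametrize(
        "q,alpha,r,expected",
        [
            (0.0, 0.5, 1.0, 0.5),
            (0.5, 0.19, 0.0, 0.405),   # one step down at the cohort-mean rate
            (0.3, 0.0, 1.0, 0.3),
        ],
    )
    def test_single_steps(self, q, alpha, r, expected):
        assert update_q(q, r, alpha) == pytest.approx(expected, abs=1e-12)

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            update_q(0.0, 1.0, 1.5)

    @given(
        q0=st.floats(0, 1), alpha=st.floats(0, 1),
        rewards=st.lists(st.sampled_from([0.0, 1.0]), max_size=30),
    )
    @settings(max_examples=100, deadline=None)
    def test_q_stays_in_unit_interval(self, q0, alpha, rewards):
        q = q0
        for r in rewards:
            q = update_q(q, r, alpha)
            assert 0.0 <= q <= 1.0


class TestLearningRateSelection:
    P45 = {"alpha0": 0.4, "alpha1": 0.1, "tau": 5, "xi": 0.1, "b": 0.0}

    @pytest.mark.parametrize(
        "action,feedback,expected",
        [
            ("go", "immediate", 0.4),
            ("nogo", "delayed", 0.4),
            ("go", "delayed", 0.1),
            ("nogo", "immediate", 0.1),
            ("go", "none", 0.1),
            ("nogo", "none", 0.1),
        ],
    )
    def test_m4_bias_congruence(self, action, feedback, expected):
        assert select_learning_rate(action, feedback, self.P45, "M4") == expected

    def test_unbiased_models_return_alpha(self):
        p = {"alpha": 0.25, "tau": 5, "xi": 0.1, "b": 0, "pi": 0}
        for action in ("go", "nogo"):
            for fb in ("immediate", "delayed", "none"):
                assert select_learning_rate(action, fb, p, "M3") == 0.25


class TestActionWeight:
    def test_m3_go_weight_sums_biases(self):
        p = {"alpha": 0.2, "tau": 5, "xi": 0.1, "b": 0.06, "pi": 0.03}
        assert action_weight(0.2, "go", +1, p, "M3") == pytest.approx(0.29)
        assert action_weight(0.2, "go", -1, p, "M3") == pytest.approx(0.23)

    def test_nogo_weight_is_q(self):
        p = {"alpha": 0.2, "tau": 5, "xi": 0.1, "b": 0.06, "pi": 0.03}
        assert action_weight(0.7, "nogo", +1, p, "M3") == 0.7

    def test_m0_has_no_biases(self):
        assert action_weight(0.4, "go", +1, {"alpha": 0.2, "tau": 5}, "M0") == 0.4


class TestGoProbability:
    def test_symmetry(self):
        for tau in (0.0, 1.0, 50.0):
            for xi in (0.0, 0.3, 1.0):
                assert go_probability(0.4, 0.4, tau, xi) == pytest.approx(0.5)

    def test_logistic_closed_form(self):
        assert go_probability(1.0, 0.0, 1.0, 0.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-1.0)), abs=1e-12
        )

    def test_pure_noise_limit(self):
        assert go_probability(10.0, -10.0, 50.0, 1.0) == pytest.approx(0.5)

    @given(
        w_go=st.floats(-5, 5), w_nogo=st.floats(-5, 5),
        tau=st.floats(0, 50), xi=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_noise_bounds(self, w_go, w_nogo, tau, xi):
        p = go_probability(w_go, w_nogo, tau, xi)
        assert xi / 2 - 1e-12 <= p <= 1 - xi / 2 + 1e-12


class TestSequenceLikelihood:
    def test_symmetric_first_trial(self):
        rng = np.random.default_rng(0)
        table = random_trial_table(rng, 1)
        p = {"alpha": 0.3, "tau": 5, "xi": 0.0, "b": 0.0, "pi": 0.0}
        assert sequence_log_likelihood(p, "M3", table) == pytest.approx(np.log(0.5))

    @pytest.mark.parametrize("model_id", list(MODELS))
    def test_matches_brute_force_oracle(self, model_id):
        rng = np.random.default_rng(99)
        for _ in range(25):
            n = int(rng.integers(1, 7))
            table = random_trial_table(rng, n)
            params = random_inbox_params(rng, model_id)
            expected = brute_force_log_likelihood(MODELS[model_id].expand(params), table)
            got = sequence_log_likelihood(params, model_id, table)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_excluding_a_trial_removes_exactly_its_term(self):
        rng = np.random.default_rng(5)
        table = random_trial_table(rng, 12)
        params = {"alpha": 0.3, "tau": 4.0, "xi": 0.1, "b": 0.2, "pi": 0.1}
        full = sequence_log_likelihood(params, "M3", table)
        drop = table.copy()
        drop.loc[7, "excluded"] = True
        partial = sequence_log_likelihood(params, "M3", drop)
        # the dropped trial's own term, from the oracle run up to that trial
        with_term = brute_force_log_likelihood(MODELS["M3"].expand(params), table)
        without_term = brute_force_log_likelihood(MODELS["M3"].expand(params), drop)
        assert full - partial == pytest.approx(with_term - without_term, abs=1e-10)
        assert partial != pytest.approx(full)

    def test_unordered_trials_rejected(self):
        rng = np.random.default_rng(1)
        table = random_trial_table(rng, 6)
        shuffled = table.sample(frac=1, random_state=2).reset_index(drop=True)
        with pytest.raises(ValueError, match="ordered"):
            sequence_log_likelihood(M3_MEANS, "M3", shuffled)

    def test_finite_on_box_corners(self):
        rng = np.random.default_rng(3)
        table = random_trial_table(rng, 20)
        corners = [
            {"alpha": 0.0, "tau": 0.0, "xi": 0.0, "b": -3.0, "pi": 3.0},
            {"alpha": 1.0, "tau": 50.0, "xi": 0.0, "b": 3.0, "pi": -3.0},
            {"alpha": 1.0, "tau": 50.0, "xi": 1.0, "b": 3.0, "pi": 3.0},
        ]
        for p in corners:
            assert np.isfinite(sequence_log_likelihood(p, "M3", table))


class TestNesting:
    """Each model reproduces its parent exactly when the extra parameter is neutral."""

    CASES = [
        ("M5", "M3", lambda p: {**{k: v for k, v in p.items() if k != "alpha"},
                                "alpha0": p["alpha"], "alpha1": p["alpha"]}),
        ("M3", "M2", None),
        ("M2", "M1", None),
        ("M1", "M0", None),
    ]

    def test_nesting_identities(self):
        rng = np.random.default_rng(17)
        neutral = {"pi": 0.0, "b": 0.0, "xi": 0.0}
        for _ in range(10):
            table = random_trial_table(rng, int(rng.integers(3, 30)))
            for big, small, lift in self.CASES:
                small_params = random_inbox_params(rng, small)
                if lift is not None:
                    big_params = lift(small_params)
                else:
                    extra = (set(MODELS[big].free_parameters)
                             - set(MODELS[small].free_parameters)).pop()
                    big_params = {**small_params, extra: neutral[extra]}
                ll_small = sequence_log_likelihood(small_params, small, table)
                ll_big = sequence_log_likelihood(big_params, big, table)
                assert ll_big == pytest.approx(ll_small, abs=1e-12)


class TestSimulation:
    def test_seeded_determinism(self):
        a = simulate_agent(M3_MEANS, "M3", seed=4)
        b = simulate_agent(M3_MEANS, "M3", seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_structure(self, m3_agent_table, design):
        t = m3_agent_table
        assert len(t) == design.n_trials
        counts = t.groupby(["required_action", "reward_type"]).size()
        assert (counts == design.trials_per_condition).all()

    def test_pure_noise_gives_half_go(self):
        p = {"alpha": 0.2, "tau": 5.0, "xi": 1.0, "b": 0.0, "pi": 0.0}
        tables = [simulate_agent(p, "M3", seed=s) for s in range(30)]
        t = pd.concat(tables)
        rate = (t["response"] == "go").groupby(
            [t["required_action"], t["reward_type"]]).mean()
        assert np.allclose(rate, 0.5, atol=0.03)

    def test_strong_pavlovian_bias_sign(self):
        """Large positive pi raises go rates on immediate over delayed cues."""
        p = {"alpha": 0.2, "tau": 10.0, "xi": 0.1, "b": 0.0, "pi": 3.0}
        t = pd.concat(simulate_agent(p, "M3", seed=s) for s in range(40))
        go = (t["response"] == "go").astype(float)
        rates = go.groupby([t["required_action"], t["reward_type"]]).mean()
        for action in ("go", "nogo"):
            assert rates[(action, "immediate")] > rates[(action, "delayed")]

    def test_loglik_peaks_near_generating_params(self):
        """Mean log-likelihood at the truth beats +/-50% perturbations."""
        params = {"alpha": 0.3, "tau": 6.0, "xi": 0.15, "b": 0.3, "pi": 0.4}
        tables = [simulate_agent(params, "M3", seed=s) for s in range(25)]
        def mean_ll(p):
            return np.mean([sequence_log_likelihood(p, "M3", t) for t in tables])
        at_truth = mean_ll(params)
        for factor in (0.5, 1.5):
            perturbed = {k: min(max(v * factor, 0.0), 1.0) if k in ("alpha", "xi")
                         else v * factor for k, v in params.items()}
            assert at_truth > mean_ll(perturbed)
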