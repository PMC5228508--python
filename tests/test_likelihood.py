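import itertools

import numpy as np
import pytest
from scipy.special import expit

from tagtelem import Coefficients, Indicators, PriorConfig, marginal_loglik
from tagtelem.encounters import EncounterData
from tagtelem.likelihood import (PackedData, complete_data_loglik,
                                 linear_predictors, log_joint, log_prior)
from tagtelem.periods import PeriodCalendar
from tagtelem.simulate import simulate_encounters, small_design

RICH_COEF = Coefficients(surv_intercept=0.8, surv_spawn=-0.9, surv_year=0.3,
                         recap_intercept=-1.2, recap_year=-0.2,
                         move_intercept=1.1, move_spawn_season=-0.7,
                         move_year=0.1, spawn_intercept=0.4,
                         spawn_length=0.6, spawn_year=-0.3)


def brute_force_marginal(enc, coef):
    """Independent oracle: enumerate every latent configuration."""
    p = PackedData(enc)
    out = []
    for i in range(p.n):
        f, l = p.first[i], p.last[i]
        lat_pos = [t for t in range(f, l + 1) if p.x_lat_mask[i, t]]
        sub = enc.subset(fish_ids=[enc.fish_ids[i]])
        total = 0.0
        for death in range(f, l + 1):  # last period alive within the window
            z = np.zeros(p.P, dtype=np.int8)
            z[f:death + 1] = 1
            for xs in itertools.product([0, 1], repeat=len(lat_pos)):
                x = np.where(p.x_obs_mask[i], np.nan_to_num(p.x_obs[i]),
                             0).astype(np.int8)
                if any(z[t] == 0 and v == 1 for t, v in zip(lat_pos, xs)):
                    continue
                for t, v in zip(lat_pos, xs):
                    x[t] = v
                ll = complete_data_loglik(sub, coef, z[None, :], x[None, :])
                if np.isfinite(ll):
                    total += np.exp(ll)
        out.append(np.log(total))
    return np.array(out)


class TestLinearPredictors:
    def test_zero_coefficients_give_half(self):
        cov = {"L": np.zeros(3), "Y": np.zeros(3), "S": np.zeros(3),
               "x": np.zeros(3)}
        probs = linear_predictors(Coefficients(), cov)
        for v in probs.values():
            assert np.allclose(v, 0.5)

    def test_spawn_season_movement_probability(self):
        # movement intercept 2.358 with spawning-season effect -2.399
        coef = Coefficients(move_intercept=2.358, move_spawn_season=-2.399)
        cov = {"L": 0.0, "Y": 0.0, "S": 1.0, "x": 0.0}
        delta = linear_predictors(coef, cov)["delta"]
        assert delta == pytest.approx(0.49, abs=0.005)

    def test_matches_independent_sigmoid(self):
        rng = np.random.default_rng(3)
        coef = Coefficients(*rng.normal(0, 1, 11))
        cov = {k: rng.normal(size=7) for k in ("L", "Y")}
        cov["S"] = rng.integers(0, 2, 7).astype(float)
        cov["x"] = rng.integers(0, 2, 7).astype(float)
        probs = linear_predictors(coef, cov)
        expect_kappa = 1 / (1 + np.exp(-(coef.spawn_intercept
                                         + coef.spawn_length * cov["L"]
                                         + coef.spawn_year * cov["Y"])))
        assert np.allclose(probs["kappa"], expect_kappa)
        expect_phi = 1 / (1 + np.exp(-(coef.surv_intercept
                                       + coef.surv_spawn * cov["x"]
                                       + coef.surv_year * cov["Y"])))
        assert np.allclose(probs["phi"], expect_phi)


class TestLogJoint:
    def test_dead_fish_with_observation_impossible(self, tiny_encounters):
        enc, truth = tiny_encounters
        z = truth["z"].copy()
        x = truth["x"].copy()
        i = int(np.argmax(enc.m.sum(axis=1)))  # fish observed moving
        t_obs = int(np.argmax(enc.m[i]))
        z[i, t_obs] = 0
        assert log_joint(enc, RICH_COEF, Indicators(), z, x, PriorConfig()) == -np.inf

    def test_joint_is_complete_loglik_plus_prior(self, tiny_encounters):
        enc, truth = tiny_encounters
        pri = PriorConfig()
        ind = Indicators(g_surv_spawn=0, g_spawn_year=0)
        lj = log_joint(enc, RICH_COEF, ind, truth["z"], truth["x"], pri)
        ll = complete_data_loglik(enc, RICH_COEF, truth["z"], truth["x"])
        assert lj == pytest.approx(ll + log_prior(RICH_COEF, ind, pri))

    def test_empty_window_gives_prior_only(self):
        # one fish released in the final period: no modelled observations
        cal = PeriodCalendar(2008, 1)
        enc = EncounterData(
            fish_ids=np.array(["F1"], dtype=object),
            species=np.array(["BullTrout"]),
            first=np.array([3]), last=np.array([3]),
            T=np.zeros((1, 4), dtype=bool), S=np.zeros((1, 4), dtype=bool),
            y=np.zeros((1, 4), dtype=np.int8), m=np.zeros((1, 4), dtype=np.int8),
            x_obs=np.full((1, 4), np.nan),
            fork_length_mm=np.full((1, 4), 650.0),
            L=np.full((1, 4), 0.5), Y=np.zeros(4), calendar=cal)
        z = np.zeros((1, 4), dtype=np.int8)
        z[0, 3] = 1
        x = np.zeros((1, 4), dtype=np.int8)
        pri = PriorConfig()
        lj = log_joint(enc, RICH_COEF, Indicators(), z, x, pri)
        assert lj == pytest.approx(log_prior(RICH_COEF, Indicators(), pri))
        assert marginal_loglik(enc, RICH_COEF) == 0.0


class TestMarginalLikelihood:
    @pytest.mark.parametrize("seed", [5, 6, 7, 8])
    def test_equals_enumeration(self, seed):
        enc, _ = simulate_encounters(small_design(n_fish=3, n_years=1, seed=seed))
        got = marginal_loglik(enc, RICH_COEF, per_fish=True)
        want = brute_force_marginal(enc, RICH_COEF)
        assert got == pytest.approx(want, abs=1e-10)

    def test_equals_enumeration_multi_year(self):
        # two years -> eight periods clipped by taking 3 fish, short tags
        d = small_design(n_fish=2, n_years=1, seed=11,
                         coefficients=RICH_COEF)
        enc, _ = simulate_encounters(d)
        assert marginal_loglik(enc, RICH_COEF, per_fish=True) == pytest.approx(
            brute_force_marginal(enc, RICH_COEF), abs=1e-10)

    def test_outcome_probabilities_sum_to_one(self):
        # one fish, a two-period window, transmitter active in the second:
        # outcome space is {y, m} in {0,1}^2
        cal = PeriodCalendar(2008, 1)

        def make(y1, m1):
            return EncounterData(
                fish_ids=np.array(["F1"], dtype=object),
                species=np.array(["BullTrout"]),
                first=np.array([2]), last=np.array([3]),
                T=np.array([[False, False, False, True]]),
                S=np.zeros((1, 4), dtype=bool),
                y=np.array([[0, 0, 0, y1]], dtype=np.int8),
                m=np.array([[0, 0, 0, m1]], dtype=np.int8),
                x_obs=np.full((1, 4), np.nan),
                fork_length_mm=np.full((1, 4), 650.0),
                L=np.full((1, 4), 0.5), Y=np.zeros(4), calendar=cal)

        total = sum(np.exp(marginal_loglik(make(y1, m1), RICH_COEF))
                    for y1 in (0, 1) for m1 in (0, 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_exchangeability_under_fish_permutation(self):
        enc, _ = simulate_encounters(small_design(n_fish=6, n_years=2, seed=4))
        base = marginal_loglik(enc, RICH_COEF)
        perm = np.random.default_rng(0).permutation(enc.n_fish)
        shuffled = enc.subset(fish_ids=enc.fish_ids[perm])
        assert marginal_loglik(shuffled, RICH_COEF) == pytest.approx(base, abs=1e-9)

    def test_fish_observed_at_final_period_all_alive_path(self):
        # a recapture in the last period forces the all-alive trajectory
        cal = PeriodCalendar(2008, 1)
        enc = EncounterData(
            fish_ids=np.array(["F1"], dtype=object),
            species=np.array(["BullTrout"]),
            first=np.array([0]), last=np.array([3]),
            T=np.zeros((1, 4), dtype=bool), S=np.zeros((1, 4), dtype=bool),
            y=np.array([[0, 0, 0, 1]], dtype=np.int8),
            m=np.zeros((1, 4), dtype=np.int8),
            x_obs=np.full((1, 4), np.nan),
            fork_length_mm=np.full((1, 4), 650.0),
            L=np.full((1, 4), 0.5), Y=np.zeros(4), calendar=cal)
        phi = expit(RICH_COEF.surv_intercept)
        rho = expit(RICH_COEF.recap_intercept)
        want = 3 * np.log(phi) + 2 * np.log(1 - rho) + np.log(rho)
        assert marginal_loglik(enc, RICH_COEF) == pytest.approx(want, abs=1e-12)
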