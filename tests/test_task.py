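"""Task generation: episode structure, tilt statistics, evidence matching."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest, vonmises

from revinfer.inference import block_evidence, simulate_responses, ModelParams
from revinfer.task import (
    TaskConfig,
    generate_block_pair,
    generate_tilts,
    per_stimulus_evidence,
    realize_block_pair,
    realize_orientations,
    sample_episode_lengths,
    truncated_exp_rate,
)


class TestEpisodeLengths:
    def test_sum_and_bounds(self, rng):
        for n_ep, total in [(6, 72), (12, 72)]:
            lengths = sample_episode_lengths(n_ep, total, 4, 24, rng)
            assert lengths.sum() == total
            assert len(lengths) == n_ep
            assert lengths.min() >= 4 and lengths.max() <= 24

    def test_single_episode_is_forced(self, rng):
        assert sample_episode_lengths(1, 10, 4, 24, rng).tolist() == [10]

    def test_infeasible_raises(self, rng):
        with pytest.raises(ValueError):
            sample_episode_lengths(6, 200, 4, 24, rng)
        with pytest.raises(ValueError):
            sample_episode_lengths(6, 10, 4, 24, rng)

    def test_marginal_matches_composition_oracle(self, rng):
        """Conditioned on the sum, length frequencies match brute-force
        enumeration of weighted integer compositions (small case)."""
        n_ep, total, lo, hi = (3, 18, 4, 8)
        rate = truncated_exp_rate(total / n_ep, lo, hi)
        # oracle: enumerate all compositions, weight by product of
        # truncated-exponential pmfs, marginalize the first coordinate
        ks = np.arange(lo, hi + 1)
        w = np.exp(-rate * (ks - lo))
        pmf = dict(zip(ks, w / w.sum()))
        weights = {}
        for comp in itertools.product(ks, repeat=n_ep):
            if sum(comp) == total:
                weights[comp] = np.prod([pmf[c] for c in comp])
        z = sum(weights.values())
        oracle_first = np.zeros(hi - lo + 1)
        for comp, wt in weights.items():
            oracle_first[comp[0] - lo] += wt / z
        draws = np.array(
            [sample_episode_lengths(n_ep, total, lo, hi, rng)[0] for _ in range(4000)]
        )
        empirical = np.bincount(draws - lo, minlength=hi - lo + 1) / len(draws)
        assert np.max(np.abs(empirical - oracle_first)) < 0.03

    def test_rate_solves_target_mean(self):
        rate = truncated_exp_rate(6.0, 4, 24)
        ks = np.arange(4, 25, dtype=float)
        w = np.exp(-rate * (ks - 4))
        assert np.isclose(np.sum(ks * w) / np.sum(w), 6.0)


class TestTilts:
    def test_evidence_boundary_values(self):
        # a stimulus at the category mean carries maximal evidence 2*kappa;
        # one on the boundary (pi/4 away) carries none
        assert per_stimulus_evidence(np.array([0.0]), 0.5)[0] == pytest.approx(1.0)
        assert per_stimulus_evidence(np.array([np.pi / 4]), 0.5)[0] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_mean_evidence_matches_quadrature(self, rng):
        """Empirical mean per-stimulus evidence equals the von Mises
        expectation computed by numerical quadrature."""
        kappa = 0.5
        tilts = np.concatenate(generate_tilts([1000] * 100, kappa, rng))
        ev = per_stimulus_evidence(tilts, kappa)
        num = quad(
            lambda d: 2 * kappa * np.cos(2 * d) * np.exp(kappa * np.cos(2 * d)),
            -np.pi / 2,
            np.pi / 2,
        )[0]
        den = quad(lambda d: np.exp(kappa * np.cos(2 * d)), -np.pi / 2, np.pi / 2)[0]
        assert ev.mean() == pytest.approx(num / den, abs=3e-3)

    def test_doubled_tilts_are_von_mises(self, rng):
        tilts = np.concatenate(generate_tilts([2000] * 10, 0.5, rng))
        stat = kstest(2 * tilts, vonmises(0.5).cdf)
        assert stat.pvalue > 0.01

    def test_orientations_von_mises_around_drawn_mean(self, task_config, rng):
        """Realized orientations, re-centered on the drawing mean, follow
        the category distribution on doubled angles."""
        doubled = []
        for _ in range(30):
            cb, _ = generate_block_pair(task_config, "stable", rng)
            realize_orientations(cb, np.zeros(cb.n_trials, dtype=int))
            for tr in cb.trials:
                d = np.mod(tr.sequence.orientations - tr.sequence.mu_drawn, np.pi)
                doubled.append(np.mod(2 * d + np.pi, 2 * np.pi) - np.pi)
        stat = kstest(np.concatenate(doubled), vonmises(0.5).cdf)
        assert stat.pvalue > 0.01

    def test_kappa_must_be_positive(self, rng):
        with pytest.raises(ValueError):
            generate_tilts([4], 0.0, rng)


class TestEvidenceMatching:
    def test_matched_pair_shares_structure(self, block_pair):
        cb, ob = block_pair
        assert cb.condition == "Cb" and ob.condition == "Ob"
        np.testing.assert_array_equal(cb.states, ob.states)
        assert cb.initial_response == ob.initial_response
        for tc, to in zip(cb.trials, ob.trials):
            np.testing.assert_array_equal(tc.sequence.tilts, to.sequence.tilts)
            assert tc.sequence.mu_a == to.sequence.mu_a

    def test_episode_counts(self, task_config, rng):
        for vol, n_expected in [("stable", 6), ("volatile", 12)]:
            cb, _ = generate_block_pair(task_config, vol, rng)
            ids = cb.episode_ids
            assert len(np.unique(ids)) == n_expected
            lengths = np.bincount(ids)
            assert lengths.min() >= 4 and lengths.max() <= 24

    @pytest.mark.parametrize("policy_seed", [0, 1])
    def test_evidence_identical_for_any_response_policy(
        self, task_config, rng, policy_seed
    ):
        """Tilt-space evidence equals orientation-space evidence in both
        conditions, for arbitrary Ob response histories."""
        cb, ob = generate_block_pair(task_config, "volatile", rng)
        policy_rng = np.random.default_rng(policy_seed)
        responses = policy_rng.choice([1, -1], size=ob.n_trials)
        realize_orientations(cb, responses)
        realize_orientations(ob, responses)
        ev_cb, _ = block_evidence(cb)
        ev_ob, _ = block_evidence(ob)
        np.testing.assert_allclose(ev_cb, ev_ob, atol=1e-12)
        # orientation-space oracle: Cb references mu_A, Ob the previous
        # response's deck, with the +1 state pointing at category A
        kappa = task_config.kappa
        for block, name in [(cb, "Cb"), (ob, "Ob")]:
            prev = block.initial_response
            for t, trial in enumerate(block.trials):
                mu_a = trial.sequence.mu_a
                if name == "Cb":
                    ref = mu_a
                else:
                    ref = mu_a if prev == 1 else (mu_a + np.pi / 2) % np.pi
                    prev = responses[t]
                ev_orient = np.sum(
                    2 * kappa * np.cos(2 * (trial.sequence.orientations - ref))
                )
                assert ev_orient == pytest.approx(ev_cb[t], abs=1e-10)

    def test_single_trial_worked_example(self, task_config, rng):
        """State 2 with two on-mean stimuli yields evidence -2 in both
        conditions at kappa = 0.5."""
        tilts = [np.array([0.0, 0.0])]
        lengths = np.array([1])
        config = TaskConfig(trials_per_block=1, episode_min=1, episode_max=1)
        for _ in range(10):
            cb, ob = realize_block_pair(tilts, lengths, config, "stable", rng)
            if cb.trials[0].state == -1:
                ev_cb, _ = block_evidence(cb)
                ev_ob, _ = block_evidence(ob)
                assert ev_cb[0] == pytest.approx(-2.0)
                assert ev_ob[0] == pytest.approx(-2.0)
                return
        pytest.fail("state 2 never drawn in 10 attempts")
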