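import logging
import math

import numpy as np
import pandas as pd
import pytest

import spikegraph as sg
from spikegraph.cox import PartialLikelihood
from spikegraph.errors import EstimationError

KER = sg.InfluenceKernel(tau_s=0.01)


def naive_covariate(ref, t, tau):
    """Independent covariate oracle: linear scan for the last spike <= t."""
    last = None
    for s in ref:
        if s <= t:
            last = s
        else:
            break
    return 0.0 if last is None else math.exp(-(t - last) / tau)


def naive_partial_loglik(obs, refs, tau, beta):
    """Brute-force partial likelihood: explicit risk sets, no shared code path."""
    ll = 0.0
    rows = list(obs.itertuples())
    for e in rows:
        if not e.event:
            continue
        u = e.length_s
        lin = []
        for o in rows:
            if o.length_s >= u:
                z = [naive_covariate(r, o.start_s + u, tau) for r in refs]
                lin.append(sum(b * zi for b, zi in zip(beta, z)))
        z_e = [naive_covariate(r, e.start_s + u, tau) for r in refs]
        own = sum(b * zi for b, zi in zip(beta, z_e))
        m = max(lin)
        ll += own - (m + math.log(sum(math.exp(v - m) for v in lin)))
    return ll


class TestInfluenceCovariates:
    def test_exact_values(self):
        ref = np.array([1.0, 2.0])
        z = sg.influence_covariates(ref, np.array([0.5, 1.0, 1.01, 2.0]), KER)
        np.testing.assert_allclose(z, [0.0, 1.0, math.exp(-1.0), 1.0], atol=1e-12)

    def test_zero_before_first_reference_spike(self):
        z = sg.influence_covariates(np.array([5.0]), np.array([0.0, 4.999]), KER)
        np.testing.assert_array_equal(z, [0.0, 0.0])

    def test_empty_reference(self):
        z = sg.influence_covariates(np.array([]), np.array([1.0, 2.0]), KER)
        np.testing.assert_array_equal(z, [0.0, 0.0])


class TestRiskSets:
    def test_interval_decomposition(self):
        obs = sg.build_risk_sets(np.array([1.0, 2.0, 4.0]), 5.0)
        assert list(obs["length_s"]) == [1.0, 1.0, 2.0, 1.0]
        assert list(obs["event"]) == [False, True, True, False]
        assert list(obs["start_s"]) == [0.0, 1.0, 2.0, 4.0]

    def test_too_few_spikes_rejected(self):
        with pytest.raises(EstimationError, match="insufficient"):
            sg.build_risk_sets(np.array([1.0]), 5.0)

    def test_boundary_splitting_censors_spanning_isis(self):
        obs = sg.build_risk_sets(np.array([1.0, 5.0]), 6.0, split_at=np.array([3.0]))
        # the ISI [1,5) crosses the boundary at 3 and is censored there
        row = obs[(obs["start_s"] == 1.0)].iloc[0]
        assert row["length_s"] == pytest.approx(2.0)
        assert not row["event"]


class TestPartialLikelihood:
    def _sim_obs(self, seed=0, n_refs=3, duration=40.0):
        truth = sg.GroundTruthGraph(n_nodes=n_refs + 1, edges=frozenset(), weights={})
        base = sg.BaselineConfig(isi_family="poisson", target_rate_hz=6.0)
        res = sg.simulate_spike_trains(truth, base, sg.KernelConfig(), duration, seed=seed)
        obs = sg.build_risk_sets(res.spikes.spikes[0], duration)
        refs = [res.spikes.spikes[j] for j in range(1, n_refs + 1)]
        return obs, refs

    def test_value_at_zero_is_minus_sum_log_risk_sizes(self):
        obs, refs = self._sim_obs()
        value, _, _ = sg.cox_partial_loglik(obs, refs, KER, np.zeros(len(refs)))
        lengths = obs["length_s"].to_numpy()
        expected = -sum(
            math.log((lengths >= u).sum()) for u in lengths[obs["event"].to_numpy()]
        )
        assert value == pytest.approx(expected, rel=1e-12)

    def test_single_event_risk_set_of_itself_contributes_zero(self):
        obs = sg.build_risk_sets(np.array([1.0, 9.5]), 10.0)
        refs = [np.array([0.5, 3.0, 7.0])]
        for beta in ([0.0], [1.3], [-2.0]):
            value, _, _ = sg.cox_partial_loglik(obs, refs, KER, np.array(beta))
            assert value == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        obs, refs = self._sim_obs(seed=3)
        rng = np.random.default_rng(0)
        for _ in range(3):
            beta = rng.normal(0, 0.7, size=len(refs))
            value, _, _ = sg.cox_partial_loglik(obs, refs, KER, beta)
            expected = naive_partial_loglik(obs, refs, KER.tau_s, beta)
            assert value == pytest.approx(expected, rel=1e-10)

    def test_gradient_and_hessian_match_finite_differences(self):
        obs, refs = self._sim_obs(seed=1)
        pl = PartialLikelihood(obs, refs, KER)
        beta = np.array([0.4, -0.6, 0.2])
        _, grad, hess = pl.loglik(beta)
        eps = 1e-6
        for k in range(3):
            e = np.zeros(3)
            e[k] = eps
            fp, gp, _ = pl.loglik(beta + e)
            fm, gm, _ = pl.loglik(beta - e)
            assert grad[k] == pytest.approx((fp - fm) / (2 * eps), rel=1e-5, abs=1e-8)
            np.testing.assert_allclose(hess[:, k], (gp - gm) / (2 * eps), rtol=1e-4, atol=1e-7)

    def test_newton_path_is_concave_increase(self):
        """The partial likelihood increases along the Newton iterates."""
        truth = sg.GroundTruthGraph(n_nodes=2, edges=frozenset({(0, 1)}),
                                    weights={(0, 1): 1.0})
        base = sg.BaselineConfig(isi_family="poisson", target_rate_hz=8.0)
        res = sg.simulate_spike_trains(truth, base, sg.KernelConfig(), 60.0, seed=2)
        obs = sg.build_risk_sets(res.spikes.spikes[1], 60.0)
        pl = PartialLikelihood(obs, [res.spikes.spikes[0]], KER)
        f0, g, h = pl.loglik(np.zeros(1))
        beta = np.zeros(1)
        prev = f0
        for _ in range(6):
            beta = beta + np.linalg.solve(-h, g)
            f, g, h = pl.loglik(beta)
            assert f >= prev - 1e-10
            prev = f


class TestFitTarget:
    def test_recovers_planted_coupling(self):
        truth = sg.GroundTruthGraph(n_nodes=2, edges=frozenset({(0, 1)}),
                                    weights={(0, 1): 1.0})
        base = sg.BaselineConfig(isi_family="poisson", target_rate_hz=8.0)
        res = sg.simulate_spike_trains(truth, base, sg.KernelConfig(), 300.0, seed=42)
        fit = sg.fit_target(1, res.spikes, KER)
        assert fit.converged
        assert fit.ci_low[0] <= 1.0 <= fit.ci_high[0]
        assert fit.ci_low[0] > 0  # and the edge is called

    def test_zero_spike_reference_dropped_with_warning(self, caplog):
        spikes = sg.SpikeTrainSet(
            channel_ids=[0, 1, 2],
            spikes={0: np.sort(np.random.default_rng(0).uniform(0, 60, 400)),
                    1: np.sort(np.random.default_rng(1).uniform(0, 60, 400)),
                    2: np.array([])},
            duration_s=60.0,
        )
        with caplog.at_level(logging.WARNING):
            fit = sg.fit_target(0, spikes, KER)
        assert 2 in fit.dropped_refs
        assert fit.reference_ids == [1]

    def test_min_events_enforced(self):
        spikes = sg.SpikeTrainSet(
            channel_ids=[0, 1],
            spikes={0: np.array([1.0, 2.0, 3.0]), 1: np.array([0.5, 1.5])},
            duration_s=10.0,
        )
        with pytest.raises(EstimationError, match="events"):
            sg.fit_target(0, spikes, KER)

    def test_circular_shift_of_reference_destroys_the_edge(self):
        """Jittering the reference by >> tau removes its explanatory power."""
        truth = sg.GroundTruthGraph(n_nodes=2, edges=frozenset({(0, 1)}),
                                    weights={(0, 1): 1.2})
        base = sg.BaselineConfig(isi_family="poisson", target_rate_hz=8.0)
        res = sg.simulate_spike_trains(truth, base, sg.KernelConfig(), 200.0, seed=8)
        fit = sg.fit_target(1, res.spikes, KER)
        assert fit.ci_low[0] > 0
        shifted = np.sort((res.spikes.spikes[0] + 1.0) % 200.0)
        jittered = sg.SpikeTrainSet(
            channel_ids=[0, 1],
            spikes={0: shifted, 1: res.spikes.spikes[1]},
            duration_s=200.0,
        )
        fit2 = sg.fit_target(1, jittered, KER)
        assert fit2.ci_low[0] <= 0 <= fit2.ci_high[0]


class TestEstimateConnectivity:
    def _indep(self, n=4, seed=0, duration=90.0):
        truth = sg.GroundTruthGraph(n_nodes=n, edges=frozenset(), weights={})
        base = sg.BaselineConfig(isi_family="poisson", target_rate_hz=8.0)
        return sg.simulate_spike_trains(truth, base, sg.KernelConfig(), duration, seed=seed)

    def test_diagonal_is_zero_and_labels_preserved(self):
        res = self._indep()
        adj, fits = sg.estimate_connectivity(res.spikes, KER)
        assert (np.diag(adj.to_numpy()) == 0).all()
        assert list(adj.index) == res.spikes.channel_ids
        assert set(fits) == set(res.spikes.channel_ids)

    def test_bonferroni_is_no_looser_than_uncorrected(self):
        res = self._indep(seed=4)
        adj_u, _ = sg.estimate_connectivity(res.spikes, KER, correction="none")
        adj_b, _ = sg.estimate_connectivity(res.spikes, KER, correction="bonferroni")
        assert (adj_b.to_numpy() <= adj_u.to_numpy()).all()

    def test_too_few_channels_rejected(self):
        res = self._indep(n=2)
        with pytest.raises(Exception):
            sg.estimate_connectivity(res.spikes, KER)
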