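"""Tests of the Gibbs sampler, the exact enumeration oracle, the M-step
updates and the full Monte Carlo EM loop."""

import math
from dataclasses import replace

import numpy as np
import pytest

from ppibayes import (ComplexRecord, EvidenceSet, ParameterVector,
                      e_step, exact_posterior, expected_complete_ll, fit,
                      gibbs_sweep, m_step, score_posteriors, simulate_dataset)
from ppibayes.mcem import GibbsState, MCEMSchedule, SuffStats
from ppibayes.simulate import SimulationConfig

from conftest import (lit_frame, make_universe, theta_mid, tiny_instances,
                      y2h_frame)


def _single_pair_evidence():
    uni = make_universe(2)
    ev = EvidenceSet.build(uni, y2h=y2h_frame([("a", "b", "s1", 1, 1)]))
    theta = ParameterVector(rho=0.01, r=1e-9, alpha_I=0.9, alpha_S=0.0,
                            alpha_U=0.005)
    return ev, theta


def _closed_form_single_pair():
    # independent Bayes-rule evaluation of the one-replicate posterior
    p1 = 1 - (1 - 0.9) * (1 - 0.005)
    p0 = 0.005
    return 0.01 * p1 / (0.01 * p1 + 0.99 * p0)


def test_single_pair_closed_form_value():
    assert _closed_form_single_pair() == pytest.approx(0.64529, abs=5e-6)


def test_exact_posterior_matches_closed_form():
    ev, theta = _single_pair_evidence()
    post = exact_posterior(ev, theta)
    assert post.get("a", "b") == pytest.approx(_closed_form_single_pair(),
                                               abs=1e-6)


def test_gibbs_matches_closed_form():
    ev, theta = _single_pair_evidence()
    post = score_posteriors(ev, theta, n_burnin=100, n_samples=4000, seed=2)
    assert post.get("a", "b") == pytest.approx(_closed_form_single_pair(),
                                               abs=0.02)


def test_exact_posterior_no_evidence_is_prior(theta_mid):
    uni = make_universe(3)
    ev = EvidenceSet.build(uni)
    post = exact_posterior(ev, theta_mid)
    for _, s in post.items():
        assert s == pytest.approx(theta_mid.rho, abs=1e-9)


def test_exact_posterior_enumeration_cap(theta_mid):
    uni = make_universe(8)
    ev = EvidenceSet.build(uni)
    with pytest.raises(ValueError, match="enumeration cap"):
        exact_posterior(ev, theta_mid, max_vars=20)


def test_uninformative_literature_cancels(theta_mid):
    uni = make_universe(2)
    theta = replace(theta_mid, gamma1=0.3, gamma0=0.3)
    with_lit = EvidenceSet.build(uni,
                                 literature=lit_frame([("a", "b", "H", 1)]))
    without = EvidenceSet.build(uni)
    p_with = exact_posterior(with_lit, theta).get("a", "b")
    p_without = exact_posterior(without, theta).get("a", "b")
    assert p_with == pytest.approx(p_without, abs=1e-9)


def test_conclusive_literature_forces_posterior():
    uni = make_universe(2)
    theta = ParameterVector(rho=0.05, gamma1=1.0, gamma0=0.0)
    ev = EvidenceSet.build(uni, literature=lit_frame([("a", "b", "H", 1)]))
    post = score_posteriors(ev, theta, n_burnin=50, n_samples=200, seed=0)
    assert post.get("a", "b") == pytest.approx(1.0, abs=1e-6)


def test_gibbs_sweep_prior_only_pair(theta_mid):
    # with no evidence the full conditional equals the prior rho
    uni = make_universe(2)
    ev = EvidenceSet.build(uni)
    state = GibbsState.from_evidence(ev, seed=4)
    for _ in range(3000):
        gibbs_sweep(state, ev, theta_mid)
    assert state.mean_z()[0] == pytest.approx(theta_mid.rho, abs=0.03)
    assert state.sweeps == 3000
    assert (state.z_sums <= state.sweeps).all()


def test_e_step_determinism_and_support(theta_mid):
    ev, theta = _single_pair_evidence()
    s1 = e_step(ev, theta, n_burnin=20, n_samples=30, seed=9)
    s2 = e_step(ev, theta, n_burnin=20, n_samples=30, seed=9)
    assert np.array_equal(s1.zbar, s2.zbar)
    assert np.array_equal(s1.ypos_tab, s2.ypos_tab)
    single = e_step(ev, theta, n_burnin=200, n_samples=1, seed=1)
    assert single.zbar[0] in (0.0, 1.0)


def test_e_step_mean_matches_exact(theta_mid):
    ev, theta = _single_pair_evidence()
    stats = e_step(ev, theta, n_burnin=100, n_samples=2000, seed=3)
    assert stats.zbar[0] == pytest.approx(_closed_form_single_pair(),
                                          abs=0.03)


def test_monotone_information(theta_mid):
    """A concordant evidence source moves a true pair's posterior up."""
    uni = make_universe(2)
    base = EvidenceSet.build(uni, y2h=y2h_frame([("a", "b", "s1", 1, 1)]))
    more = EvidenceSet.build(uni, y2h=y2h_frame([("a", "b", "s1", 1, 1)]),
                             literature=lit_frame([("a", "b", "H", 1)]))
    p_base = exact_posterior(base, theta_mid).get("a", "b")
    p_more = exact_posterior(more, theta_mid).get("a", "b")
    assert p_more > p_base


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def _stats(**kw):
    defaults = dict(n_sweeps=10, zbar=np.array([0.5]), xbar=np.array([0.0]),
                    ypos_tab=np.zeros((2, 3)), ytot_tab=np.zeros((2, 3)),
                    mpc=np.zeros(4), lit_h=np.zeros(4), lit_l=np.zeros(4),
                    tz=np.zeros((2, 2)), tx=np.zeros((2, 2)))
    defaults.update(kw)
    return SuffStats(**defaults)


def test_m_step_rho_is_mean_density():
    stats = _stats(zbar=np.array([0.1, 0.3, 0.2]))
    theta = m_step(stats, ParameterVector())
    assert theta.rho == pytest.approx(0.2)


def test_m_step_degenerate_rate_clipped():
    # all sampled z = 1 and every report positive: gamma1 -> 1, clipped
    stats = _stats(lit_h=np.array([5.0, 5.0, 0.0, 0.0]))
    theta = m_step(stats, ParameterVector())
    assert theta.gamma1 == pytest.approx(1.0 - 1e-6)


def test_m_step_keeps_unsupported_components():
    old = ParameterVector(psi1=0.62, beta1=0.44, beta0=0.11)
    theta = m_step(_stats(), old)
    assert theta.psi1 == pytest.approx(0.62)
    assert theta.beta1 == pytest.approx(0.44)


def test_m_step_rejects_infeasible_stats():
    with pytest.raises(ValueError):
        m_step(_stats(zbar=np.array([1.7])), ParameterVector())
    with pytest.raises(ValueError):
        m_step(_stats(ypos_tab=np.full((2, 3), 5.0)), ParameterVector())


def test_m_step_enforces_rate_ordering():
    stats = _stats(lit_h=np.array([10.0, 2.0, 10.0, 9.0]))  # g1=0.2 < g0=0.9
    theta = m_step(stats, ParameterVector())
    assert theta.gamma1 > theta.gamma0


def test_m_step_is_q_ascent(theta_mid):
    """One M-step from the generating parameters cannot decrease the
    Monte Carlo Q-function."""
    sim = simulate_dataset(SimulationConfig(
        n_proteins=40, theta_true=theta_mid, n_baits=8, seed=6))
    stats = e_step(sim.evidence, theta_mid, n_burnin=30, n_samples=100,
                   seed=8)
    theta_new = m_step(stats, theta_mid)
    assert expected_complete_ll(stats, theta_new) >= \
        expected_complete_ll(stats, theta_mid) - 1e-6


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

def test_fit_zero_iterations_returns_init(theta_mid):
    ev, theta = _single_pair_evidence()
    res = fit(ev, theta_init=theta, max_iter=0, seed=1,
              schedule=MCEMSchedule(burnin=5, score_burnin=20,
                                    score_samples=100))
    assert not res.converged
    assert res.theta_hat.to_dict() == theta.clipped().to_dict()


def test_fit_determinism(theta_mid):
    sim = simulate_dataset(SimulationConfig(
        n_proteins=25, theta_true=theta_mid, n_baits=5, seed=12))
    sched = MCEMSchedule(burnin=10, base=30, step=10, score_burnin=10,
                         score_samples=50)
    r1 = fit(sim.evidence, schedule=sched, max_iter=3, seed=42)
    r2 = fit(sim.evidence, schedule=sched, max_iter=3, seed=42)
    assert r1.theta_hat.to_dict() == r2.theta_hat.to_dict()
    assert r1.posterior.scores == r2.posterior.scores
    assert r1.diff_trace == r2.diff_trace


def test_fit_rejects_overrides(theta_mid):
    ev, theta = _single_pair_evidence()
    bad = replace(theta, overrides={"s1": {"alpha_U": 0.2}})
    with pytest.raises(ValueError, match="overrides"):
        fit(ev, theta_init=bad, max_iter=1, seed=0)


def test_chain_invariance_across_seeds(theta_mid):
    """Two independent chains agree within Monte Carlo error."""
    sim = tiny_instances(theta_mid, 1, start_seed=40)[0]
    n = 3000
    p1 = score_posteriors(sim.evidence, theta_mid, n_burnin=100,
                          n_samples=n, seed=1)
    p2 = score_posteriors(sim.evidence, theta_mid, n_burnin=100,
                          n_samples=n, seed=2)
    for pair, s in p1.items():
        se = math.sqrt(max(s * (1 - s), 1e-4) / n)
        # generous allowance for autocorrelation in the chains
        assert abs(s - p2.scores[pair]) < 6 * se + 0.01


def test_gibbs_agrees_with_exact_on_random_instances(theta_mid):
    """Sampler vs brute-force enumeration on small full-evidence instances
    (the acceptance suite runs the larger version of this check)."""
    sims = tiny_instances(theta_mid, 5, start_seed=60)
    errs = []
    for k, sim in enumerate(sims):
        ex = exact_posterior(sim.evidence, theta_mid)
        gb = score_posteriors(sim.evidence, theta_mid, n_burnin=200,
                              n_samples=2000, seed=100 + k)
        errs.append(np.mean([abs(ex.scores[p] - gb.scores[p])
                             for p in ex.scores]))
    assert np.mean(errs) <= 0.05
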