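"""Unit and property tests for the per-source probability models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppibayes import (ComplexRecord, EvidenceSet, LatentState,
                      ParameterVector, complete_log_likelihood,
                      complex_log_likelihood, joint_identity,
                      literature_log_prob, prior_log_prob, transfer_prob,
                      y2h_response_prob)
from ppibayes.likelihood import transfer_links
from ppibayes.types import EvidenceError

from conftest import lit_frame, make_universe, y2h_frame


# ---------------------------------------------------------------------------
# Y2H response model
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("z,xi,xj,theta_kw,expected", [
    (0, 0, 0, dict(alpha_I=0.9, alpha_S=0.3, alpha_U=0.007), 0.007),
    (1, 0, 0, dict(alpha_I=0.933, alpha_S=0.3, alpha_U=0.007),
     1.0 - 0.067 * 0.993),
    (1, 1, 1, dict(alpha_I=0.0, alpha_S=0.0, alpha_U=0.0), 0.0),
])
def test_y2h_response_examples(z, xi, xj, theta_kw, expected):
    theta = ParameterVector(**theta_kw)
    assert y2h_response_prob(z, xi, xj, theta) == pytest.approx(expected,
                                                                abs=1e-9)


def test_y2h_self_activation_exponent_vs_indicator():
    theta = ParameterVector(alpha_I=0.5, alpha_S=0.4, alpha_U=0.01)
    # exponent mode multiplies (1-alpha_S) once per self-activating partner
    p_exp = y2h_response_prob(0, 1, 1, theta, "exponent")
    p_ind = y2h_response_prob(0, 1, 1, theta, "indicator")
    assert p_exp == pytest.approx(1.0 - 0.6 ** 2 * 0.99)
    assert p_ind == pytest.approx(1.0 - 0.6 * 0.99)
    assert y2h_response_prob(0, 1, 0, theta, "exponent") == \
        pytest.approx(p_ind)
    with pytest.raises(ValueError):
        y2h_response_prob(0, 0, 0, theta, "bogus")


def test_y2h_uninformative_limit():
    # with alpha_I = alpha_S = 0 the response no longer depends on z or x
    theta = ParameterVector(alpha_I=0.0, alpha_S=0.0, alpha_U=0.03)
    vals = [y2h_response_prob(z, xi, xj, theta)
            for z in (0, 1) for xi in (0, 1) for xj in (0, 1)]
    assert vals == pytest.approx([0.03] * 8)


@given(z=st.integers(0, 1), xi=st.integers(0, 1), xj=st.integers(0, 1),
       ai=st.floats(0, 1), as_=st.floats(0, 1), au=st.floats(0, 1))
@settings(max_examples=50, deadline=None)
def test_y2h_response_is_probability(z, xi, xj, ai, as_, au):
    theta = ParameterVector(alpha_I=ai, alpha_S=as_, alpha_U=au)
    p = y2h_response_prob(z, xi, xj, theta)
    assert 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# complex capture model
# ---------------------------------------------------------------------------

def _state_with_edges(universe, edges):
    state = LatentState.zeros(universe)
    for a, b in edges:
        key = (a, b) if a < b else (b, a)
        state.z[key] = 1
    return state


def test_complex_log_likelihood_examples():
    uni = make_universe(4)  # a=bait, b,c 1-step, d 2-step via b
    state = _state_with_edges(uni, [("a", "b"), ("a", "c"), ("b", "d")])
    theta = ParameterVector(psi1=0.8, psi2=0.6)
    # n1={b,c}, n2={d}; observed {b,d}: hit b, miss c, hit d
    ll = complex_log_likelihood("a", {"b", "d"}, state, theta)
    assert ll == pytest.approx(math.log(0.8 * 0.2 * 0.6))
    # full capture: no miss factors
    ll = complex_log_likelihood("a", {"b", "c", "d"}, state, theta)
    assert ll == pytest.approx(2 * math.log(0.8) + math.log(0.6))


def test_complex_single_miss_table_value():
    uni = make_universe(2)
    state = _state_with_edges(uni, [("a", "b")])
    theta = ParameterVector(psi1=0.809)
    ll = complex_log_likelihood("a", set(), state, theta)
    assert ll == pytest.approx(math.log(1.0 - 0.809))


def test_complex_distant_member_uses_background_rate():
    uni = make_universe(4)
    state = _state_with_edges(uni, [("a", "b")])  # c, d unreachable
    theta = ParameterVector(psi1=0.8, psi_bg=1e-3)
    ll = complex_log_likelihood("a", {"b", "c"}, state, theta)
    assert ll == pytest.approx(math.log(0.8) + math.log(1e-3))


def test_complex_unknown_bait_errors():
    uni = make_universe(3)
    state = LatentState.zeros(uni)
    with pytest.raises(EvidenceError):
        complex_log_likelihood("zz", set(), state, ParameterVector())


def test_complex_invariant_to_remote_edges():
    # edits to Z that leave the bait's 1-/2-step neighbourhoods unchanged
    # cannot change the complex likelihood
    uni = make_universe(6)
    base = [("a", "b"), ("b", "c")]
    theta = ParameterVector(psi1=0.7, psi2=0.3)
    ll0 = complex_log_likelihood("a", {"b"},
                                 _state_with_edges(uni, base), theta)
    ll1 = complex_log_likelihood(
        "a", {"b"}, _state_with_edges(uni, base + [("d", "e"), ("e", "f")]),
        theta)
    assert ll0 == pytest.approx(ll1)


# ---------------------------------------------------------------------------
# literature, transfer, prior
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("obs,z,pos,neg,expected", [
    (1, 1, 0.8, 0.01, math.log(0.8)),
    (1, 0, 0.8, 0.01, math.log(0.01)),
    (0, 1, 0.8, 0.01, math.log(0.2)),
])
def test_literature_log_prob(obs, z, pos, neg, expected):
    assert literature_log_prob(obs, z, pos, neg) == pytest.approx(expected)


def test_literature_normalizes():
    for z in (0, 1):
        total = sum(math.exp(literature_log_prob(o, z, 0.8, 0.05))
                    for o in (0, 1))
        assert total == pytest.approx(1.0)


def test_transfer_prob_modes():
    theta = ParameterVector(phi1=0.7, phi0=0.05, lambda1=0.6, lambda0=0.1)
    assert transfer_prob(1, 0.5, "interaction", theta) == 0.7
    assert transfer_prob(0, 0.5, "interaction", theta) == 0.05
    assert transfer_prob(1, 0.5, "self_activation", theta) == 0.6
    # logistic parameterization is monotone increasing in identity
    hi = transfer_prob(1, 0.9, "interaction", theta, "logistic")
    lo = transfer_prob(1, 0.3, "interaction", theta, "logistic")
    assert hi > lo
    with pytest.raises(ValueError):
        transfer_prob(1, 0.5, "sideways", theta)


def test_joint_identity_geometric_mean():
    assert joint_identity(0.49, 1.0) == pytest.approx(0.7)
    assert joint_identity(0.6, 0.6) == pytest.approx(0.6)


def test_prior_log_prob_examples():
    uni = make_universe(3)
    theta = ParameterVector(rho=0.5, r=0.5)
    state = LatentState.zeros(uni)
    assert prior_log_prob(state, theta) == pytest.approx(6 * math.log(0.5))
    uni2 = make_universe(2)
    st2 = LatentState.zeros(uni2)
    st2.z[("a", "b")] = 1
    st2.x = {}
    assert prior_log_prob(st2, ParameterVector(rho=0.01)) == \
        pytest.approx(math.log(0.01))
    # degenerate prior: rho=1 with an absent edge drives the log prior to
    # the guarded floor (effectively minus infinity)
    st3 = LatentState.zeros(uni2)
    st3.x = {}
    assert prior_log_prob(st3, ParameterVector(rho=1.0)) < -600


# ---------------------------------------------------------------------------
# complete likelihood
# ---------------------------------------------------------------------------

def test_complete_ll_empty_evidence_is_prior(theta_mid):
    uni = make_universe(3)
    ev = EvidenceSet.build(uni)
    state = LatentState.zeros(uni)
    assert complete_log_likelihood(state, ev, theta_mid) == \
        pytest.approx(prior_log_prob(state, theta_mid))


def test_complete_ll_additivity_single_record(theta_mid):
    uni = make_universe(2)
    ev = EvidenceSet.build(uni, y2h=y2h_frame([("a", "b", "s1", 1, 1)]))
    state = LatentState.zeros(uni)
    p = y2h_response_prob(0, 0, 0, theta_mid)
    expected = prior_log_prob(state, theta_mid) + math.log(p)
    assert complete_log_likelihood(state, ev, theta_mid) == \
        pytest.approx(expected)


def _tiny_full_evidence(theta):
    uni = make_universe(3, star=[("a*", "org1"), ("b*", "org1")])
    import pandas as pd
    hom = pd.DataFrame({"human": ["a", "b"], "ortholog": ["a*", "b*"],
                        "organism": ["org1", "org1"],
                        "identity": [0.8, 0.6]})
    ev = EvidenceSet.build(
        uni,
        y2h=y2h_frame([("a", "b", "s1", 1, 1), ("a", "b", "s1", 2, 0),
                       ("b", "c", "s1", 1, 1),
                       ("a*", "b*", "s2", 1, 1)]),
        literature=lit_frame([("a", "b", "H", 1), ("a", "c", "L", 0)]),
        complexes=[ComplexRecord("a", frozenset({"b"}), "e1")],
        homology=hom)
    return uni, ev


def test_complete_ll_equals_sum_of_factors(theta_mid):
    """Cross-check against an independent per-factor summation."""
    uni, ev = _tiny_full_evidence(theta_mid)
    state = LatentState.zeros(uni, ev.homology)
    rng = np.random.default_rng(3)
    for key in state.z:
        state.z[key] = int(rng.integers(2))
    for key in state.x:
        state.x[key] = int(rng.integers(2))
    state.star["org1"].z[("a*", "b*")] = 1
    state.star["org1"].x["a*"] = 1

    expected = prior_log_prob(state, theta_mid)
    for row in ev.y2h.itertuples(index=False):
        org = uni.organism[row.a]
        zm, xm = state.z_of(org), state.x_of(org)
        pair = tuple(sorted((row.a, row.b)))
        p = y2h_response_prob(zm[pair], xm[row.a], xm[row.b], theta_mid)
        expected += math.log(p if row.observed else 1 - p)
    expected += complex_log_likelihood("a", {"b"}, state, theta_mid)
    expected += literature_log_prob(1, state.z[("a", "b")],
                                    theta_mid.gamma1, theta_mid.gamma0)
    expected += literature_log_prob(0, state.z[("a", "c")],
                                    theta_mid.beta1, theta_mid.beta0)
    for org, hpair, spair, jid in transfer_links(ev.homology):
        p = transfer_prob(state.z[hpair], jid, "interaction", theta_mid)
        zs = state.star[org].z[spair]
        expected += math.log(p if zs else 1 - p)
    for row in ev.homology.itertuples(index=False):
        p = transfer_prob(state.x[row.human], row.identity,
                          "self_activation", theta_mid)
        xs = state.star[row.organism].x[row.ortholog]
        expected += math.log(p if xs else 1 - p)

    assert complete_log_likelihood(state, ev, theta_mid) == \
        pytest.approx(expected)


def test_complete_ll_permutation_equivariance(theta_mid):
    """Relabelling proteins leaves the likelihood unchanged."""
    uni, ev = _tiny_full_evidence(theta_mid)
    state = LatentState.zeros(uni, ev.homology)
    state.z[("a", "b")] = 1
    state.x["c"] = 1
    state.star["org1"].z[("a*", "b*")] = 1
    ll = complete_log_likelihood(state, ev, theta_mid)

    ren = {"a": "q", "b": "p", "c": "r", "a*": "q*", "b*": "p*"}
    from ppibayes import ProteinUniverse
    uni2 = ProteinUniverse([ren[p] for p in uni.proteins],
                           [uni.organism[p] for p in uni.proteins])
    y2 = ev.y2h.copy()
    y2["a"], y2["b"] = y2["a"].map(ren), y2["b"].map(ren)
    l2 = ev.literature.copy()
    l2["a"], l2["b"] = l2["a"].map(ren), l2["b"].map(ren)
    h2 = ev.homology.copy()
    h2["human"], h2["ortholog"] = h2["human"].map(ren), \
        h2["ortholog"].map(ren)
    cx2 = [ComplexRecord(ren[c.bait],
                         frozenset(ren[m] for m in c.members),
                         c.experiment_id) for c in ev.complexes]
    ev2 = EvidenceSet.build(uni2, y2h=y2, literature=l2, complexes=cx2,
                            homology=h2)
    state2 = LatentState.zeros(uni2, h2)
    state2.z[tuple(sorted(("q", "p")))] = 1
    state2.x["r"] = 1
    state2.star["org1"].z[tuple(sorted(("q*", "p*")))] = 1
    assert complete_log_likelihood(state2, ev2, theta_mid) == \
        pytest.approx(ll)


def test_self_pairs_dropped_with_warning(caplog):
    uni = make_universe(2)
    with caplog.at_level("WARNING"):
        ev = EvidenceSet.build(uni, y2h=y2h_frame([
            ("a", "a", "s1", 1, 1), ("a", "b", "s1", 1, 1)]))
    assert len(ev.y2h) == 1
    assert "self-pair" in caplog.text


def test_unknown_protein_rejected():
    uni = make_universe(2)
    with pytest.raises(EvidenceError):
        EvidenceSet.build(uni, y2h=y2h_frame([("a", "zz", "s1", 1, 1)]))


def test_per_source_overrides_change_only_that_source(theta_mid):
    theta = ParameterVector(alpha_U=0.01,
                            overrides={"s2": {"alpha_U": 0.2}})
    assert theta.for_source("s1").alpha_U == 0.01
    assert theta.for_source("s2").alpha_U == 0.2
    assert theta.for_source(None).alpha_U == 0.01
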