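"""Shared fixtures: small hand-built evidence sets and the session-scoped
parameter-recovery simulation (500 proteins, known generating parameters)
that several integration tests share."""

import numpy as np
import pandas as pd
import pytest

from ppibayes import (EvidenceSet, ParameterVector, ProteinUniverse,
                      simulate_dataset)
from ppibayes.mcem import MCEMSchedule, fit
from ppibayes.simulate import SimulationConfig


def make_universe(n_human, star=()):
    """n_human human proteins 'a', 'b', ... plus optional starred ids."""
    names = [chr(ord("a") + i) for i in range(n_human)]
    prots = names + [s for s, _ in star]
    orgs = ["human"] * n_human + [o for _, o in star]
    return ProteinUniverse(prots, orgs)


def y2h_frame(rows):
    """rows: (a, b, source, replicate, observed)"""
    return pd.DataFrame(rows, columns=["a", "b", "source_id", "replicate",
                                       "observed"])


def lit_frame(rows):
    """rows: (a, b, channel, observed)"""
    return pd.DataFrame(rows, columns=["a", "b", "channel", "observed"])


@pytest.fixture
def theta_mid():
    """Interior parameters exercising every factor."""
    return ParameterVector(rho=0.2, r=0.2, alpha_I=0.8, alpha_S=0.5,
                           alpha_U=0.05, psi1=0.8, psi2=0.4,
                           gamma1=0.8, gamma0=0.05, beta1=0.7, beta0=0.1,
                           phi1=0.7, phi0=0.1, lambda1=0.7, lambda0=0.1)


def tiny_sim_config(seed, theta):
    return SimulationConfig(
        n_proteins=4, theta_true=theta, n_y2h_replicates=2,
        y2h_coverage=1.0, n_baits=2, n_homolog_organisms=1,
        homolog_fraction=0.5, seed=seed)


def tiny_instances(theta, count, max_vars=14, require_all_types=True,
                   start_seed=0):
    """Simulated 4-protein instances small enough for exact enumeration."""
    out, seed = [], start_seed
    while len(out) < count:
        sim = simulate_dataset(tiny_sim_config(seed, theta))
        seed += 1
        ev = sim.evidence
        n_star_prot = len(ev.homology)
        n_vars = 6 + 4 + n_star_prot * (n_star_prot - 1) // 2 + n_star_prot
        if n_vars > max_vars:
            continue
        if require_all_types and (not len(ev.y2h) or not len(ev.literature)
                                  or not ev.complexes
                                  or n_star_prot < 2):
            continue
        out.append(sim)
    return out


# ---------------------------------------------------------------------------
# the shared recovery study: 500 proteins, full evidence, known theta*
# ---------------------------------------------------------------------------

THETA_STAR = ParameterVector(
    rho=0.01, r=8.9e-5, alpha_I=0.9, alpha_S=0.4, alpha_U=0.005,
    psi1=0.8, psi2=0.4, gamma1=0.8, gamma0=0.01, beta1=0.7, beta0=0.02,
    phi1=0.7, phi0=0.05, lambda1=0.7, lambda0=0.05)

#: schedule keeping the 500-protein fits inside a few minutes
LEAN_SCHEDULE = MCEMSchedule(burnin=30, base=60, step=40, cap=300,
                             score_burnin=50, score_samples=300)


@pytest.fixture(scope="session")
def recovery_sim():
    cfg = SimulationConfig(n_proteins=500, theta_true=THETA_STAR, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def recovery_fit(recovery_sim):
    return fit(recovery_sim.evidence, schedule=LEAN_SCHEDULE,
               tol=0.01, max_iter=25, seed=7)
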