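"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's vectorised code paths:
the Hamiltonian oracle is a plain double loop, and the joint-distribution
oracle enumerates every sequence of a tiny model so that single-site
conditionals and stationary distributions can be checked exactly.
"""

import itertools

import numpy as np
import pytest

from epistasim import Alphabet, PottsModel, SimulationConfig, SyntheticModelSpec, generate_potts_model


def hamiltonian_oracle(seq, model):
    """Brute-force double-loop log weight: sum_{i<j} J + sum_i h."""
    total = 0.0
    n = model.n_sites
    for i in range(n):
        total += model.fields[i, seq[i]]
        for j in range(i + 1, n):
            total += model.couplings[i, j, seq[i], seq[j]]
    return total


def enumerate_joint(model):
    """All sequences of a tiny model with their Boltzmann probabilities."""
    n, q = model.n_sites, model.n_states
    seqs = list(itertools.product(range(q), repeat=n))
    logw = np.array([hamiltonian_oracle(s, model) for s in seqs])
    w = np.exp(logw - logw.max())
    return seqs, w / w.sum()


def conditional_oracle(seq, site, model):
    """P(a_site | rest) from the enumerated joint distribution."""
    seqs, probs = enumerate_joint(model)
    q = model.n_states
    out = np.zeros(q)
    for s, p in zip(seqs, probs):
        if all(s[j] == seq[j] for j in range(model.n_sites) if j != site):
            out[s[site]] += p
    return out / out.sum()


def random_tiny_model(rng, n_max=4, q_max=4):
    """A random small dense model suitable for exhaustive enumeration."""
    n = int(rng.integers(2, n_max + 1))
    q = int(rng.integers(2, q_max + 1))
    couplings = rng.normal(0, 0.8, size=(n, n, q, q))
    couplings = 0.5 * (couplings + couplings.transpose(1, 0, 3, 2))
    couplings[np.arange(n), np.arange(n)] = 0.0
    fields = rng.normal(0, 0.8, size=(n, q))
    return PottsModel.from_arrays(couplings, fields, Alphabet.generic(q))


@pytest.fixture(scope="session")
def tiny_model():
    """Fixed 4-site, 4-state dense model for enumeration-based checks."""
    return random_tiny_model(np.random.default_rng(42), n_max=4, q_max=4)


@pytest.fixture(scope="session")
def small_synthetic():
    """Default-structure synthetic model, shrunk to N=30 for speed."""
    return generate_potts_model(SyntheticModelSpec(n_sites=30, seed=11))


@pytest.fixture(scope="session")
def strong_coupling_model():
    """Coupling-dominated synthetic model for regression-style checks."""
    return generate_potts_model(
        SyntheticModelSpec(
            n_sites=40, coupling_density=0.15, coupling_scale=1.5, field_scale=1.0, seed=5
        )
    )


@pytest.fixture(scope="session")
def short_config():
    return SimulationConfig(total_generations=2000, burn_in=400, n_replicates=8, master_seed=3)
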