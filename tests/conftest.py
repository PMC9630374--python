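"""Shared fixtures and the independent brute-force oracle.

The oracle computes the Cloude covariance matrix by explicit looped Pauli
summation and the purity indices straight from numpy's eigen-decomposition.
It deliberately shares no code with the package implementation.
"""

import numpy as np
import pytest


def oracle_covariance(M):
    """Brute-force H(M) = (1/4) sum_ab m_ab sigma_a (x) conj(sigma_b)."""
    sigma = [
        np.array([[1, 0], [0, 1]], complex),
        np.array([[1, 0], [0, -1]], complex),
        np.array([[0, 1], [1, 0]], complex),
        np.array([[0, -1j], [1j, 0]], complex),
    ]
    H = np.zeros((4, 4), complex)
    for a in range(4):
        for b in range(4):
            H += M[a, b] * np.kron(sigma[a], sigma[b].conj())
    return H / 4.0


def oracle_spectrum(M):
    """Descending clamped normalized eigenvalues of the oracle covariance."""
    lam = np.sort(np.linalg.eigvalsh(oracle_covariance(M)).real)[::-1]
    lam = np.clip(lam, 0.0, None)
    return lam / lam.sum()


def oracle_ipps(M):
    l0, l1, l2, l3 = oracle_spectrum(M)
    return np.array([l0 - l1, l0 + l1 - 2 * l2, l0 + l1 + l2 - 3 * l3])


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_mixtures(rng):
    """Physically realizable random matrices: convex sums of random pure elements."""
    from polcolor import random_cloude_mixture

    return random_cloude_mixture(rng, 500)


@pytest.fixture
def constant_stack():
    """A 8x8 observable stack from an all-identity Mueller image."""
    from polcolor import MuellerImage, compute_observables

    elements = np.broadcast_to(np.eye(4), (8, 8, 4, 4)).copy()
    return compute_observables(MuellerImage(elements=elements))
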