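import numpy as np
import pytest

from spincompass import synthetic_data
from spincompass.spin_core import FieldDirection


@pytest.fixture(scope="session")
def fixtures():
    """Named small radical-pair systems shared across the suite."""
    return synthetic_data.fixture_systems()


@pytest.fixture(scope="session")
def coarse_times():
    """Short time grid for pointwise dense-oracle comparisons (us)."""
    return np.linspace(0.0, 4.0, 81)


@pytest.fixture(scope="session")
def z_direction():
    return FieldDirection.from_vector([0.0, 0.0, 1.0])


@pytest.fixture(scope="session")
def oblique_direction():
    return FieldDirection.from_vector([1.0, -2.0, 1.5])


def dense_singlet_probability(pair, direction, times):
    """Full-Hilbert-space oracle for p_S(t) using scaling-and-squaring expm.

    Independent of the production path: no eigendecomposition, stepwise
    propagation with a fixed-step propagator.
    """
    from scipy.linalg import expm

    from spincompass.spin_core import pair_hamiltonian, singlet_projector

    times = np.asarray(times)
    dt = times[1] - times[0]
    assert np.allclose(np.diff(times), dt), "oracle needs a uniform grid"
    field = pair.b0 * direction.unit if direction is not None else np.zeros(3)
    h = pair_hamiltonian(pair, field)
    p_s = singlet_projector(pair.radical_a.z, pair.radical_b.z)
    rho = p_s / np.trace(p_s).real
    u = expm(-1j * h * dt)
    out = np.empty(times.size)
    sigmas = np.empty((times.size, 4, 4), dtype=complex)
    za, zb = pair.radical_a.z, pair.radical_b.z
    for i in range(times.size):
        out[i] = np.einsum("ij,ji->", p_s, rho).real
        r = rho.reshape(2, za, 2, zb, 2, za, 2, zb)
        sigmas[i] = np.einsum("iajbkalb->ijkl", r).reshape(4, 4)
        rho = u @ rho @ u.conj().T
    return out, sigmas


def spectral_yield_oracle(pair, direction):
    """Exact double sum over eigenpairs of the *joint* Hamiltonian.

    Independent route: diagonalizes H_A + H_B on the full pair space rather
    than composing per-radical eigensystems.
    """
    from spincompass.spin_core import pair_hamiltonian, singlet_projector

    field = pair.b0 * direction.unit if direction is not None else np.zeros(3)
    h = pair_hamiltonian(pair, field)
    w, v = np.linalg.eigh(h)
    p_s = singlet_projector(pair.radical_a.z, pair.radical_b.z)
    p_eig = v.conj().T @ p_s @ v
    m = pair.radical_a.z * pair.radical_b.z
    w_diff = w[:, None] - w[None, :]
    k = pair.k
    return float(np.sum(np.abs(p_eig) ** 2 * k**2 / (k**2 + w_diff**2)) / m)
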