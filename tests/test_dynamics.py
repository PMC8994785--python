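import numpy as np
import pytest

from conftest import dense_singlet_probability, spectral_yield_oracle
from spincompass import dynamics as dy
from spincompass.spin_core import (
    DensityOperator,
    EulerOrientation,
    FieldDirection,
    NucleusSpec,
    RadicalPairSpec,
    RadicalSpec,
    pair_hamiltonian,
    singlet_projector,
)

Z_DIR = FieldDirection.from_vector([0.0, 0.0, 1.0])


class TestPropagateDensity:
    def test_stationary_state_unchanged_without_decay(self):
        h = np.diag([1.0, 2.0, 3.0]).astype(complex)
        rho0 = np.diag([0.5, 0.3, 0.2]).astype(complex)  # commutes with H
        traj = dy.propagate_density(rho0, h, 0.0, np.linspace(0, 3, 7))
        assert np.abs(traj.values - rho0).max() < 1e-12

    def test_trace_decays_exponentially(self, fixtures):
        pair = fixtures["one_proton"]
        h = pair_hamiltonian(pair, [0, 0, 50.0])
        p = singlet_projector(pair.radical_a.z, pair.radical_b.z)
        times = np.linspace(0, 5, 21)
        traj = dy.propagate_density(p / np.trace(p).real, h, 1.3, times)
        traces = np.einsum("tii->t", traj.values).real
        assert np.abs(traces - np.exp(-1.3 * times)).max() < 1e-12

    def test_matches_expm_oracle(self, fixtures, coarse_times, oblique_direction):
        """One-proton pair vs scaling-and-squaring matrix exponentials."""
        from scipy.linalg import expm

        pair = fixtures["one_proton"]
        h = pair_hamiltonian(pair, pair.b0 * oblique_direction.unit)
        p = singlet_projector(pair.radical_a.z, pair.radical_b.z)
        rho0 = p / np.trace(p).real
        k = 0.7
        traj = dy.propagate_density(rho0, h, k, coarse_times)
        for i in (0, 10, 40, 80):
            t = coarse_times[i]
            u = expm(-1j * h * t)
            expected = np.exp(-k * t) * (u @ rho0 @ u.conj().T)
            assert np.abs(traj.values[i] - expected).max() < 1e-10

    def test_rejects_non_hermitian(self):
        with pytest.raises(ValueError):
            dy.propagate_density(np.eye(2) / 2, np.array([[0, 1], [0, 0.0]]),
                                 0.0, [0.0, 1.0])


class TestSpinCorrelationTensor:
    def test_bare_electron_zero_field_is_static(self):
        times = np.linspace(0, 3, 31)
        sct = dy.compute_sct(RadicalSpec("bare"), [0, 0, 0], times)
        expected = np.broadcast_to(np.eye(3) / 2, (31, 3, 3))
        assert np.abs(sct.r - expected).max() < 1e-12

    def test_bare_electron_larmor_precession(self):
        times = np.linspace(0, 2, 101)
        b = 50.0
        sct = dy.compute_sct(RadicalSpec("bare"), [0, 0, b], times)
        omega = 2 * np.pi * 28.024951e-3 * b  # rad/us
        assert np.abs(sct.r[:, 2, 2] - 0.5).max() < 1e-12
        assert np.abs(sct.r[:, 0, 0] - 0.5 * np.cos(omega * times)).max() < 1e-10

    def test_isotropic_coupling_gives_isotropic_sct(self):
        """One isotropic proton at B=0: R_ab = delta_ab r(t), oracle-checked."""
        a = 10.0
        rad = RadicalSpec("A", (NucleusSpec("H", 0.5, a * np.eye(3)),))
        times = np.linspace(0, 2, 101)
        sct = dy.compute_sct(rad, [0, 0, 0], times)
        # Heisenberg-picture dense oracle on the 4-dim radical space
        from scipy.linalg import expm

        from spincompass.spin_core import build_radical_hamiltonian, electron_spin_ops

        h = build_radical_hamiltonian(rad, [0, 0, 0])
        s_ops = electron_spin_ops(rad)
        for i in (0, 17, 50, 100):
            u = expm(-1j * h * times[i])
            r_oracle = np.array(
                [
                    [np.trace(s_ops[a_] @ u @ s_ops[b_] @ u.conj().T).real
                     for b_ in range(3)]
                    for a_ in range(3)
                ]
            ) / rad.z
            assert np.abs(sct.r[i] - r_oracle).max() < 1e-10
        off = sct.r - np.eye(3)[None, :, :] * sct.r[:, 0, 0][:, None, None]
        assert np.abs(off).max() < 1e-10

    def test_dimension_guard(self):
        rad = RadicalSpec(
            "big", tuple(NucleusSpec(f"N{i}", 1.0, np.eye(3)) for i in range(8))
        )
        assert rad.dim > dy.MAX_DENSE_DIM
        with pytest.raises(ValueError, match="guard"):
            dy.compute_sct(rad, [0, 0, 0], np.linspace(0, 1, 3))


class TestSingletProbability:
    def test_nucleus_free_pair_stays_singlet(self):
        times = np.linspace(0, 5, 41)
        pair = RadicalPairSpec(RadicalSpec("A"), RadicalSpec("B"), b0=50.0)
        sa, sb = dy.pair_scts(pair, Z_DIR, times)
        p = dy.singlet_probability(sa, sb).values
        assert np.abs(p - 1.0).max() < 1e-12

    def test_singlet_born_at_t0(self, fixtures, coarse_times, oblique_direction):
        for name in ("one_proton", "two_proton_aniso", "three_nucleus"):
            sa, sb = dy.pair_scts(fixtures[name], oblique_direction, coarse_times)
            p = dy.singlet_probability(sa, sb).values
            assert p[0] == pytest.approx(1.0, abs=1e-12)
            assert np.all(p > -1e-10) and np.all(p < 1 + 1e-10)

    def test_grid_mismatch_rejected(self, fixtures):
        pair = fixtures["one_proton"]
        sa, _ = dy.pair_scts(pair, Z_DIR, np.linspace(0, 1, 11))
        _, sb = dy.pair_scts(pair, Z_DIR, np.linspace(0, 2, 11))
        with pytest.raises(ValueError):
            dy.singlet_probability(sa, sb)

    @pytest.mark.parametrize(
        "name", ["one_proton", "two_proton_aniso", "three_nucleus"]
    )
    def test_sct_route_matches_dense_oracle(
        self, fixtures, coarse_times, oblique_direction, name
    ):
        """p_S(t) and sigma(t) from SCTs vs full-Hilbert-space propagation."""
        pair = fixtures[name].with_orientation(EulerOrientation(25, 70, 130))
        p_oracle, sig_oracle = dense_singlet_probability(
            pair, oblique_direction, coarse_times
        )
        sa, sb = dy.pair_scts(pair, oblique_direction, coarse_times)
        p = dy.singlet_probability(sa, sb).values
        sig = dy.electronic_density(sa, sb).values
        assert np.abs(p - p_oracle).max() < 1e-9
        assert np.abs(sig - sig_oracle).max() < 1e-9

    def test_rotation_shortcut_equals_recomputation(self, fixtures):
        """Conjugating the SCT by the Euler rotation == rotating the tensors."""
        pair = fixtures["two_proton_aniso"].with_orientation(
            EulerOrientation(111.0, 47.0, 201.0)
        )
        times = np.linspace(0, 3, 61)
        d = FieldDirection.from_vector([0.2, 0.9, -0.4])
        sa1, _ = dy.pair_scts(pair, d, times, rotate_sct=False)
        sa2, _ = dy.pair_scts(pair, d, times, rotate_sct=True)
        assert np.abs(sa1.r - sa2.r).max() < 1e-9


class TestElectronicDensity:
    def test_density_axioms_along_trajectory(self, fixtures, coarse_times):
        sa, sb = dy.pair_scts(fixtures["two_proton_aniso"], Z_DIR, coarse_times)
        sig = dy.electronic_density(sa, sb).values
        assert np.abs(sig - sig.conj().transpose(0, 2, 1)).max() < 1e-12
        traces = np.einsum("tii->t", sig).real
        assert np.abs(traces - 1.0).max() < 1e-12
        assert np.linalg.eigvalsh(sig).min() > -1e-10

    def test_initial_state_is_singlet_projector(self, fixtures, coarse_times):
        sa, sb = dy.pair_scts(fixtures["one_proton"], Z_DIR, coarse_times)
        sig0 = dy.electronic_density(sa, sb).values[0]
        s = np.array([0, 1.0, -1.0, 0]) / np.sqrt(2)
        assert np.abs(sig0 - np.outer(s, s)).max() < 1e-12


class TestSingletYield:
    def test_nucleus_free_pair_yield_is_one(self):
        pair = RadicalPairSpec(RadicalSpec("A"), RadicalSpec("B"), b0=50.0)
        for method in ("spectral", "time"):
            y = dy.singlet_yield(pair, Z_DIR, method)
            assert y.value == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize(
        "name", ["one_proton", "two_proton_aniso", "three_nucleus"]
    )
    def test_yield_conservation(self, fixtures, oblique_direction, name):
        """Y_S + Y_T = 1 with k_S = k_T: triplet yield via P_T = 1 - P_S."""
        pair = fixtures[name]
        omega, p_eig = dy.spectral_ingredients(pair, oblique_direction)
        m = pair.radical_a.z * pair.radical_b.z
        w_diff = omega[:, None] - omega[None, :]
        lor = pair.k**2 / (pair.k**2 + w_diff**2)
        y_s = np.sum(np.abs(p_eig) ** 2 * lor) / m
        # triplet yield of the singlet-born pair via P_T = 1 - P_S:
        # Y_T = (1/M) sum_jk conj(<j|P_T|k>) <j|P_S|k> L_jk
        p_t_eig = np.eye(p_eig.shape[0]) - p_eig
        y_t = np.sum((p_t_eig.conj() * p_eig).real * lor) / m
        assert y_s + y_t == pytest.approx(1.0, abs=1e-8)

    def test_spectral_equals_time_quadrature(self, fixtures, oblique_direction):
        for name in ("one_proton", "two_proton_aniso", "three_nucleus"):
            pair = fixtures[name]
            y_s = dy.singlet_yield(pair, oblique_direction, "spectral").value
            y_t = dy.singlet_yield(pair, oblique_direction, "time").value
            assert abs(y_s - y_t) < 1e-6

    def test_spectral_matches_joint_eigenbasis_oracle(self, fixtures):
        """Product-basis factorization vs direct joint diagonalization."""
        pair = fixtures["one_proton"]
        pair = RadicalPairSpec(pair.radical_a, pair.radical_b, b0=0.0, k=1.0)
        y = dy.singlet_yield(pair, None, "spectral").value
        assert y == pytest.approx(spectral_yield_oracle(pair, None), abs=1e-10)

    def test_unknown_method_rejected(self, fixtures):
        with pytest.raises(ValueError):
            dy.singlet_yield(fixtures["one_proton"], Z_DIR, "guess")


class TestMonteCarloYield:
    def test_exhaustive_fallback_is_exact(self, fixtures, z_direction):
        pair = fixtures["one_proton"]
        exact = dy.singlet_yield(pair, z_direction, "spectral").value
        mc = dy.monte_carlo_yield(pair, "singlet", z_direction, 10**7, seed=3)
        assert mc.stderr == 0.0
        assert mc.value == pytest.approx(exact, abs=1e-12)

    def test_estimator_unbiased_over_seeds(self, fixtures, oblique_direction):
        """Mean of 50 seeded estimates within 3 stderr of the exact sum.

        Uses the 5-nucleus fixture so that the sampled index-pair count
        stays far below the total and the estimator genuinely samples.
        """
        pair = fixtures["flavinlike_random"]
        exact = dy.singlet_yield(pair, oblique_direction, "spectral").value
        estimates = np.array(
            [
                dy.monte_carlo_yield(
                    pair, "singlet", oblique_direction, 10**4, seed=s
                ).value
                for s in range(50)
            ]
        )
        stderr_of_mean = estimates.std(ddof=1) / np.sqrt(50)
        assert abs(estimates.mean() - exact) < 3 * stderr_of_mean

    def test_stderr_scales_with_sample_size(self, fixtures, oblique_direction):
        pair = fixtures["flavinlike_random"]
        s1 = dy.monte_carlo_yield(pair, "singlet", oblique_direction,
                                  4000, seed=11).stderr
        s4 = dy.monte_carlo_yield(pair, "singlet", oblique_direction,
                                  16000, seed=11).stderr
        assert s4 == pytest.approx(s1 / 2, rel=0.25)

    def test_invalid_inputs(self, fixtures, z_direction):
        with pytest.raises(ValueError):
            dy.monte_carlo_yield(fixtures["one_proton"], "bogus", z_direction,
                                 10, seed=0)
        with pytest.raises(ValueError):
            dy.monte_carlo_yield(fixtures["one_proton"], "singlet", z_direction,
                                 0, seed=0)


def test_trajectory_validation():
    with pytest.raises(ValueError):
        dy.Trajectory(times=np.array([0.5, 1.0]), values=np.zeros(2))
    with pytest.raises(ValueError):
        dy.Trajectory(times=np.array([0.0, 0.0]), values=np.zeros(2))


def test_density_operator_validation():
    good = DensityOperator(np.eye(2) / 2)
    good.validate()
    with pytest.raises(ValueError):
        DensityOperator(np.array([[0.5, 0.5], [0.0, 0.5]])).validate()
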