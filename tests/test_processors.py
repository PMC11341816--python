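"""Bartlett and sparsity-aware processors against independent oracles."""

import numpy as np
import pytest

from biosonar.forward import EchoDataset, SteeringMatrixSet, simulate_echoes
from biosonar.processors import (SolverConfig, bartlett_known,
                                 bartlett_unknown, epsilon_from_energy,
                                 sa_known, sa_unknown)
from biosonar.solvers import solve_sparse_vector

from conftest import random_instance


def brute_force_bartlett_known(a, data):
    """Naive per-voxel, per-sensor, per-frequency delay-and-sum loop."""
    K, F, M, N = a.shape
    h = np.zeros(N)
    for k in range(K):
        acc = np.zeros(N)
        for n in range(N):
            for i in range(F):
                inner = 0.0 + 0.0j
                for m in range(M):
                    inner += np.conj(a[k, i, m, n]) * data[m, i, k]
                acc[n] += abs(inner) ** 2
        h += np.sqrt(acc)
    return h / K


def brute_force_bartlett_unknown(b, data):
    F, M, N = b.shape
    K = data.shape[2]
    h = np.zeros(N)
    for k in range(K):
        for i in range(F):
            for n in range(N):
                inner = 0.0 + 0.0j
                for m in range(M):
                    inner += np.conj(b[i, m, n]) * data[m, i, k]
                h[n] += abs(inner)
    return h / (F * K)


def _known_set(freqs, a):
    K, F, M, N = a.shape
    return SteeringMatrixSet("known", freqs, np.ones((M, N)), a=a,
                             tx_voxel_dist=np.ones((K, N)))


def _unknown_set(freqs, b):
    F, M, N = b.shape
    return SteeringMatrixSet("unknown", freqs, np.ones((M, N)), b=b)


class TestBartlettOracles:
    @pytest.mark.parametrize("trial", range(20))
    def test_known_matches_bruteforce(self, trial):
        rng = np.random.default_rng(1000 + trial)
        m, n, f, k = (int(rng.integers(2, 8)), int(rng.integers(2, 50)),
                      int(rng.integers(1, 6)), int(rng.integers(1, 4)))
        freqs, a, data = random_instance(rng, m, n, f, k, "known")
        out = bartlett_known(EchoDataset(data, freqs, "known"),
                             _known_set(freqs, a))
        expected = brute_force_bartlett_known(a, data)
        assert np.allclose(out.h, expected, rtol=1e-9, atol=0)

    @pytest.mark.parametrize("trial", range(20))
    def test_unknown_matches_bruteforce(self, trial):
        rng = np.random.default_rng(2000 + trial)
        m, n, f, k = (int(rng.integers(2, 8)), int(rng.integers(2, 50)),
                      int(rng.integers(1, 6)), int(rng.integers(1, 4)))
        freqs, b, data = random_instance(rng, m, n, f, k, "unknown")
        out = bartlett_unknown(EchoDataset(data, freqs, "unknown"),
                               _unknown_set(freqs, b))
        expected = brute_force_bartlett_unknown(b, data)
        assert np.allclose(out.h, expected, rtol=1e-9, atol=0)


class TestBartlettProperties:
    def test_single_scatterer_peak_sqrtF_M(self, rng):
        freqs, a, _ = random_instance(rng, 6, 30, 5, 2, "known")
        K, F, M, N = a.shape
        n_star = 7
        data = np.stack([a[k, :, :, n_star].T for k in range(K)], axis=2)
        out = bartlett_known(EchoDataset(data, freqs, "known"),
                             _known_set(freqs, a))
        assert int(np.argmax(out.h)) == n_star
        assert out.h[n_star] == pytest.approx(np.sqrt(F) * M, rel=1e-12)

    def test_unknown_per_frequency_peak_M(self, rng):
        freqs, b, _ = random_instance(rng, 6, 30, 4, 1, "unknown")
        F, M, N = b.shape
        n_star = 3
        data = b[:, :, n_star].T[:, :, None]
        out = bartlett_unknown(EchoDataset(data, freqs, "unknown"),
                               _unknown_set(freqs, b))
        # every per-frequency image peaks at M at the true voxel, so the
        # average does too
        assert out.h[n_star] == pytest.approx(M, rel=1e-12)
        assert int(np.argmax(out.h)) == n_star

    def test_homogeneous_in_data(self, rng):
        freqs, a, data = random_instance(rng, 4, 10, 3, 2, "known")
        ds1 = EchoDataset(data, freqs, "known")
        ds2 = EchoDataset(3.0 * data, freqs, "known")
        st = _known_set(freqs, a)
        assert np.allclose(bartlett_known(ds2, st).h,
                           3.0 * bartlett_known(ds1, st).h)

    def test_identical_clicks_equal_single_click(self, rng):
        freqs, b, data = random_instance(rng, 4, 10, 3, 1, "unknown")
        rep = np.repeat(data, 4, axis=2)
        st = _unknown_set(freqs, b)
        h1 = bartlett_unknown(EchoDataset(data, freqs, "unknown"), st).h
        h4 = bartlett_unknown(EchoDataset(rep, freqs, "unknown"), st).h
        assert np.allclose(h1, h4)

    def test_dimension_mismatch_rejected(self, rng):
        freqs, a, data = random_instance(rng, 4, 10, 3, 2, "known")
        st = _known_set(freqs, a)
        bad = EchoDataset(data[:3], freqs, "known")
        with pytest.raises(ValueError):
            bartlett_known(bad, st)


class TestSolverConfig:
    def test_nonconvex_p_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(p=0.9)
        with pytest.raises(ValueError):
            solve_sparse_vector([np.eye(2) + 0j], [np.ones(2) + 0j],
                                0.1, p=0.5)

    def test_epsilon_fraction_bounds(self):
        with pytest.raises(ValueError):
            SolverConfig(epsilon_fraction=0.0)
        with pytest.raises(ValueError):
            SolverConfig(epsilon=-1.0)


class TestEpsilonFromEnergy:
    def test_fraction_of_unit_energy(self, rng):
        data = np.zeros((2, 2, 1), complex)
        data[0, 0, 0] = 1.0            # unit total energy
        ds = EchoDataset(data, np.array([1e5, 1.1e5]), "known")
        assert epsilon_from_energy(ds, 0.5)[0] == pytest.approx(0.5)

    def test_linear_in_energy(self, rng):
        data = rng.standard_normal((3, 4, 2)) + 1j * rng.standard_normal((3, 4, 2))
        ds1 = EchoDataset(data, np.sort(rng.uniform(1e5, 2e5, 4)), "known")
        ds2 = EchoDataset(2.0 * data, ds1.freqs, "known")
        assert np.allclose(epsilon_from_energy(ds2, 0.1),
                           4.0 * epsilon_from_energy(ds1, 0.1))

    def test_zero_energy_click_rejected(self):
        data = np.zeros((2, 2, 1), complex)
        ds = EchoDataset(data, np.array([1e5, 1.1e5]), "known")
        with pytest.raises(ValueError):
            epsilon_from_energy(ds, 0.1)


class TestSparsityAwareKnown:
    def _scene(self, rng, n_voxels=15, n_freqs=4, n_sensors=6):
        freqs, a, _ = random_instance(rng, n_sensors, n_voxels, n_freqs,
                                      1, "known")
        return freqs, a

    def test_large_epsilon_gives_zero_solution(self, rng):
        freqs, a = self._scene(rng)
        n_star = 4
        data = a[0, :, :, n_star].T[:, :, None]
        ds = EchoDataset(data, freqs, "known")
        st = _known_set(freqs, a)
        energy = ds.total_energy()
        with pytest.warns(UserWarning):
            out = sa_known(ds, st, SolverConfig(epsilon=1.1 * energy))
        assert not out.h.any()

    def test_noiseless_single_scatterer_mass_on_true_voxel(self, rng):
        """With a tight residual budget the solution concentrates >= 95%
        of its 1-norm mass on the true voxel."""
        freqs, a = self._scene(rng)
        n_star = 9
        data = a[0, :, :, n_star].T[:, :, None]
        ds = EchoDataset(data, freqs, "known")
        st = _known_set(freqs, a)
        cfg = SolverConfig(epsilon=1e-6 * ds.total_energy(), max_iter=3000,
                           tol=1e-10)
        out = sa_known(ds, st, cfg)
        assert out.h[n_star] / out.h.sum() >= 0.95
        # cross-check against exhaustive single-voxel least-squares fits:
        # no other single voxel explains the data comparably
        residues = []
        y = np.concatenate([data[:, i, 0] for i in range(len(freqs))])
        for n in range(a.shape[3]):
            col = np.concatenate([a[0, i, :, n] for i in range(len(freqs))])
            amp = np.vdot(col, y) / np.vdot(col, col)
            residues.append(float(np.linalg.norm(y - amp * col) ** 2))
        assert int(np.argmin(residues)) == n_star

    def test_feasibility_and_objective_bound(self, rng):
        """Returned solution is feasible and no worse than the min-norm
        least-squares feasible point."""
        freqs, a = self._scene(rng)
        g_true = np.zeros(a.shape[3], complex)
        g_true[[2, 11]] = (1.0, 0.5 - 0.2j)
        st = _known_set(freqs, a)
        ds = simulate_echoes(g_true, st, directivity=False)
        eps = 0.05 * ds.total_energy()
        cfg = SolverConfig(epsilon=eps, max_iter=2000, tol=1e-9, p=1.05)
        out = sa_known(ds, st, cfg)
        diag = out.diagnostics["clicks"][0]
        assert diag["residual"] <= eps * (1 + 1e-9)
        # min-norm least-squares feasible point via the pseudoinverse
        A = np.vstack([a[0, i] for i in range(len(freqs))])
        y = np.concatenate([ds.data[:, i, 0] for i in range(len(freqs))])
        g_ls = np.linalg.pinv(A) @ y
        assert np.linalg.norm(A @ g_ls - y) ** 2 <= eps
        p_norm = lambda v: float(np.sum(np.abs(v) ** 1.05) ** (1 / 1.05))
        assert diag["objective"] <= p_norm(g_ls) * (1 + 1e-6)

    def test_backends_agree(self, rng):
        freqs, a = self._scene(rng, n_voxels=12)
        g_true = np.zeros(12, complex)
        g_true[5] = 1.0
        st = _known_set(freqs, a)
        ds = simulate_echoes(g_true, st, directivity=False)
        eps = 0.05 * ds.total_energy()
        sols = []
        for backend in ("complex", "real"):
            cfg = SolverConfig(epsilon=eps, max_iter=4000, tol=1e-12,
                               backend=backend)
            sols.append(sa_known(ds, st, cfg).per_click[0])
        assert np.abs(sols[0] - sols[1]).max() <= 1e-6


class TestSparsityAwareUnknown:
    def test_zero_data_zero_solution(self, rng):
        freqs, b, _ = random_instance(rng, 4, 10, 3, 1, "unknown")
        data = np.zeros((4, 3, 1), complex)
        ds = EchoDataset(data, freqs, "unknown")
        with pytest.warns(UserWarning):
            out = sa_unknown(ds, _unknown_set(freqs, b),
                             SolverConfig(epsilon=1.0))
        assert not out.h.any()

    def test_single_scatterer_row_mass(self, rng):
        """A scatterer with frequency-varying amplitude concentrates the
        row-norm mass on its voxel."""
        freqs, b, _ = random_instance(rng, 6, 14, 5, 1, "unknown")
        n_star = 6
        amps = 0.5 + rng.uniform(size=5)
        data = (b[:, :, n_star].T * amps[None, :])[:, :, None].astype(complex)
        ds = EchoDataset(data, freqs, "unknown")
        cfg = SolverConfig(epsilon=1e-6 * ds.total_energy(), max_iter=3000,
                           tol=1e-10)
        out = sa_unknown(ds, _unknown_set(freqs, b), cfg)
        G = out.per_click[0]
        row = np.linalg.norm(G, axis=1)
        assert row[n_star] / row.sum() >= 0.95
        # exhaustive single-row fit oracle: per frequency the best
        # single-voxel explanation is the true voxel
        for i in range(len(freqs)):
            fits = [abs(np.vdot(b[i, :, n], data[:, i, 0])) ** 2
                    / np.vdot(b[i, :, n], b[i, :, n]).real
                    for n in range(b.shape[2])]
            assert int(np.argmax(fits)) == n_star

    def test_row_support_shrinks_with_epsilon(self, rng):
        freqs, b, _ = random_instance(rng, 5, 12, 4, 1, "unknown")
        g = np.zeros(12, complex)
        g[[3, 8]] = (1.0, 0.7)
        st = _unknown_set(freqs, b)
        ds = simulate_echoes(g, st, n_clicks=1)
        noisy, _ = np.asarray(ds.data), None
        supports = []
        for frac in (0.02, 0.1, 0.4):
            cfg = SolverConfig(epsilon=frac * ds.total_energy(),
                               max_iter=2000, tol=1e-9)
            G = sa_unknown(ds, st, cfg).per_click[0]
            row = np.linalg.norm(G, axis=1)
            supports.append(int((row > 1e-3 * row.max()).sum())
                            if row.max() > 0 else 0)
        assert supports[0] >= supports[1] >= supports[2]
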