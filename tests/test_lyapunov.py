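import numpy as np
import pytest

from conftest import random_stable_sparse_jacobian
from metajac.lyapunov import (
    FluctuationSpec,
    StabilityError,
    bootstrap_jacobian,
    differential_jacobian,
    solve_forward,
    solve_inverse,
)
from metajac.network import MetabolicNetwork, SparsityPattern, Species, jacobian_sparsity
from metajac.table import MetaboliteTable


def full_pattern(n):
    return SparsityPattern(n, frozenset((i, j) for i in range(n) for j in range(n)))


def kron_solve(J, F):
    """Independent oracle: vectorized Lyapunov solve via Kronecker products,
    (I (x) J + J (x) I) vec(C) = vec(-2F)."""
    n = J.shape[0]
    A = np.kron(np.eye(n), J) + np.kron(J, np.eye(n))
    return np.linalg.solve(A, (-2.0 * F).flatten(order="F")).reshape((n, n), order="F")


class TestForward:
    def test_scalar_closed_form(self):
        C = solve_forward(np.array([[-1.0]]), FluctuationSpec.diagonal([1.0]))
        assert C[0, 0] == pytest.approx(1.0)

    def test_identity_case(self):
        C = solve_forward(-np.eye(3), FluctuationSpec.identity())
        assert np.allclose(C, np.eye(3))

    def test_matches_kronecker_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            J, _ = random_stable_sparse_jacobian(rng, 5)
            vals = rng.uniform(0.5, 2.0, 5)
            F = np.diag(vals)
            C = solve_forward(J, FluctuationSpec.diagonal(vals))
            assert np.abs(C - kron_solve(J, F)).max() < 1e-9

    def test_output_symmetric_psd_with_small_residual(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            J, _ = random_stable_sparse_jacobian(rng, 4)
            flu = FluctuationSpec.diagonal(rng.uniform(0.5, 2.0, 4))
            C = solve_forward(J, flu)
            assert np.allclose(C, C.T)
            assert np.linalg.eigvalsh(C).min() > -1e-12
            F = flu.matrix(4)
            assert np.linalg.norm(J @ C + C @ J.T + 2 * F) < 1e-10 * np.linalg.norm(F)

    def test_unstable_drift_rejected(self):
        with pytest.raises(StabilityError, match="eigenvalues"):
            solve_forward(np.array([[1.0]]), FluctuationSpec.identity())


class TestInverse:
    def test_scalar_closed_form(self):
        # 2 j c = -2 f  =>  j = -f/c = -2 with c = 2, f = 4
        est = solve_inverse(np.array([[2.0]]), FluctuationSpec.diagonal([4.0]), full_pattern(1))
        assert est.values == pytest.approx([-2.0])
        assert not est.rank_deficient

    def test_roundtrip_recovers_sparse_jacobian(self):
        rng = np.random.default_rng(2)
        J, entries = random_stable_sparse_jacobian(rng, 3)
        flu = FluctuationSpec.diagonal([1.0, 1.3, 0.7])
        C = solve_forward(J, flu)
        pat = SparsityPattern(3, frozenset(entries))
        est = solve_inverse(C, flu, pat)
        assert np.abs(est.matrix() - J).max() < 1e-8
        assert est.residual_norm < 1e-8

    def test_dense_pattern_is_rank_deficient_with_tiny_residual(self):
        rng = np.random.default_rng(3)
        J, _ = random_stable_sparse_jacobian(rng, 3)
        flu = FluctuationSpec.identity()
        C = solve_forward(J, flu)
        est = solve_inverse(C, flu, full_pattern(3))
        assert est.rank_deficient  # 9 unknowns > 6 equations
        assert est.residual_norm < 1e-10
        assert est.n_equations == 6 and est.n_unknowns == 9

    def test_strict_mode_raises_on_rank_deficiency(self):
        C = np.eye(3)
        with pytest.raises(np.linalg.LinAlgError):
            solve_inverse(C, FluctuationSpec.identity(), full_pattern(3), strict=True)

    def test_flu_scale_equivariance(self):
        """Scaling FLU by c scales the reconstructed J by c, so signs and
        rankings are invariant to the overall fluctuation scale."""
        rng = np.random.default_rng(4)
        J, entries = random_stable_sparse_jacobian(rng, 4)
        flu1 = FluctuationSpec.diagonal([1.0, 2.0, 0.5, 1.5])
        C = solve_forward(J, flu1)
        pat = SparsityPattern(4, frozenset(entries))
        est1 = solve_inverse(C, flu1, pat)
        flu5 = FluctuationSpec.diagonal([5.0, 10.0, 2.5, 7.5])
        est5 = solve_inverse(C, flu5, pat)
        assert np.allclose(est5.values, 5.0 * est1.values, rtol=1e-8)

    def test_ridge_path_converges_to_lstsq(self):
        rng = np.random.default_rng(5)
        J, entries = random_stable_sparse_jacobian(rng, 4)
        flu = FluctuationSpec.identity()
        C = solve_forward(J, flu)
        pat = SparsityPattern(4, frozenset(entries))
        exact = solve_inverse(C, flu, pat)
        prev_err = np.inf
        for ridge in (1e-2, 1e-4, 1e-6, 1e-8):
            est = solve_inverse(C, flu, pat, ridge=ridge)
            err = np.abs(est.values - exact.values).max()
            assert err < prev_err + 1e-12
            prev_err = err
        assert prev_err < 1e-6

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="pattern"):
            solve_inverse(np.eye(3), FluctuationSpec.identity(), full_pattern(2))


def _scalar_net():
    return MetabolicNetwork([Species("A")], [], [("A", 10.0)], [("A", 1.0)])


def _ou_table(seed, n=100, k=1.0, sigma=1.0, mean=10.0):
    """Exact stationary OU samples (the estimator only sees the table)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(mean, np.sqrt(sigma**2 / (2 * k)), size=(n, 1))
    return MetaboliteTable([f"s{i}" for i in range(n)], ["c"] * n, ["A"], x)


class TestBootstrap:
    def test_constant_table_degenerate(self):
        net = _scalar_net()
        tab = MetaboliteTable(["a", "b", "c", "d"], ["c"] * 4, ["A"], np.full((4, 1), 2.0))
        with pytest.raises(RuntimeError, match="degenerate"):
            bootstrap_jacobian(tab, "c", net, FluctuationSpec.identity(), B=50, seed=0)

    def test_determinism(self):
        net = _scalar_net()
        tab = _ou_table(0)
        flu = FluctuationSpec.diagonal([0.5])
        a = bootstrap_jacobian(tab, "c", net, flu, B=60, seed=9)
        b = bootstrap_jacobian(tab, "c", net, flu, B=60, seed=9)
        assert np.array_equal(a.bootstrap_se, b.bootstrap_se)

    def test_bootstrap_se_close_to_monte_carlo_se(self):
        """Bootstrap SE of the scalar OU reconstruction within +-50% of the
        SD of the estimate over 50 independent datasets."""
        net = _scalar_net()
        flu = FluctuationSpec.diagonal([0.5])  # sigma^2/2 for sigma = 1
        est = bootstrap_jacobian(_ou_table(1), "c", net, flu, B=200, seed=1)
        mc = [
            solve_inverse(
                np.cov(_ou_table(100 + s).values, rowvar=False, ddof=1).reshape(1, 1),
                flu,
                jacobian_sparsity(net),
            ).values[0]
            for s in range(50)
        ]
        mc_sd = np.std(mc, ddof=1)
        assert 0.5 * mc_sd < est.bootstrap_se[0] < 1.5 * mc_sd

    def test_b_too_small(self):
        with pytest.raises(ValueError, match="B >= 50"):
            bootstrap_jacobian(_ou_table(0), "c", _scalar_net(),
                               FluctuationSpec.identity(), B=10, seed=0)


class TestDifferential:
    def test_identical_estimates_give_zero(self):
        net = _scalar_net()
        flu = FluctuationSpec.diagonal([0.5])
        est = bootstrap_jacobian(_ou_table(2), "c", net, flu, B=60, seed=2)
        rep = differential_jacobian(est, est, net)
        assert np.all(rep.delta == 0) and np.all(rep.z == 0)
        assert all(v == 0 for v in rep.pathway_scores.values())

    def test_pattern_mismatch_rejected(self, mannose_net):
        net = _scalar_net()
        flu = FluctuationSpec.diagonal([0.5])
        est = bootstrap_jacobian(_ou_table(3), "c", net, flu, B=60, seed=3)
        est2 = bootstrap_jacobian(_ou_table(4), "c", net, flu, B=60, seed=4)
        est2.pattern = jacobian_sparsity(mannose_net)
        with pytest.raises(ValueError):
            differential_jacobian(est, est2, net)

    def test_ranking_is_permutation_sorted_by_abs_z(self, mannose_net):
        from metajac.simulate import SimulationConfig, generate_study

        flu = FluctuationSpec.identity()
        cfg = SimulationConfig(net=mannose_net, n_replicates=40, seed=0,
                               conditions={"WT": {}, "AD": {"in:Man": 3.0}})
        tab = generate_study(cfg)
        ea = bootstrap_jacobian(tab, "WT", mannose_net, flu, B=60, seed=0)
        eb = bootstrap_jacobian(tab, "AD", mannose_net, flu, B=60, seed=1)
        rep = differential_jacobian(ea, eb, mannose_net)
        assert sorted(rep.ranking) == sorted(rep.entry_ids)
        zs = sorted(np.abs(rep.z))[::-1]
        ordered = [abs(rep.z[rep.entry_ids.index(e)]) for e in rep.ranking]
        assert np.allclose(ordered, zs)
        assert set(rep.pathway_scores) <= {"glycosylation", "glycolysis"}
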