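"""Hill-type force evaluation and static-optimization QP."""

import numpy as np
import pytest

from symphysim import muscles as mu


def _grid_oracle(R, Q, lo=0.01, hi=1.0, step=1e-3):
    """Exhaustive search over the activation cube for <=3 muscles.

    The first n-k activations are enumerated on the grid; the remaining k
    (k = number of axes) are solved exactly from the moment equalities, so
    every candidate satisfies the constraints to machine precision.
    """
    n_ax, n = R.shape
    assert n <= 3
    free = n - n_ax
    grid = np.arange(lo, hi + step / 2, step)
    # enumerate along the null-space direction with the largest component so
    # the feasible segment is well resolved by the grid
    if free == 1:
        _, _, vh = np.linalg.svd(R)
        null = vh[-1]
        order = np.argsort(np.abs(null))[::-1]
        perm = np.concatenate([order[:1], np.sort(order[1:])])
        obj, a = _grid_oracle_ordered(R[:, perm], Q, lo, hi, step)
        if a is None:
            return obj, a
        out = np.empty_like(a)
        out[perm] = a
        return obj, out
    return _grid_oracle_ordered(R, Q, lo, hi, step)


def _grid_oracle_ordered(R, Q, lo, hi, step):
    n_ax, n = R.shape
    free = n - n_ax
    grid = np.arange(lo, hi + step / 2, step)
    Rsq = R[:, free:]
    if free == 0:
        a = np.linalg.solve(Rsq, Q)
        if np.all(a >= lo - 1e-9) and np.all(a <= hi + 1e-9):
            return float(a @ a), a
        return np.inf, None
    mesh = np.meshgrid(*([grid] * free), indexing="ij")
    A_free = np.stack([m.ravel() for m in mesh])  # (free, G)
    rhs = Q[:, None] - R[:, :free] @ A_free  # (n_ax, G)
    A_dep = np.linalg.solve(Rsq, rhs)  # (n_ax, G)
    ok = np.all((A_dep >= lo - 1e-9) & (A_dep <= hi + 1e-9), axis=0)
    if not ok.any():
        return np.inf, None
    obj = (A_free**2).sum(axis=0) + (A_dep**2).sum(axis=0)
    obj[~ok] = np.inf
    k = int(np.argmin(obj))
    a = np.concatenate([A_free[:, k], A_dep[:, k]])
    return float(obj[k]), a


class TestHillForce:
    def test_all_factors_unity(self):
        m = mu.MuscleDef("m", F0=500.0, L_opt=80.0)
        assert mu.hill_force(m, 1.0) == pytest.approx(500.0)

    def test_linear_in_activation(self):
        m = mu.MuscleDef("m", F0=500.0)
        assert mu.hill_force(m, 0.5) == pytest.approx(0.5 * mu.hill_force(m, 1.0))

    def test_pennation_cosine(self):
        m = mu.MuscleDef("m", F0=100.0, alpha=np.pi / 3)
        assert mu.hill_force(m, 1.0) == pytest.approx(50.0)

    def test_force_length_off_optimum(self):
        m = mu.MuscleDef("m", F0=100.0, L_opt=100.0, L=145.0)
        expected = 100.0 * np.exp(-(0.45 / 0.45) ** 2)
        assert mu.hill_force(m, 1.0) == pytest.approx(expected)

    def test_force_velocity_at_rest_is_unity(self):
        assert mu.fv_hyperbolic(0.0) == pytest.approx(1.0)

    def test_activation_out_of_range(self):
        with pytest.raises(ValueError):
            mu.hill_force(mu.MuscleDef("m", 100.0), 1.5)


class TestStaticOptimization:
    def test_symmetric_pair_shares_equally(self):
        ms = [
            mu.MuscleDef("a", 100.0, moment_arms=[10.0]),
            mu.MuscleDef("b", 100.0, moment_arms=[10.0]),
        ]
        Q = 800.0
        sol = mu.solve_static_opt(mu.StaticOptProblem(ms, [Q]))
        expected = Q / (2 * 100.0 * 10.0)
        assert sol.a == pytest.approx([expected, expected], abs=1e-9)

    def test_zero_moment_single_muscle_projects_to_lower_bound(self):
        p = mu.StaticOptProblem([mu.MuscleDef("m", 50.0, moment_arms=[5.0])], [0.0])
        with pytest.raises(mu.InfeasibleMomentsError) as exc:
            mu.solve_static_opt(p)
        assert exc.value.solution.a == pytest.approx([0.01])

    def test_moment_balance_on_success(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(2, 6)
            k = rng.integers(1, 3)
            ms = [
                mu.MuscleDef(f"m{i}", rng.uniform(50, 500), moment_arms=rng.uniform(-20, 20, k))
                for i in range(n)
            ]
            R = mu.StaticOptProblem(ms, np.zeros(k)).moment_matrix()
            Q = R @ rng.uniform(0.05, 0.95, n)
            sol = mu.solve_static_opt(mu.StaticOptProblem(ms, Q))
            assert np.max(np.abs(R @ sol.a - Q)) <= 1e-6 * max(1.0, np.abs(Q).max())
            assert np.all(sol.a >= 0.01 - 1e-12) and np.all(sol.a <= 1 + 1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_exhaustive_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ms = [
            mu.MuscleDef(f"m{i}", rng.uniform(80, 300), moment_arms=rng.uniform(-15, 15, 2))
            for i in range(3)
        ]
        R = mu.StaticOptProblem(ms, [0, 0]).moment_matrix()
        Q = R @ rng.uniform(0.1, 0.8, 3)
        sol = mu.solve_static_opt(mu.StaticOptProblem(ms, Q))
        obj, a = _grid_oracle(R, Q)
        assert a is not None
        assert sol.objective <= obj + 1e-4
        assert np.max(np.abs(sol.a - a)) <= 2e-3

    def test_doubling_strength_halves_interior_activations(self):
        rng = np.random.default_rng(11)
        ms = [
            mu.MuscleDef(f"m{i}", rng.uniform(100, 300), moment_arms=rng.uniform(5, 15, 1))
            for i in range(4)
        ]
        Q = [2000.0]
        s1 = mu.solve_static_opt(mu.StaticOptProblem(ms, Q))
        ms2 = [
            mu.MuscleDef(m.name, 2 * m.F0, moment_arms=m.moment_arms) for m in ms
        ]
        s2 = mu.solve_static_opt(mu.StaticOptProblem(ms2, Q))
        interior = (s1.a > 0.011) & (s1.a < 0.999) & (s2.a > 0.011)
        assert interior.any()
        assert s2.a[interior] == pytest.approx(0.5 * s1.a[interior], rel=1e-6)

    def test_objective_monotone_in_moment_magnitude(self):
        ms = [
            mu.MuscleDef("a", 200.0, moment_arms=[12.0]),
            mu.MuscleDef("b", 150.0, moment_arms=[8.0]),
        ]
        objs = []
        for q in [500.0, 1000.0, 1500.0, 2000.0]:
            objs.append(mu.solve_static_opt(mu.StaticOptProblem(ms, [q])).objective)
        assert np.all(np.diff(objs) >= -1e-12)

    def test_infeasible_reports_minimal_residual(self):
        ms = [mu.MuscleDef("m", 10.0, moment_arms=[1.0])]
        with pytest.raises(mu.InfeasibleMomentsError) as exc:
            mu.solve_static_opt(mu.StaticOptProblem(ms, [1e6]))
        assert exc.value.solution.a == pytest.approx([1.0])


class TestForceTable:
    def test_rows_equal_hill_force(self):
        rng = np.random.default_rng(5)
        ms = [
            mu.MuscleDef(f"m{i}", rng.uniform(80, 300), moment_arms=rng.uniform(5, 15, 1))
            for i in range(3)
        ]
        sol = mu.solve_static_opt(mu.StaticOptProblem(ms, [1500.0]))
        table = mu.force_table(sol, ms)
        for (_, row), m, a in zip(table.iterrows(), ms, sol.a):
            assert row["force_N"] == pytest.approx(mu.hill_force(m, a))

    def test_symmetric_pair_equal_rows(self):
        ms = [
            mu.MuscleDef("a", 100.0, moment_arms=[10.0]),
            mu.MuscleDef("b", 100.0, moment_arms=[10.0]),
        ]
        sol = mu.solve_static_opt(mu.StaticOptProblem(ms, [600.0]))
        t = mu.force_table(sol, ms)
        assert t["force_N"].iloc[0] == pytest.approx(t["force_N"].iloc[1])

    def test_zero_force_length_factor_gives_zero_forces(self):
        ms = [mu.MuscleDef("m", 100.0, moment_arms=[10.0])]
        sol = mu.ActivationSolution(
            a=np.array([0.01]), forces=np.array([0.0]), residual=0.0, objective=1e-4
        )
        t = mu.force_table(sol, ms)
        assert t["force_N"].iloc[0] == 0.0


class TestStanceForceFixture:
    def test_fixture_shape_and_flags(self):
        from symphysim.stance_forces import standing_muscle_forces

        t = standing_muscle_forces()
        assert len(t) == 27
        assert (t["force_N"] >= 0).all()
        # typesetting artifacts preserved verbatim and flagged
        sart = t[t["name"] == "Sartorius"].iloc[0]
        assert sart["printed"] == "13.I" and sart["ambiguous"]
        assert sart["force_N"] == pytest.approx(13.1)
        gmax2 = t[t["name"] == "Gluteus maximus 2"].iloc[0]
        assert gmax2["printed"] == "27.IV" and gmax2["force_N"] == pytest.approx(27.4)
        # zero rows preserved
        assert (t["force_N"] == 0).sum() >= 8
        assert t[t["name"] == "Gluteus medius 1"]["force_N"].iloc[0] == pytest.approx(620.6)
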