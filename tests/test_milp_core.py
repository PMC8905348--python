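"""MILP assembly, single solve, objective re-evaluation, feasibility checking."""

import numpy as np
import pytest

import deltaflux as df
from deltaflux.milp_core import ProblemError, write_lp
from tests.conftest import chain_problem


class TestBuildProblem:
    @pytest.mark.parametrize("lam", [0.0, -0.5, 1.5])
    def test_lambda_range_enforced(self, lam, chain):
        net, ms, _ = chain
        bounds = df.build_bound_vectors(net, ms)
        with pytest.raises(ProblemError, match="lambda"):
            df.build_problem(net, bounds, lam)

    def test_cardinality_mode_flag(self, chain):
        net, ms, _ = chain
        bounds = df.build_bound_vectors(net, ms)
        p = df.build_problem(net, bounds, 1.0)
        assert p.cardinality_only

    def test_dimension_mismatch(self, chain):
        net, ms, _ = chain
        other = df.make_toy_network("chain", 5)
        bounds = df.build_bound_vectors(other, df.MeasurementSet(intervals={}))
        with pytest.raises(ProblemError, match="metabolites"):
            df.build_problem(net, bounds, 0.1)


class TestSolveOnce:
    def test_chain_worked_example(self, chain):
        """phi = (2,2), both reactions active, objective 0.1*2 - 0.9*(2+2) = -3.4."""
        _net, _ms, p = chain
        sol = df.solve_once(p)
        np.testing.assert_allclose(sol.phi, [2.0, 2.0], atol=1e-6)
        assert sol.support.all()
        assert sol.objective == pytest.approx(-3.4, abs=1e-6)
        assert sol.status == "optimal"
        np.testing.assert_allclose(sol.predicted_variation, [-2, 0, 2], atol=1e-6)

    def test_chain_cardinality_mode(self):
        _net, _ms, p = chain_problem(lam=1.0)
        sol = df.solve_once(p)
        assert sol.support.all()
        assert sol.objective == pytest.approx(2.0, abs=1e-6)

    def test_empty_measurements_zero_solution(self):
        net = df.make_toy_network("chain", 3)
        bounds = df.build_bound_vectors(net, df.MeasurementSet(intervals={}))
        p = df.build_problem(net, bounds, 0.1)
        sol = df.solve_once(p)
        assert not sol.support.any()
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_reports_measured(self):
        # demand production of M3 with the only producing reaction blocked
        net = df.make_toy_network("chain", 3)
        net, _ = df.block_boundary(net, [])  # no boundary here; block manually below
        ms = df.MeasurementSet(
            intervals={"M3": df.DeltaInterval("M3", 1.0, 2.0)}, epsilon=0.0
        )
        bounds = df.build_bound_vectors(net, ms)
        p = df.build_problem(net, bounds, 0.1)
        # epsilon = 0 forbids taking M2 down, and nothing produces M2 upstream
        # of r2 without also depleting M1 beyond its [0,0] band -> infeasible
        with pytest.raises(df.InfeasibleProblemError) as exc:
            df.solve_once(p)
        assert "M3" in exc.value.measured_ids

    def test_blocked_reaction_stays_out(self, chain):
        """Upper bound 0 excludes a reaction even when it is the only route."""
        net, ms, _ = chain
        from dataclasses import replace

        reactions = [replace(net.reactions[0], upper_bound=0.0), net.reactions[1]]
        blocked = df.SplitNetwork(
            base=df.MetabolicNetwork(net.metabolites, reactions),
            pair_map=[], origin_map=dict(net.origin_map),
        )
        bounds = df.build_bound_vectors(blocked, ms)
        p = df.build_problem(blocked, bounds, 0.1)
        with pytest.raises(df.InfeasibleProblemError):
            df.solve_once(p)

    def test_epsilon_slack_lands_on_unmeasured(self):
        """With M3 dropped and epsilon >= 2, r1 alone explains M1's depletion."""
        net = df.make_toy_network("chain", 3)
        ms = df.MeasurementSet(
            intervals={"M1": df.DeltaInterval("M1", -2.0, -2.0)}, epsilon=2.0
        )
        p = df.build_problem(net, df.build_bound_vectors(net, ms), 0.1)
        sol = df.solve_once(p)
        assert sol.support_ids(net) == ["r1"]
        assert sol.predicted_variation[1] == pytest.approx(2.0, abs=1e-6)


class TestEvaluateObjective:
    def test_matches_solver_objective(self, chain):
        _net, _ms, p = chain
        sol = df.solve_once(p)
        assert df.evaluate_objective(p, sol) == pytest.approx(sol.objective, abs=1e-9)

    def test_zero_solution(self, chain):
        net, _ms, p = chain
        zero = df.Solution(
            phi=np.zeros(2), support=np.zeros(2, bool), objective=0.0,
            predicted_variation=np.zeros(3), status="optimal",
        )
        assert df.evaluate_objective(p, zero) == 0.0

    def test_unmeasured_slack_costs(self):
        """One unit of slack on the unmeasured metabolite costs (1-lam)."""
        _net, _ms, p = chain_problem(epsilon=1.0)
        balanced = df.Solution(
            phi=np.array([2.0, 2.0]), support=np.ones(2, bool), objective=0.0,
            predicted_variation=np.zeros(3), status="optimal",
        )
        slack = df.Solution(
            phi=np.array([2.0, 1.0]), support=np.ones(2, bool), objective=0.0,
            predicted_variation=np.zeros(3), status="optimal",
        )
        lo = df.evaluate_objective(p, balanced)
        hi = df.evaluate_objective(p, slack)
        # losing a unit of explained M3 change and gaining a unit of slack on M2
        assert hi - lo == pytest.approx(0.9 * 2.0, abs=1e-9)


class TestCheckFeasibility:
    def test_solver_solution_clean(self, chain):
        _net, _ms, p = chain
        sol = df.solve_once(p)
        assert df.check_feasibility(p, sol) == []

    def test_bound_violation_detected(self, chain):
        _net, _ms, p = chain
        sol = df.solve_once(p)
        sol.phi = sol.phi.copy()
        sol.phi[0] += 1.0  # breaks the M1 interval and M2 conservation
        assert len(df.check_feasibility(p, sol)) >= 1

    def test_theta_link_violation(self, chain):
        net, _ms, p = chain
        sol = df.solve_once(p)
        sol.phi = sol.phi.copy()
        sol.phi[1] = p.theta / 10  # active but below theta
        violations = df.check_feasibility(p, sol)
        assert any("theta" in v for v in violations)

    def test_pair_exclusivity_detected(self):
        net = df.make_toy_network("reversible_pair", 2)
        ms = df.MeasurementSet(intervals={"M2": df.DeltaInterval("M2", 1.0, 1.0)})
        p = df.build_problem(net, df.build_bound_vectors(net, ms), 0.1)
        both = df.Solution(
            phi=np.array([1.0, 1.0]), support=np.ones(2, bool), objective=0.0,
            predicted_variation=net.S @ np.array([1.0, 1.0]), status="optimal",
        )
        assert any("pair" in v for v in df.check_feasibility(p, both))


class TestInvariants:
    def test_sign_correctness_at_optimum(self, chain):
        """s_i (S.phi)_i >= 0 on measured rows: the one-signed interval forces it."""
        _net, _ms, p = chain
        sol = df.solve_once(p)
        measured = p.bounds.measured_mask
        signed = p.bounds.sign[measured] * sol.predicted_variation[measured]
        assert np.all(signed >= -1e-9)

    def test_scale_covariance(self):
        """Scaling deltas and epsilon by c scales the continuous objective by c."""
        lam = 0.1
        base_net, _, p1 = chain_problem(lam=lam)
        sol1 = df.solve_once(p1)
        c = 7.0
        net = df.make_toy_network("chain", 3)
        ms = df.MeasurementSet(
            intervals={
                "M1": df.DeltaInterval("M1", -2 * c, -1 * c),
                "M3": df.DeltaInterval("M3", 1 * c, 2 * c),
            },
            epsilon=0.0,
        )
        p2 = df.build_problem(net, df.build_bound_vectors(net, ms), lam)
        sol2 = df.solve_once(p2)
        assert sol2.support_ids(net) == sol1.support_ids(base_net)
        card = lam * sol1.support.sum()
        assert sol2.objective - card == pytest.approx(c * (sol1.objective - card), rel=1e-6)

    def test_epsilon_zero_conservation(self, chain):
        _net, _ms, p = chain
        sol = df.solve_once(p)
        unmeasured = ~p.bounds.measured_mask
        assert np.all(np.abs(sol.predicted_variation[unmeasured]) <= 1e-6)


def test_lp_dump(tmp_path, chain):
    _net, _ms, p = chain
    path = tmp_path / "problem.lp"
    write_lp(p, str(path))
    text = path.read_text()
    assert "Minimize" in text and "Binaries" in text and "y_r1" in text
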