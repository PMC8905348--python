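import pytest

import deltaflux as df


def chain_problem(lam=0.1, epsilon=0.0, theta=1e-4):
    """The worked 2-reaction chain: M1 -> M2 -> M3, X = {M1:[-2,-1], M3:[1,2]}."""
    net = df.make_toy_network("chain", 3)
    ms = df.MeasurementSet(
        intervals={
            "M1": df.DeltaInterval("M1", -2.0, -1.0),
            "M3": df.DeltaInterval("M3", 1.0, 2.0),
        },
        epsilon=epsilon,
    )
    bounds = df.build_bound_vectors(net, ms)
    return net, ms, df.build_problem(net, bounds, lam, theta=theta)


def branch_problem(lam=0.1, epsilon=0.0):
    """Branch: r1 M1->M2 direct, r2 M1->M3, r3 M3->M2; X = {M1:[-1,-1], M2:[1,1]}."""
    net = df.make_toy_network("branch", 3)
    ms = df.MeasurementSet(
        intervals={
            "M1": df.DeltaInterval("M1", -1.0, -1.0),
            "M2": df.DeltaInterval("M2", 1.0, 1.0),
        },
        epsilon=epsilon,
    )
    bounds = df.build_bound_vectors(net, ms)
    return net, ms, df.build_problem(net, bounds, lam)


@pytest.fixture
def chain():
    return chain_problem()


@pytest.fixture
def branch():
    return branch_problem()


@pytest.fixture
def branch_solutions(branch):
    _net, _ms, p = branch
    return df.enumerate_solutions(p, 10)
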