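import numpy as np
import pytest

import pinpattern as pp


@pytest.fixture(scope="session")
def disc_small():
    """60-cell disc, enough structure for geometric checks."""
    return pp.generate_disc_tissue(60, 60.0, seed=3, relaxation_steps=5)


@pytest.fixture(scope="session")
def disc_study():
    """The ~400-cell, radius-60 disc used for the patterning experiments."""
    return pp.generate_disc_tissue(400, 60.0, seed=1, relaxation_steps=10)


@pytest.fixture(scope="session")
def ring100():
    return pp.generate_ring_tissue(100)


@pytest.fixture
def params():
    return pp.ModelParams()


def pin_ode_steady_state(P_tot, X, f_p, k_p, k_x=1.0):
    """Steady state of the explicit PIN1 endo/exocytosis exchange ODE.

    dP_ij/dt = k_x [(1 - k_p) + k_p X_j] P_i - k_n P_ij with cytosolic
    P_i = P_tot - sum_j P_ij and k_n = f_p * k_x.  Independent oracle
    for the closed-form quasi-equilibrium allocation.
    """
    from scipy.integrate import solve_ivp

    X = np.asarray(X, dtype=float)
    k_n = f_p * k_x
    w = 1.0 - k_p + k_p * X

    def rhs(_t, P):
        P_cyt = P_tot - P.sum()
        return k_x * w * P_cyt - k_n * P

    t_end = 60.0 / min(k_n, k_x)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        np.zeros(len(X)),
        method="LSODA",
        rtol=1e-12,
        atol=1e-14,
    )
    return sol.y[:, -1]
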