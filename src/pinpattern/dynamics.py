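"""Auxin / PIN1 / signal-X dynamics on a cell network.

The state of each cell i is its auxin concentration ``A_i``, total PIN1
``P_i_tot`` (cytosol + membranes) and polarizing-signal level ``X_i``.
Auxin moves between neighboring cells passively (coefficient ``D``) and
actively through membrane PIN1 (coefficient ``T``):

    dA_i/dt = c_A - d_A A_i
              + (1/V_i) [ D  sum_j a_ij (A_j - A_i)
                        + T  sum_j a_ij (P_ji A_j - P_ij A_i) ]
    dP_i_tot/dt = c_P - d_P P_i_tot
    dX_i/dt = V_X H+(A_i; K_XA, n_XA) H-(R_i; K_XR, n_XR)
                  H-(K_i; K_XK, n_XK) - d_X X_i

where H+ and H- are activating and repressing Hill functions.  X is
produced in response to auxin and repressed by the KAN and REV
prepattern fields; with K = R = 0 everywhere the repression factors are
identically 1 and the model reduces to the classical up-the-gradient
auxin/PIN1 feedback.

Membrane PIN1 is never an ODE state: PIN1 cycling between cytosol and
membrane sections is assumed fast (quasi-equilibrium), giving the
algebraic allocation

    P_ij = P_i_tot (1 - k_p + k_p X_j) / (f_p + sum_k (1 - k_p + k_p X_k))

recomputed from the instantaneous X at every derivative evaluation.
``f_p = k_n/k_x`` is the endocytosis/exocytosis rate ratio and ``k_p``
in [0, 1] weights polarized against symmetric exocytosis.  A cell with
high auxin raises X, which recruits PIN1 in its neighbors onto the
shared wall — the up-the-gradient feedback that destabilizes the
homogeneous state and forms auxin maxima.

Integration uses an adaptive embedded 5th-order Runge-Kutta pair
(Dormand-Prince, via scipy) from zero initial concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .prepattern import PrepatternField, null_prepattern
from .tissue import TissueGraph

__all__ = [
    "ModelParams",
    "SolverOptions",
    "NoiseSpec",
    "SystemState",
    "Trajectory",
    "IntegrationError",
    "pin_allocation",
    "rhs_auxin",
    "rhs_pin_total",
    "rhs_signal_x",
    "simulate",
    "steady_state",
]


class IntegrationError(RuntimeError):
    """Numerical failure during integration (step underflow, NaN/Inf)."""


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the auxin/PIN1/X model.

    Defaults are a calibrated patterning set: from zero initial
    conditions the uniform state (A* = c_A/d_A = 1, P* = c_P/d_P = 1,
    X* = 0.5) is unstable to the up-the-gradient feedback, so auxin
    maxima form spontaneously on irregular templates; repression
    half-maxes K_XR, K_XK sit well below the REV/KAN plateau levels so
    that expressing cells lose most of their X production.  The scan
    that produced these values ships as ``scripts/calibrate.py``.
    """

    c_A: float = 1.0      # auxin production
    d_A: float = 1.0      # auxin degradation
    D: float = 0.3        # passive transport coefficient
    T: float = 20.0       # active (PIN1-mediated) transport coefficient
    c_P: float = 1.0      # PIN1 production
    d_P: float = 1.0      # PIN1 degradation
    V_X: float = 1.0      # max X production
    K_XA: float = 1.0     # auxin half-max for X activation
    n_XA: float = 4.0
    K_XR: float = 0.5     # REV half-max for X repression
    n_XR: float = 4.0
    K_XK: float = 0.25    # KAN half-max for X repression
    n_XK: float = 2.0
    d_X: float = 1.0      # X degradation
    f_p: float = 1.0      # k_n / k_x, endo/exocytosis ratio
    k_p: float = 1.0      # polarized vs symmetric exocytosis weight

    def __post_init__(self) -> None:
        for name in ("c_A", "d_A", "D", "T", "c_P", "d_P", "V_X", "d_X"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.f_p <= 0:
            raise ValueError("f_p must be positive")
        if not 0.0 <= self.k_p <= 1.0:
            raise ValueError("k_p must lie in [0, 1]")
        for name in ("K_XA", "K_XR", "K_XK"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_XA", "n_XR", "n_XK"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class SolverOptions:
    """Adaptive Runge-Kutta settings."""

    rtol: float = 1e-6
    atol: float = 1e-9
    min_step: float = 1e-12
    max_step: float = np.inf
    n_output: int = 51           # evenly spaced sample times if output_times unset
    output_times: Sequence[float] | None = None


@dataclass(frozen=True)
class NoiseSpec:
    """Seeded multiplicative per-cell noise on c_A (symmetry breaking).

    ``c_A_i = c_A * exp(sd * z_i)`` with standard-normal z from the
    given seed.  Off by default; needed only on perfectly regular
    templates (rings), where the homogeneous state persists to machine
    precision from exactly zero initial conditions.
    """

    sd: float = 0.05
    seed: int = 0


@dataclass
class SystemState:
    """Per-cell concentrations at one time point.

    ``P_mem`` holds membrane PIN1 per directed wall, aligned with the
    directed-wall order of the tissue (all walls (i, j) followed by all
    reversed (j, i)); it is derived from X via the quasi-equilibrium
    allocation, not independent state.
    """

    t: float
    A: np.ndarray
    P_tot: np.ndarray
    X: np.ndarray
    P_mem: np.ndarray | None = None


@dataclass
class Trajectory:
    times: np.ndarray
    states: list[SystemState]
    solver_stats: dict = field(default_factory=dict)

    @property
    def final(self) -> SystemState:
        return self.states[-1]


# ---------------------------------------------------------------------------
# quasi-equilibrium PIN allocation
# ---------------------------------------------------------------------------


def pin_allocation(
    P_tot_i: float, X_neighbors: Sequence[float], f_p: float, k_p: float
) -> np.ndarray:
    """Membrane PIN1 of one cell on its walls, given neighbor X levels.

    Returns ``P_ij = P_tot_i w_j / (f_p + sum_k w_k)`` with
    ``w_j = 1 - k_p + k_p X_j``, the steady state of fast PIN1 cycling.
    The cytosolic remainder is ``P_tot_i f_p / (f_p + sum_k w_k)``.
    """
    if f_p <= 0:
        raise ValueError("f_p must be positive")
    if not 0.0 <= k_p <= 1.0:
        raise ValueError("k_p must lie in [0, 1]")
    if P_tot_i < 0:
        raise ValueError("P_tot must be non-negative")
    X = np.asarray(X_neighbors, dtype=float)
    w = 1.0 - k_p + k_p * X
    return P_tot_i * w / (f_p + w.sum())


# ---------------------------------------------------------------------------
# vectorized geometry cache and RHS
# ---------------------------------------------------------------------------


class _Geometry:
    """Index arrays for vectorized flux sums on a tissue graph.

    Directed walls are ordered: for undirected wall index w of (i, j),
    directed index w is (i -> j) and w + n_walls is (j -> i).
    """

    def __init__(self, tissue: TissueGraph):
        wi, wj = tissue.wall_index_arrays()
        self.n = tissue.n_cells
        self.n_walls = len(wi)
        self.di = np.concatenate([wi, wj])   # source cell of directed wall
        self.dj = np.concatenate([wj, wi])   # target cell
        self.areas = np.concatenate([tissue.wall_areas, tissue.wall_areas])
        self.V = tissue.volumes

    def neighbor_sum(self, values_by_target: np.ndarray) -> np.ndarray:
        """sum_{j in N_i} values[j] for each i."""
        return np.bincount(self.di, weights=values_by_target[self.dj], minlength=self.n)

    def pin_membrane(self, P_tot: np.ndarray, X: np.ndarray, f_p: float, k_p: float):
        w = 1.0 - k_p + k_p * X
        S = f_p + self.neighbor_sum(w)
        P_dir = P_tot[self.di] * w[self.dj] / S[self.di]
        return P_dir

    def reversed_walls(self, P_dir: np.ndarray) -> np.ndarray:
        return np.concatenate([P_dir[self.n_walls:], P_dir[: self.n_walls]])


def _hill_up(x, K, n):
    z = np.power(np.maximum(np.asarray(x, dtype=float), 0.0) / K, n)
    return z / (1.0 + z)


def _hill_down(x, K, n):
    return 1.0 / (1.0 + np.power(np.maximum(np.asarray(x, dtype=float), 0.0) / K, n))


def _x_production(A, K_field, R_field, p: ModelParams):
    return (
        p.V_X
        * _hill_up(A, p.K_XA, p.n_XA)
        * _hill_down(R_field, p.K_XR, p.n_XR)
        * _hill_down(K_field, p.K_XK, p.n_XK)
    )


def _rhs_arrays(
    A: np.ndarray,
    P_tot: np.ndarray,
    X: np.ndarray,
    geom: _Geometry,
    pre: PrepatternField,
    p: ModelParams,
    c_A_cell: np.ndarray,
):
    P_dir = geom.pin_membrane(P_tot, X, p.f_p, p.k_p)
    P_rev = geom.reversed_walls(P_dir)
    Ai, Aj = A[geom.di], A[geom.dj]
    passive = geom.areas * (Aj - Ai)
    active = geom.areas * (P_rev * Aj - P_dir * Ai)
    transport = (
        p.D * np.bincount(geom.di, weights=passive, minlength=geom.n)
        + p.T * np.bincount(geom.di, weights=active, minlength=geom.n)
    ) / geom.V
    dA = c_A_cell - p.d_A * A + transport
    dP = p.c_P - p.d_P * P_tot
    dX = _x_production(A, pre.K, pre.R, p) - p.d_X * X
    return dA, dP, dX


# public per-equation RHS (thin wrappers over the vectorized core)


def rhs_auxin(state: SystemState, tissue: TissueGraph, params: ModelParams) -> np.ndarray:
    """dA_i/dt for the current state.

    Membrane PIN1 is taken from ``state.P_mem`` when present (directed
    wall order), otherwise recomputed from X via the quasi-equilibrium
    allocation.
    """
    if len(state.A) != tissue.n_cells:
        raise ValueError("state/tissue size mismatch")
    geom = _Geometry(tissue)
    if state.P_mem is not None:
        P_dir = np.asarray(state.P_mem, dtype=float)
        if P_dir.shape != (2 * geom.n_walls,):
            raise ValueError("P_mem/tissue size mismatch")
    else:
        P_dir = geom.pin_membrane(state.P_tot, state.X, params.f_p, params.k_p)
    P_rev = geom.reversed_walls(P_dir)
    A = state.A
    passive = geom.areas * (A[geom.dj] - A[geom.di])
    active = geom.areas * (P_rev * A[geom.dj] - P_dir * A[geom.di])
    transport = (
        params.D * np.bincount(geom.di, weights=passive, minlength=geom.n)
        + params.T * np.bincount(geom.di, weights=active, minlength=geom.n)
    ) / geom.V
    return params.c_A - params.d_A * A + transport


def rhs_pin_total(state: SystemState, params: ModelParams) -> np.ndarray:
    """dP_i_tot/dt = c_P - d_P P_i_tot."""
    return params.c_P - params.d_P * state.P_tot


def rhs_signal_x(
    state: SystemState, prepattern: PrepatternField | None, params: ModelParams
) -> np.ndarray:
    """dX_i/dt: auxin-activated, KAN/REV-repressed production minus decay."""
    pre = prepattern if prepattern is not None else null_prepattern(len(state.A))
    return _x_production(state.A, pre.K, pre.R, params) - params.d_X * state.X


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def simulate(
    tissue: TissueGraph,
    prepattern: PrepatternField | None,
    params: ModelParams,
    t_end: float,
    solver_opts: SolverOptions | None = None,
    perturbation: NoiseSpec | None = None,
    initial_state: SystemState | None = None,
) -> Trajectory:
    """Integrate the coupled (A, P_tot, X) system.

    Initial concentrations are zero in all compartments unless an
    explicit ``initial_state`` is supplied (used e.g. for closed-system
    mass-conservation runs).  ``prepattern=None`` runs the unrepressed
    model (K = R = 0).  The optional ``perturbation`` applies seeded
    multiplicative noise to c_A per cell.  Membrane PIN1 is recomputed
    algebraically inside every derivative evaluation and attached to
    each sampled state.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    opts = solver_opts or SolverOptions()
    pre = prepattern if prepattern is not None else null_prepattern(tissue.n_cells)
    if len(pre.K) != tissue.n_cells:
        raise ValueError("prepattern/tissue size mismatch")
    geom = _Geometry(tissue)
    n = tissue.n_cells

    c_A_cell = np.full(n, params.c_A)
    if perturbation is not None:
        rng = np.random.default_rng(perturbation.seed)
        c_A_cell = c_A_cell * np.exp(perturbation.sd * rng.standard_normal(n))

    def rhs(t, y):
        A, P_tot, X = y[:n], y[n : 2 * n], y[2 * n :]
        dA, dP, dX = _rhs_arrays(A, P_tot, X, geom, pre, params, c_A_cell)
        return np.concatenate([dA, dP, dX])

    if initial_state is not None:
        if any(np.any(v < 0) for v in (initial_state.A, initial_state.P_tot, initial_state.X)):
            raise ValueError("initial concentrations must be non-negative")
        y0 = np.concatenate([initial_state.A, initial_state.P_tot, initial_state.X])
        if y0.shape != (3 * n,):
            raise ValueError("initial_state/tissue size mismatch")
    else:
        y0 = np.zeros(3 * n)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method="RK45",
        rtol=opts.rtol,
        atol=opts.atol,
        max_step=opts.max_step,
        dense_output=True,
    )
    if sol.status == -1 or not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1]:.6g}: {sol.message}"
        )
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationError("non-finite values in solution")
    accepted = len(sol.t) - 1
    steps = np.diff(sol.t)
    if accepted > 0 and np.min(steps) < opts.min_step:
        raise IntegrationError(
            f"step size underflow (min step {np.min(steps):.3g} < {opts.min_step})"
        )
    # RK45 is FSAL: ~6 evaluations per accepted step, ~5 per rejection
    rejected_est = max(0, round((sol.nfev - 1 - 6 * accepted) / 5))

    if opts.output_times is not None:
        t_out = np.asarray(opts.output_times, dtype=float)
    else:
        t_out = np.linspace(0.0, t_end, opts.n_output)
    y_out = sol.sol(t_out)

    states = []
    for k, t in enumerate(t_out):
        A = y_out[:n, k]
        P_tot = y_out[n : 2 * n, k]
        X = y_out[2 * n :, k]
        P_mem = geom.pin_membrane(P_tot, X, params.f_p, params.k_p)
        states.append(SystemState(t=float(t), A=A, P_tot=P_tot, X=X, P_mem=P_mem))

    min_val = float(y_out.min(initial=0.0))
    stats = {
        "n_accepted": accepted,
        "n_rejected_est": int(rejected_est),
        "nfev": int(sol.nfev),
        "final_step": float(sol.t[-1] - sol.t[-2]) if accepted > 0 else 0.0,
        "min_state_value": min_val,
    }
    return Trajectory(times=t_out, states=states, solver_stats=stats)


def steady_state(
    trajectory: Trajectory, window: int = 5, tol: float = 1e-4
) -> SystemState | None:
    """Final state if auxin has settled over the trailing window, else None.

    Convergence: the max relative change of any cell's A across the last
    ``window`` sampled states is below ``tol`` (relative to the largest
    final auxin level, floored to avoid division by zero).
    """
    if len(trajectory.states) < window:
        raise ValueError("trajectory shorter than window")
    A_end = trajectory.final.A
    scale = max(float(np.max(np.abs(A_end), initial=0.0)), 1e-300)
    for st in trajectory.states[-window:]:
        if np.max(np.abs(st.A - A_end)) / scale >= tol:
            return None
    return trajectory.final
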