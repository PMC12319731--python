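"""Network control theory on structural connectomes.

The connectome is turned into a stable continuous-time linear system
x' = A_norm x + B u with A_norm = A / (lambda_max(A) + c) - I, and the
optimal control steering the system from a source brain state x0 to a
target state xf over horizon T is found by minimising

    J = int_0^T ( x(t)' S x(t) + rho * u(t)' u(t) ) dt,

a two-point boundary-value problem solved exactly through the Hamiltonian
block matrix exponential. With the uniform full control set B = I the
per-region control energy int_0^T u_i(t)^2 dt measures how strongly each
region must be driven to realise the transition; S = I weights the whole
state trajectory, and rho balances input energy against trajectory
magnitude (rho = 1 weighs them equally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.linalg import expm, solve

__all__ = [
    "ControlEnergyResult",
    "consensus_threshold",
    "normalize_adjacency",
    "optimal_control",
    "transition_energy",
]


@dataclass
class ControlEnergyResult:
    """Solution of one optimal state transition.

    per_region_energy : int_0^T u_i(t)^2 dt for every region
    total_energy      : sum of per-region energies
    times             : uniform grid over [0, T]
    state_trajectory  : x(t) on the grid, shape (n_grid, N)
    control_trajectory: u(t) on the grid, shape (n_grid, N)
    terminal_error    : || x(T) - xf ||_2
    """

    per_region_energy: np.ndarray
    total_energy: float
    times: np.ndarray
    state_trajectory: np.ndarray
    control_trajectory: np.ndarray
    terminal_error: float


def _check_connectome(a: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("connectome must be square")
    if not np.isfinite(a).all():
        raise ValueError("connectome has non-finite entries")
    if np.abs(a - a.T).max() > tol:
        raise ValueError("connectome must be symmetric")
    if (a < 0).any():
        raise ValueError("connectome weights must be non-negative")
    return a


def consensus_threshold(cohort_A: list[np.ndarray], fraction: float = 0.5
                        ) -> tuple[list[np.ndarray], np.ndarray]:
    """Keep edges present (nonzero) in at least `fraction` of subjects.

    The boundary is inclusive: an edge in exactly fraction*n subjects stays.
    Returns the masked cohort and the boolean consensus mask.
    """
    if not cohort_A:
        raise ValueError("empty cohort")
    mats = [_check_connectome(a) for a in cohort_A]
    shapes = {a.shape for a in mats}
    if len(shapes) > 1:
        raise ValueError("all connectomes must share the same region count")
    presence = np.mean([a != 0 for a in mats], axis=0)
    mask = presence >= fraction
    np.fill_diagonal(mask, False)
    return [a * mask for a in mats], mask


def normalize_adjacency(A: np.ndarray, c: float = 1.0) -> np.ndarray:
    """A_norm = A / (lambda_max(A) + c) - I; all eigenvalues strictly stable.

    The spectral shift places the largest eigenvalue of A_norm at
    -c / (lambda_max + c) < 0, so activity decays in the absence of input.
    """
    A = _check_connectome(A)
    lam_max = float(np.linalg.eigvalsh(A)[-1])
    return A / (lam_max + c) - np.eye(A.shape[0])


def optimal_control(
    A_norm: np.ndarray,
    x0: np.ndarray,
    xf: np.ndarray,
    T: float = 1.0,
    rho: float = 1.0,
    B: np.ndarray | None = None,
    S: np.ndarray | None = None,
    n_grid: int = 1001,
    terminal_tol: float = 1e-6,
) -> ControlEnergyResult:
    """Continuous-time optimal control between two states.

    Pontryagin's conditions give u = -B'p / (2 rho) and the linear
    Hamiltonian system d/dt [x; p] = M [x; p] with
    M = [[A, -B B'/(2 rho)], [-2 S, -A']]. The unknown initial costate p0
    is found from the terminal condition x(T) = xf via the partitioned
    matrix exponential of M T; trajectories are rolled out on a uniform
    grid and energies integrated by composite Simpson quadrature (n_grid
    must be odd).
    """
    A_norm = np.asarray(A_norm, dtype=float)
    n = A_norm.shape[0]
    x0 = np.asarray(x0, dtype=float).reshape(n)
    xf = np.asarray(xf, dtype=float).reshape(n)
    if rho <= 0 or T <= 0:
        raise ValueError("rho and T must be positive")
    if n_grid < 3 or n_grid % 2 == 0:
        raise ValueError("n_grid must be odd and >= 3 for Simpson quadrature")
    if np.max(np.real(np.linalg.eigvals(A_norm))) >= 0:
        raise ValueError("A_norm must be stable (all eigenvalue real parts < 0)")
    B = np.eye(n) if B is None else np.asarray(B, dtype=float)
    S = np.eye(n) if S is None else np.asarray(S, dtype=float)

    M = np.block([[A_norm, -B @ B.T / (2.0 * rho)],
                  [-2.0 * S, -A_norm.T]])
    E = expm(M * T)
    E11, E12 = E[:n, :n], E[:n, n:]
    cond = np.linalg.cond(E12)
    if not np.isfinite(cond):
        raise np.linalg.LinAlgError(
            f"singular boundary-condition solve at horizon T={T}; try a shorter horizon"
        )
    if cond > 1e10:
        warnings.warn(f"ill-conditioned boundary solve (cond~{cond:.2e}) at horizon T={T}",
                      RuntimeWarning, stacklevel=2)
    p0 = solve(E12, xf - E11 @ x0)

    dt = T / (n_grid - 1)
    Ed = expm(M * dt)
    z = np.empty((n_grid, 2 * n))
    z[0] = np.concatenate([x0, p0])
    for k in range(1, n_grid):
        z[k] = Ed @ z[k - 1]
    x = z[:, :n]
    u = -(z[:, n:] @ B) / (2.0 * rho)
    terminal_error = float(np.linalg.norm(x[-1] - xf))
    if terminal_error > terminal_tol:
        raise RuntimeError(
            f"terminal reconstruction error {terminal_error:.3e} exceeds {terminal_tol:.1e}"
        )
    per_region = simpson(u ** 2, dx=dt, axis=0)
    per_region = np.maximum(per_region, 0.0)
    return ControlEnergyResult(
        per_region_energy=per_region,
        total_energy=float(per_region.sum()),
        times=np.arange(n_grid) * dt,
        state_trajectory=x,
        control_trajectory=u,
        terminal_error=terminal_error,
    )


def binarize_pattern(x: np.ndarray) -> np.ndarray:
    """Positive entries -> 1, everything else -> 0."""
    return (np.asarray(x, dtype=float) > 0).astype(float)


def transition_energy(
    sc: np.ndarray,
    centroids: np.ndarray,
    from_state: int,
    to_state: int,
    T: float = 1.0,
    rho: float = 1.0,
    c: float = 1.0,
    binarize_states: bool = False,
    n_grid: int = 1001,
) -> ControlEnergyResult:
    """Per-region optimal control energy for one centroid-to-centroid
    transition on one connectome (uniform full control set, S = I).

    `from_state`/`to_state` are 1-based state indices into `centroids`.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    k, n = centroids.shape
    if not (1 <= from_state <= k and 1 <= to_state <= k):
        raise ValueError(f"state indices must be in 1..{k}")
    sc = _check_connectome(sc)
    if sc.shape[0] != n:
        raise ValueError(
            f"connectome has {sc.shape[0]} regions but centroids have {n}"
        )
    x0 = centroids[from_state - 1]
    xf = centroids[to_state - 1]
    if binarize_states:
        x0, xf = binarize_pattern(x0), binarize_pattern(xf)
    return optimal_control(normalize_adjacency(sc, c=c), x0, xf, T=T, rho=rho, n_grid=n_grid)
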