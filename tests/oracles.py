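"""Independent reference implementations used only by the tests.

These are deliberately naive: brute-force loops for the cluster-validity
indices and a direct equality-constrained quadratic program over
piecewise-constant controls for the optimal-control cost. They share no
code with the package paths they check.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


# ---------------------------------------------------------------------------
# Cluster validity by brute force

def brute_dunn(points: np.ndarray, labels: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = len(points)
    inter, diam = np.inf, 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(points[i] - points[j])
            if labels[i] == labels[j]:
                diam = max(diam, d)
            else:
                inter = min(inter, d)
    if diam <= 0:
        diam = np.finfo(float).eps
    return inter / diam


def brute_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = len(points)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not own:  # singleton cluster contributes 0
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in own])
        b = np.inf
        for lab in set(labels.tolist()):
            if lab == labels[i]:
                continue
            other = [j for j in range(n) if labels[j] == lab]
            b = min(b, np.mean([np.linalg.norm(points[i] - points[j]) for j in other]))
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def brute_calinski_harabasz(points: np.ndarray, labels: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = len(points)
    labs = sorted(set(labels.tolist()))
    k = len(labs)
    grand = points.mean(axis=0)
    between = sum(
        (labels == lab).sum() * np.sum((points[labels == lab].mean(axis=0) - grand) ** 2)
        for lab in labs
    )
    within = sum(
        np.sum((points[labels == lab] - points[labels == lab].mean(axis=0)) ** 2)
        for lab in labs
    )
    return float((between / (k - 1)) / (within / (n - k)))


# ---------------------------------------------------------------------------
# Optimal-control cost by discretized-control quadratic programming

def discretized_control_energy(
    A: np.ndarray,
    x0: np.ndarray,
    xf: np.ndarray,
    T: float = 1.0,
    rho: float = 1.0,
    n_steps: int = 400,
) -> tuple[float, float]:
    """(total input energy, total cost) of the optimal piecewise-constant
    control steering x' = A x + u from x0 to xf while minimising
    int (x'x + rho u'u) dt.

    Controls are constant on each of `n_steps` intervals; the state recursion
    uses the exact zero-order-hold discretization, the terminal state is an
    equality constraint, the trajectory term uses trapezoid quadrature over
    the nodes, and the resulting equality-constrained QP is solved through
    its KKT system. Converges to the continuous optimum at O(dt^2).
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    x0 = np.asarray(x0, dtype=float).reshape(n)
    xf = np.asarray(xf, dtype=float).reshape(n)
    dt = T / n_steps
    Ad = expm(A * dt)
    aug = np.zeros((2 * n, 2 * n))
    aug[:n, :n] = A
    aug[:n, n:] = np.eye(n)
    Bd = expm(aug * dt)[:n, n:]

    # x_k = Ad^k x0 + sum_{j<k} Ad^{k-1-j} Bd u_j ;  stack nodes k=0..n_steps
    powers = [np.eye(n)]
    for _ in range(n_steps):
        powers.append(Ad @ powers[-1])
    g = np.concatenate([p @ x0 for p in powers])
    F = np.zeros(((n_steps + 1) * n, n_steps * n))
    for k in range(1, n_steps + 1):
        for j in range(k):
            F[k * n:(k + 1) * n, j * n:(j + 1) * n] = powers[k - 1 - j] @ Bd

    w = np.ones(n_steps + 1)
    w[0] = w[-1] = 0.5
    Wdiag = np.repeat(w * dt, n)           # S = I
    H = 2.0 * (F.T * Wdiag) @ F + 2.0 * rho * dt * np.eye(n_steps * n)
    f = 2.0 * (F.T * Wdiag) @ g
    C = F[-n:, :]
    kkt = np.block([[H, C.T], [C, np.zeros((n, n))]])
    rhs = np.concatenate([-f, xf - g[-n:]])
    sol = np.linalg.solve(kkt, rhs)
    u = sol[: n_steps * n].reshape(n_steps, n)

    energy = float(rho_free_energy(u, dt))
    x = (F @ sol[: n_steps * n] + g).reshape(n_steps + 1, n)
    cost = float(np.sum(w * np.sum(x ** 2, axis=1)) * dt + rho * energy)
    return energy, cost


def rho_free_energy(u: np.ndarray, dt: float) -> float:
    """Exact integral of |u(t)|^2 for piecewise-constant u."""
    return float(np.sum(u ** 2) * dt)
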