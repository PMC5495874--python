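"""Smoothed-aggregation algebraic multigrid preconditioner.

A compact SA-AMG implementation for the symmetric positive-definite systems
arising from the grounded FE discretization of the EEG/MEG forward problem.
Used as the preconditioner inside conjugate gradients (AMG-CG).

The setup follows the classical smoothed-aggregation recipe: a strength
graph filters weak couplings, greedy aggregation builds piecewise-constant
tentative prolongators, one damped-Jacobi smoothing step improves them, and
Galerkin triple products define the coarse operators.  V-cycles use
symmetric damped-Jacobi smoothing so the preconditioner is SPD, as CG
requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator

__all__ = ["AMGPreconditioner"]


def _strength_graph(A: sparse.csr_matrix, theta: float) -> sparse.csr_matrix:
    """Symmetric strength-of-connection filter: keep |a_ij| >= theta*sqrt(a_ii*a_jj)."""
    d = np.sqrt(np.abs(A.diagonal()))
    d[d == 0] = 1.0
    C = A.tocoo()
    mask = (C.row != C.col) & (np.abs(C.data) >= theta * d[C.row] * d[C.col])
    S = sparse.csr_matrix(
        (np.ones(mask.sum()), (C.row[mask], C.col[mask])), shape=A.shape
    )
    return S


def _aggregate(S: sparse.csr_matrix) -> np.ndarray:
    """Greedy aggregation on the strength graph; returns aggregate id per node."""
    n = S.shape[0]
    agg = np.full(n, -1, dtype=np.int64)
    indptr, indices = S.indptr, S.indices
    next_agg = 0
    # pass 1: nodes whose strong neighborhood is untouched seed a new aggregate
    for i in range(n):
        if agg[i] != -1:
            continue
        nbrs = indices[indptr[i] : indptr[i + 1]]
        if np.all(agg[nbrs] == -1):
            agg[i] = next_agg
            agg[nbrs] = next_agg
            next_agg += 1
    # pass 2: attach stragglers to an adjacent aggregate
    for i in range(n):
        if agg[i] != -1:
            continue
        nbrs = indices[indptr[i] : indptr[i + 1]]
        hit = agg[nbrs]
        hit = hit[hit != -1]
        if len(hit):
            agg[i] = hit[0]
    # pass 3: isolated leftovers become singletons
    for i in range(n):
        if agg[i] == -1:
            agg[i] = next_agg
            next_agg += 1
    return agg


@dataclass
class _Level:
    A: sparse.csr_matrix
    P: sparse.csr_matrix
    dinv: np.ndarray
    omega: float  # Jacobi smoothing damping / rho(D^-1 A)


class AMGPreconditioner:
    """SPD V-cycle preconditioner; callable and usable as a LinearOperator.

    Parameters
    ----------
    A
        Sparse SPD matrix (the grounded FE stiffness matrix).
    theta
        Strength-of-connection threshold.
    max_coarse
        Recursion stops when a level has at most this many unknowns; the
        coarsest system is solved densely (Cholesky).
    presmooth, postsmooth
        Number of damped-Jacobi sweeps on each side of the coarse correction.
    """

    def __init__(
        self,
        A: sparse.spmatrix,
        theta: float = 0.02,
        max_coarse: int = 600,
        max_levels: int = 12,
        presmooth: int = 2,
        postsmooth: int = 2,
        seed: int = 0,
    ):
        A = sparse.csr_matrix(A)
        self.shape = A.shape
        self.dtype = A.dtype
        self.presmooth = presmooth
        self.postsmooth = postsmooth
        self.levels: list[_Level] = []
        rng = np.random.default_rng(seed)
        while A.shape[0] > max_coarse and len(self.levels) < max_levels:
            dinv = 1.0 / A.diagonal()
            rho = self._rho_dinv_a(A, dinv, rng)
            S = _strength_graph(A, theta)
            agg = _aggregate(S)
            nc = int(agg.max()) + 1
            if nc >= A.shape[0]:  # aggregation stalled
                break
            T = sparse.csr_matrix(
                (np.ones(A.shape[0]), (np.arange(A.shape[0]), agg)),
                shape=(A.shape[0], nc),
            )
            # normalize tentative prolongator columns
            colnorm = np.sqrt(np.asarray(T.multiply(T).sum(axis=0)).ravel())
            T = T @ sparse.diags(1.0 / colnorm)
            # prolongator smoothing: P = (I - 4/(3 rho) D^-1 A) T
            DA = sparse.diags(dinv) @ A
            P = (T - (4.0 / (3.0 * rho)) * (DA @ T)).tocsr()
            self.levels.append(_Level(A=A, P=P, dinv=dinv, omega=4.0 / (3.0 * rho)))
            A = (P.T @ A @ P).tocsr()
            A.eliminate_zeros()
        # dense coarse solve (SPD after grounding)
        from scipy.linalg import cho_factor

        Ad = A.toarray()
        # tiny diagonal lift guards against semi-definiteness from aggregation round-off
        Ad[np.diag_indices_from(Ad)] *= 1.0 + 1e-12
        self._coarse = cho_factor(Ad, lower=True)
        self._coarse_n = Ad.shape[0]

    @staticmethod
    def _rho_dinv_a(A, dinv, rng, iters: int = 12) -> float:
        """Power-iteration estimate of rho(D^-1 A), slightly inflated."""
        x = rng.standard_normal(A.shape[0])
        x /= np.linalg.norm(x)
        rho = 1.0
        for _ in range(iters):
            y = dinv * (A @ x)
            ny = np.linalg.norm(y)
            if ny == 0:
                break
            rho = ny
            x = y / ny
        return 1.1 * rho

    def _cycle(self, level: int, b: np.ndarray) -> np.ndarray:
        if level == len(self.levels):
            from scipy.linalg import cho_solve

            return cho_solve(self._coarse, b)
        lv = self.levels[level]
        x = np.zeros_like(b)
        for _ in range(self.presmooth):
            x += lv.omega * lv.dinv * (b - lv.A @ x)
        r = b - lv.A @ x
        x += lv.P @ self._cycle(level + 1, lv.P.T @ r)
        for _ in range(self.postsmooth):
            x += lv.omega * lv.dinv * (b - lv.A @ x)
        return x

    def __call__(self, b: np.ndarray) -> np.ndarray:
        return self._cycle(0, np.asarray(b, float))

    def as_linear_operator(self) -> LinearOperator:
        return LinearOperator(self.shape, matvec=self, dtype=float)

    @property
    def n_levels(self) -> int:
        return len(self.levels) + 1

    def grid_complexity(self) -> float:
        """Sum of level sizes relative to the fine level."""
        n0 = self.levels[0].A.shape[0] if self.levels else self._coarse_n
        total = sum(lv.A.shape[0] for lv in self.levels) + self._coarse_n
        return total / n0
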