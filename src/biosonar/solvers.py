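"""Proximal solvers for the sparsity-aware imaging programs.

Two convex programs are solved, one per operating mode:

* vector form    min ||g||_p   s.t.  sum_i ||y_i - A_i g||_2^2 <= eps
* row-group form min ||G||_p,2 s.t.  sum_i ||x_i - B_i G[:, i]||_2^2 <= eps

with complex unknowns and p >= 1.  Both are handled by an accelerated
proximal-gradient (FISTA) iteration on the penalized Lagrangian

    min_g  1/2 ||.||^2 residual  +  lam * sum_n phi(|g_n|),   phi(r) = r^p,

combined with a monotone search over the penalty ``lam`` so the returned
solution meets the residual-energy budget ``eps`` (the constraint is
active at the optimum whenever the zero solution is infeasible, and the
residual of the penalized path is monotone in ``lam``).  Minimizing
``sum phi(|g_n|)`` under the constraint selects the same minimizers as
the p-norm itself (monotone transform).

The scalar proximal map of ``t * r^p`` is soft thresholding at p = 1, has
a closed form at p = 2, and is solved by a vectorized bisection otherwise
(the optimality equation ``r + t p r^(p-1) = u`` is strictly monotone).

Complex unknowns are supported natively, or through real/imaginary
stacking where each voxel becomes a group of 2 (or 2F) real variables;
the two routes are mathematically identical and are cross-checked in the
test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class SolverError(RuntimeError):
    """Solver failed to produce a feasible solution; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class SolveResult:
    solution: np.ndarray          # (N,) complex or (N, F) complex
    status: str                   # "optimal" | "zero-feasible"
    residual: float               # realized residual energy
    epsilon: float
    objective: float              # p-norm (or (p,2)-norm) of the solution
    lam: float
    n_iterations: int
    lipschitz: float


def prox_power(u: np.ndarray, t: float, p: float) -> np.ndarray:
    """Proximal map of ``t * r^p`` on r >= 0: argmin t r^p + (r-u)^2 / 2."""
    u = np.asarray(u, float)
    if p == 1.0:
        return np.maximum(u - t, 0.0)
    if p == 2.0:
        return u / (1.0 + 2.0 * t)
    # monotone scalar equation r + t p r^(p-1) = u solved by Newton.
    # f(r) = r + c r^q - u is increasing and concave for 1 < p < 2, so
    # after at most one overshoot (clamped away from zero) the iteration
    # converges monotonically from the left.
    c = t * p
    q = p - 1.0
    out = np.zeros_like(u)
    pos = u > 0
    if not pos.any():
        return out
    uv = u[pos]
    lo = np.zeros_like(uv)
    hi = uv.copy()
    # start from whichever regime dominates: r ~ u (penalty negligible)
    # or r ~ (u/c)^(1/q) (penalty dominates); the safeguarded bracket
    # keeps either start safe
    with np.errstate(over="ignore"):
        alt = (uv / c) ** (1.0 / q) if q > 0 else np.zeros_like(uv)
    r = np.minimum(uv, np.where(np.isfinite(alt), alt, uv))
    for _ in range(25):
        rq = r ** q
        f = r + c * rq - uv
        above = f > 0
        hi = np.where(above, r, hi)
        lo = np.where(above, lo, r)
        newton = r - f / (1.0 + c * q * rq / np.maximum(r, 1e-300))
        inside = (newton > lo) & (newton < hi)
        r = np.where(inside, newton, 0.5 * (lo + hi))
    out[pos] = r
    return out


def _power_iteration(matvec, rmatvec, n: int, dtype=complex,
                     iters: int = 50) -> float:
    """Largest squared singular value (Lipschitz constant of the data-fit
    gradient), deterministic start."""
    v = np.ones(n, dtype) / np.sqrt(n)
    s = 1.0
    for _ in range(iters):
        w = rmatvec(matvec(v))
        s = float(np.linalg.norm(w))
        if s == 0:
            return 1.0
        v = w / s
    return 1.02 * s   # small safety margin keeps the step valid


class _VectorProblem:
    """Stacked vector problem ||y - A g||; native complex or real-stacked."""

    def __init__(self, a: np.ndarray, y: np.ndarray, backend: str):
        if backend not in ("complex", "real"):
            raise ValueError("backend must be 'complex' or 'real'")
        self.backend = backend
        self.n = a.shape[1]
        if backend == "complex":
            self.a, self.y = a, y
        else:
            ar, ai = a.real, a.imag
            self.a = np.block([[ar, -ai], [ai, ar]])
            self.y = np.concatenate([y.real, y.imag])
        self.ah = np.ascontiguousarray(self.a.conj().T)

    def matvec(self, g):
        return self.a @ g

    def rmatvec(self, r):
        return self.ah @ r

    def zeros(self):
        m = self.n if self.backend == "complex" else 2 * self.n
        return np.zeros(m, complex if self.backend == "complex" else float)

    def group_abs(self, g):
        if self.backend == "complex":
            return np.abs(g)
        return np.hypot(g[:self.n], g[self.n:])

    def scale_groups(self, g, s):
        if self.backend == "complex":
            return g * s
        return g * np.concatenate([s, s])

    def residual(self, g):
        r = self.matvec(g) - self.y
        return float(np.vdot(r, r).real)

    def to_complex(self, g):
        if self.backend == "complex":
            return g
        return g[:self.n] + 1j * g[self.n:]

    def dual_scale(self):
        """max group-modulus of A^H y (the p=1 zero-solution threshold)."""
        return float(self.group_abs(self.rmatvec(self.y)).max())


class _MatrixProblem:
    """Per-frequency systems x_i = B_i G[:, i]; rows grouped across i."""

    def __init__(self, b_list, x_list, backend: str):
        if backend not in ("complex", "real"):
            raise ValueError("backend must be 'complex' or 'real'")
        self.backend = backend
        self.n = b_list[0].shape[1]
        self.nf = len(b_list)
        if backend == "complex":
            self.b_list = list(b_list)
            self.x_list = list(x_list)
        else:
            self.b_list = [np.block([[b.real, -b.imag], [b.imag, b.real]])
                           for b in b_list]
            self.x_list = [np.concatenate([x.real, x.imag]) for x in x_list]
        self.bh_list = [np.ascontiguousarray(b.conj().T)
                        for b in self.b_list]

    def zeros(self):
        rows = self.n if self.backend == "complex" else 2 * self.n
        return np.zeros((rows, self.nf),
                        complex if self.backend == "complex" else float)

    def matvec(self, g):
        # only used column-wise through grad/residual below
        raise NotImplementedError

    def grad(self, g):
        out = np.empty_like(g)
        for i, (b, bh, x) in enumerate(zip(self.b_list, self.bh_list,
                                           self.x_list)):
            out[:, i] = bh @ (b @ g[:, i] - x)
        return out

    def residual(self, g):
        tot = 0.0
        for i, (b, x) in enumerate(zip(self.b_list, self.x_list)):
            r = b @ g[:, i] - x
            tot += float(np.vdot(r, r).real)
        return tot

    def lipschitz(self):
        best = 0.0
        for b in self.b_list:
            s = _power_iteration(lambda v, b=b: b @ v,
                                 lambda r, b=b: b.conj().T @ r,
                                 b.shape[1],
                                 complex if self.backend == "complex"
                                 else float)
            best = max(best, s)
        return best

    def group_abs(self, g):
        if self.backend == "complex":
            return np.linalg.norm(g, axis=1)
        return np.sqrt((g[:self.n] ** 2 + g[self.n:] ** 2).sum(axis=1))

    def scale_groups(self, g, s):
        if self.backend == "complex":
            return g * s[:, None]
        return g * np.concatenate([s, s])[:, None]

    def to_complex(self, g):
        if self.backend == "complex":
            return g
        return g[:self.n] + 1j * g[self.n:]

    def dual_scale(self):
        g0 = self.zeros()
        return float(self.group_abs(-self.grad(g0)).max())

    def data_energy(self):
        return float(sum(np.vdot(x, x).real for x in self.x_list))


def _fista(problem, grad, lam: float, p: float, lipschitz: float,
           g0, max_iter: int, tol: float):
    """Accelerated proximal gradient on the penalized objective."""
    g = g0.copy()
    z = g.copy()
    t_k = 1.0
    step = 1.0 / lipschitz
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        v = z - step * grad(z)
        r = problem.group_abs(v)
        rp = prox_power(r, lam * step, p)
        s = np.where(r > 0, rp / np.where(r > 0, r, 1.0), 0.0)
        g_new = problem.scale_groups(v, s)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k ** 2))
        z = g_new + ((t_k - 1.0) / t_next) * (g_new - g)
        delta = float(np.max(np.abs(g_new - g)))
        scale = max(1.0, float(np.max(np.abs(g_new))))
        g = g_new
        t_k = t_next
        if delta <= tol * scale:
            break
    return g, n_iter


def _objective(problem, g, p: float) -> float:
    r = problem.group_abs(g)
    if not np.any(r > 0):
        return 0.0
    return float(np.sum(r ** p) ** (1.0 / p))


def _solve_constrained(problem, grad, epsilon: float, p: float,
                       data_energy: float, lipschitz: float,
                       max_iter: int, tol: float,
                       eps_band: float = 0.05, max_bisect: int = 40):
    """Penalty search: largest ``lam`` whose solution stays feasible."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if data_energy <= epsilon:
        g0 = problem.zeros()
        return SolveResult(problem.to_complex(g0), "zero-feasible",
                           data_energy, epsilon, 0.0, np.inf, 0, lipschitz)

    total_iters = 0

    def solve_at(lam, warm):
        nonlocal total_iters
        g, it = _fista(problem, grad, lam, p, lipschitz, warm,
                       max_iter, tol)
        total_iters += it
        return g, problem.residual(g)

    # upper bracket: lam large enough that the solution is infeasible-sparse
    lam_hi = max(problem.dual_scale(), 1e-30)
    g_hi, res_hi = solve_at(lam_hi, problem.zeros())
    for _ in range(30):
        if res_hi > epsilon:
            break
        lam_hi *= 4.0
        g_hi, res_hi = solve_at(lam_hi, g_hi)
    # lower bracket: lam small enough to be feasible
    lam_lo = lam_hi
    g_lo, res_lo = g_hi, res_hi
    for _ in range(60):
        lam_lo /= 8.0
        g_lo, res_lo = solve_at(lam_lo, g_lo)
        if res_lo <= epsilon:
            break
    if res_lo > epsilon:
        raise SolverError(
            "could not reach the residual budget; the program may be "
            "ill-conditioned or max_iter too small",
            {"residual": res_lo, "epsilon": epsilon, "lam": lam_lo,
             "iterations": total_iters})

    best_g, best_res, best_lam = g_lo, res_lo, lam_lo
    for _ in range(max_bisect):
        if best_res >= (1.0 - eps_band) * epsilon:
            break
        lam_mid = np.sqrt(lam_lo * lam_hi)
        g_mid, res_mid = solve_at(lam_mid, best_g)
        if res_mid <= epsilon:
            lam_lo, best_g, best_res, best_lam = lam_mid, g_mid, res_mid, \
                lam_mid
        else:
            lam_hi = lam_mid
        if lam_hi / lam_lo < 1.01:
            break
    return SolveResult(problem.to_complex(best_g), "optimal", best_res,
                       epsilon, _objective(problem, best_g, p), best_lam,
                       total_iters, lipschitz)


def solve_sparse_vector(a_list, y_list, epsilon: float, p: float = 1.05,
                        max_iter: int = 500, tol: float = 1e-7,
                        backend: str = "complex") -> SolveResult:
    """Solve the known-transmit program for one click.

    ``a_list`` / ``y_list`` hold the per-frequency model matrices (rows
    already reduced to the valid sensors at that frequency) and data
    vectors; they are stacked into a single least-squares block.
    """
    if p < 1.0:
        raise ValueError("p < 1 is non-convex; p must be >= 1")
    a = np.vstack(a_list)
    y = np.concatenate(y_list)
    prob = _VectorProblem(a, y, "complex" if backend == "complex" else "real")
    lip = _power_iteration(prob.matvec, prob.rmatvec, prob.a.shape[1],
                           complex if prob.backend == "complex" else float)

    def grad(g):
        return prob.rmatvec(prob.matvec(g) - prob.y)

    energy = float(np.vdot(y, y).real)
    if energy <= epsilon:
        warnings.warn("epsilon >= total data energy: zero solution is "
                      "feasible and optimal")
    return _solve_constrained(prob, grad, epsilon, p, energy, lip,
                              max_iter, tol)


def solve_sparse_rows(b_list, x_list, epsilon: float, p: float = 1.0,
                      max_iter: int = 500, tol: float = 1e-7,
                      backend: str = "complex") -> SolveResult:
    """Solve the unknown-transmit (p, 2) row-sparsity program for one click.

    The unknown is the N x F occupancy matrix; the p-norm of the per-row
    2-norms couples the frequencies so that active voxels carry energy
    across the whole band while inactive rows are driven to zero.
    """
    if p < 1.0:
        raise ValueError("p < 1 is non-convex; p must be >= 1")
    prob = _MatrixProblem(b_list, x_list,
                          "complex" if backend == "complex" else "real")
    lip = prob.lipschitz()
    energy = prob.data_energy()
    if energy <= epsilon:
        warnings.warn("epsilon >= total data energy: zero solution is "
                      "feasible and optimal")
    return _solve_constrained(prob, prob.grad, epsilon, p, energy, lip,
                              max_iter, tol)
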