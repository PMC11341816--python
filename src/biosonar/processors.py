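"""Imaging engines: broadband Bartlett and sparsity-aware inversion.

Both engines turn an :class:`~biosonar.forward.EchoDataset` plus its
steering matrices into a non-negative voxel image ``h``:

* Bartlett, known transmit — per click, correlate the data against every
  steering column coherently across frequencies,
  ``ghat_n(k) = sqrt(sum_i |a_n(f_i,k)^H y(f_i,k)|^2)``, then average over
  clicks.
* Bartlett, unknown transmit — phases cannot be aligned across
  frequencies, so magnitudes ``|b_n(f_i)^H x(f_i,k)|`` are averaged over
  frequencies and clicks (incoherent combination).
* Sparsity-aware (SA) — solve the convex p-norm (or (p,2) row-norm)
  program of :mod:`biosonar.solvers` per click at a residual budget
  ``epsilon``, then average the solution magnitudes.

Band selection is honoured everywhere by deleting the invalid sensor rows
of the data and model matrices at each frequency before processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import EchoDataset, SteeringMatrixSet
from .solvers import SolveResult, solve_sparse_rows, solve_sparse_vector

DEFAULT_EPSILON_FRACTION = 0.1


@dataclass
class SolverConfig:
    """Settings for the sparsity-aware programs.

    ``p`` defaults to 1.05 for the known-transmit case and 1.0 for the
    unknown-transmit case (set per call if None).  ``epsilon`` is an
    absolute residual-energy budget; when None it is derived per click as
    ``epsilon_fraction`` times the click's data energy.
    """

    p: float | None = None
    epsilon: float | None = None
    epsilon_fraction: float = DEFAULT_EPSILON_FRACTION
    max_iter: int = 500
    tol: float = 1e-7
    backend: str = "complex"        # "complex" | "real"

    def __post_init__(self) -> None:
        if self.p is not None and self.p < 1.0:
            raise ValueError("p < 1 breaks convexity; p must be >= 1")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (0.0 < self.epsilon_fraction < 1.0):
            raise ValueError("epsilon_fraction must be in (0, 1)")
        if self.backend not in ("complex", "real"):
            raise ValueError("backend must be 'complex' or 'real'")


@dataclass
class ProcessorOutput:
    """Aggregated voxel image with per-click intermediates."""

    h: np.ndarray                         # (N,) non-negative
    processor: str                        # "bartlett" | "sa"
    mode: str                             # "known" | "unknown"
    per_click: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, float)
        if np.any(self.h < -1e-12):
            raise ValueError("processor image must be non-negative")
        self.h = np.maximum(self.h, 0.0)


def _check_shapes(dataset: EchoDataset, steering: SteeringMatrixSet,
                  mode: str) -> None:
    if dataset.mode != mode or steering.mode != mode:
        raise ValueError(f"dataset/steering mode must both be {mode!r}")
    if dataset.n_sensors != steering.n_sensors:
        raise ValueError("sensor count mismatch between data and steering")
    if dataset.n_freqs != steering.n_freqs:
        raise ValueError("frequency axis mismatch between data and steering")
    if mode == "known" and dataset.n_clicks != steering.n_clicks:
        raise ValueError("click count mismatch between data and steering")


def bartlett_known(dataset: EchoDataset,
                   steering: SteeringMatrixSet) -> ProcessorOutput:
    """Coherent broadband Bartlett image for known transmit parameters."""
    _check_shapes(dataset, steering, "known")
    N = steering.n_voxels
    K = dataset.n_clicks
    per_click = []
    h = np.zeros(N)
    for k in range(K):
        acc = np.zeros(N)
        for i in range(dataset.n_freqs):
            rows = dataset.valid[:, i]
            if not rows.any():
                continue
            a = steering.a[k, i][rows]          # (Mv, N)
            y = dataset.data[rows, i, k]
            acc += np.abs(a.conj().T @ y) ** 2
        ghat = np.sqrt(acc)
        per_click.append(ghat)
        h += ghat
    return ProcessorOutput(h / K, "bartlett", "known", per_click)


def bartlett_unknown(dataset: EchoDataset,
                     steering: SteeringMatrixSet) -> ProcessorOutput:
    """Incoherent broadband Bartlett image (transmit parameters unknown)."""
    _check_shapes(dataset, steering, "unknown")
    N = steering.n_voxels
    K, F = dataset.n_clicks, dataset.n_freqs
    per_click = []
    h = np.zeros(N)
    for k in range(K):
        gk = np.zeros((N, F))
        for i in range(F):
            rows = dataset.valid[:, i]
            if not rows.any():
                continue
            b = steering.b[i][rows]
            x = dataset.data[rows, i, k]
            gk[:, i] = np.abs(b.conj().T @ x)
        per_click.append(gk)
        h += gk.sum(axis=1)
    return ProcessorOutput(h / (F * K), "bartlett", "unknown", per_click)


def epsilon_from_energy(dataset: EchoDataset, fraction: float) -> np.ndarray:
    """Per-click residual budgets: ``fraction`` x click data energy."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    eps = np.empty(dataset.n_clicks)
    for k in range(dataset.n_clicks):
        e = dataset.total_energy(click=k)
        if e == 0:
            raise ValueError(f"click {k} has zero energy; epsilon undefined")
        eps[k] = fraction * e
    return eps


def _click_systems(dataset: EchoDataset, steering: SteeringMatrixSet,
                   k: int):
    """Per-frequency (matrix, data) pairs with invalid rows deleted."""
    mats, vecs = [], []
    for i in range(dataset.n_freqs):
        rows = dataset.valid[:, i]
        if not rows.any():
            continue
        m = steering.a[k, i][rows] if steering.mode == "known" \
            else steering.b[i][rows]
        mats.append(m)
        vecs.append(dataset.data[rows, i, k])
    if not mats:
        raise ValueError("band selection removed every (sensor, frequency) "
                         "cell; nothing to solve")
    return mats, vecs


def _resolve_epsilons(dataset: EchoDataset,
                      config: SolverConfig) -> np.ndarray:
    if config.epsilon is not None:
        return np.full(dataset.n_clicks, config.epsilon)
    return epsilon_from_energy(dataset, config.epsilon_fraction)


def sa_known(dataset: EchoDataset, steering: SteeringMatrixSet,
             config: SolverConfig | None = None) -> ProcessorOutput:
    """Sparsity-aware image for known transmit parameters (p default 1.05)."""
    config = config or SolverConfig()
    _check_shapes(dataset, steering, "known")
    p = 1.05 if config.p is None else config.p
    eps = _resolve_epsilons(dataset, config)
    h = np.zeros(steering.n_voxels)
    per_click, diags = [], []
    for k in range(dataset.n_clicks):
        mats, vecs = _click_systems(dataset, steering, k)
        result = solve_sparse_vector(mats, vecs, float(eps[k]), p=p,
                                     max_iter=config.max_iter,
                                     tol=config.tol,
                                     backend=config.backend)
        per_click.append(result.solution)
        diags.append(_diag(result))
        h += np.abs(result.solution)
    return ProcessorOutput(h / dataset.n_clicks, "sa", "known", per_click,
                           {"p": p, "epsilon": eps.tolist(),
                            "epsilon_fraction": (None if config.epsilon
                                                 else config.epsilon_fraction),
                            "clicks": diags})


def sa_unknown(dataset: EchoDataset, steering: SteeringMatrixSet,
               config: SolverConfig | None = None) -> ProcessorOutput:
    """Sparsity-aware image with unknown transmit (row sparsity, p default 1)."""
    config = config or SolverConfig()
    _check_shapes(dataset, steering, "unknown")
    p = 1.0 if config.p is None else config.p
    eps = _resolve_epsilons(dataset, config)
    F = dataset.n_freqs
    h = np.zeros(steering.n_voxels)
    per_click, diags = [], []
    for k in range(dataset.n_clicks):
        mats, vecs = _click_systems(dataset, steering, k)
        result = solve_sparse_rows(mats, vecs, float(eps[k]), p=p,
                                   max_iter=config.max_iter,
                                   tol=config.tol,
                                   backend=config.backend)
        sol = result.solution                    # (N, F_valid)
        per_click.append(sol)
        diags.append(_diag(result))
        h += np.abs(sol).sum(axis=1)
    return ProcessorOutput(h / (F * dataset.n_clicks), "sa", "unknown",
                           per_click,
                           {"p": p, "epsilon": eps.tolist(),
                            "epsilon_fraction": (None if config.epsilon
                                                 else config.epsilon_fraction),
                            "clicks": diags})


def _diag(result: SolveResult) -> dict:
    return {"status": result.status, "residual": result.residual,
            "epsilon": result.epsilon, "objective": result.objective,
            "lambda": result.lam, "iterations": result.n_iterations}


def compute_image(dataset: EchoDataset, steering: SteeringMatrixSet,
                  processor: str = "bartlett",
                  config: SolverConfig | None = None) -> ProcessorOutput:
    """Dispatch helper: processor in {'bartlett', 'sa'}, mode from data."""
    if processor == "bartlett":
        return (bartlett_known if dataset.mode == "known"
                else bartlett_unknown)(dataset, steering)
    if processor == "sa":
        return (sa_known if dataset.mode == "known"
                else sa_unknown)(dataset, steering, config)
    raise ValueError("processor must be 'bartlett' or 'sa'")
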