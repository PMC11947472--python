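"""Metropolis Monte-Carlo equilibration of a two-row configuration.

Cell boundaries fluctuate by Gaussian vertex displacements modelling
filopodia-driven mechanical noise; moves are accepted with the Metropolis
probability ``min(1, exp(-dE/E0))`` where ``E0`` is the effective temperature.
Moves that would flip a cell past its neighbour on the same row are rejected
outright, and the two end vertices of each row are pinned, so the total span
is conserved exactly.

The unit of "iteration" throughout is one vertex proposal.  By default the
trajectory is recorded every ``2(N-1)`` proposals, i.e. roughly once per
sweep over the movable vertices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .energetics import AdhesionParameters, delta_energy, move_is_allowed, total_energy
from .errors import CellMatchError, ConfigurationError, InsufficientDataError
from .geometry import TissueConfiguration
from .mismatch import tissue_mismatch


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings.

    deltaX : proposal standard deviation (μm); default 0.05.
    E0 : effective temperature (energy units); default 0.1, i.e. E0/K = 0.1 μm²
        at the default K = 1.
    n_steps : proposal budget; default 4e6, which covers the slow transient
        of N = 52 rows about twice over.
    record_every : proposals between recorded samples; ``None`` means 2(N-1).
    convergence_window / convergence_slope_tol : the run may stop early once
        the fitted slope of the recorded mismatch over the last window of
        samples falls below the tolerance (per recorded sample).
    """

    deltaX: float = 0.05
    E0: float = 0.1
    n_steps: int = 4_000_000
    seed: int | None = None
    record_every: int | None = None
    convergence_window: int = 1000
    convergence_slope_tol: float = 2e-5
    early_stop: bool = True
    min_fraction: float = 0.5  # fraction of n_steps to run before early stop

    def __post_init__(self) -> None:
        if not self.deltaX > 0:
            raise ConfigurationError("deltaX must be > 0")
        if not self.E0 > 0:
            raise ConfigurationError("E0 must be > 0")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")


@dataclass
class MCMCTrajectory:
    """Recorded output of one Metropolis run."""

    steps: np.ndarray          # proposal index of each recorded sample
    tissue_mismatch: np.ndarray
    total_energy: np.ndarray
    acceptance_rate: float
    final_config: TissueConfiguration
    converged: bool
    n_steps_run: int

    def __len__(self) -> int:
        return len(self.steps)


# ----------------------------------------------------------- single proposals
def propose_move(
    config: TissueConfiguration, rng: np.random.Generator, deltaX: float
) -> tuple[int, int, float]:
    """Draw (row, vertex index, dx): a uniformly chosen interior vertex and a
    Gaussian displacement of standard deviation ``deltaX``.

    The vertex index is 0-based into the row's vertex array; end vertices
    (0 and N) are never proposed.
    """
    n = config.n_cells
    if n < 2:
        raise CellMatchError("no movable vertex: need at least 2 cells per row")
    idx = min(int(rng.random() * 2 * (n - 1)), 2 * (n - 1) - 1)
    row = idx // (n - 1) + 1
    i = idx % (n - 1) + 1
    dx = rng.standard_normal() * deltaX
    return row, i, dx


def move_allowed(config: TissueConfiguration, row: int, i: int, dx: float) -> bool:
    """Whether a vertex move keeps cells from flipping or overlapping in-row."""
    return move_is_allowed(config, row, i, dx)


def acceptance_probability(dE: float, E0: float) -> float:
    """Metropolis probability min(1, exp(-dE/E0))."""
    if not E0 > 0:
        raise ConfigurationError("E0 must be > 0")
    if dE <= 0:
        return 1.0
    return math.exp(-dE / E0)


def step(
    config: TissueConfiguration,
    params: AdhesionParameters,
    settings: MCMCSettings,
    rng: np.random.Generator,
) -> tuple[TissueConfiguration, bool]:
    """One propose/evaluate/accept-reject cycle, in place on ``config``.

    Returns the (mutated) configuration and whether the move was accepted.
    Mirrors one iteration of the compiled kernel, including the RNG call
    pattern (uniform for the vertex, normal for the displacement, uniform for
    the acceptance draw only when dE > 0).
    """
    row, i, dx = propose_move(config, rng, settings.deltaX)
    if not move_allowed(config, row, i, dx):
        return config, False
    dE = delta_energy(config, (row, i, dx), params)
    if dE <= 0.0:
        accept = True
    else:
        accept = rng.random() < math.exp(-dE / settings.E0)
    if accept:
        config.vertices[row - 1, i] += dx
    return config, accept


# -------------------------------------------------------------------- run
def run(
    config: TissueConfiguration,
    params: AdhesionParameters,
    settings: MCMCSettings,
) -> MCMCTrajectory:
    """Equilibrate a configuration; the input is not modified.

    Runs up to ``settings.n_steps`` proposals through the compiled kernel in
    windows of ``convergence_window`` recorded samples, stopping early when
    the mismatch trend flattens.  The kernel's incrementally tracked total
    energy is checked against a full recomputation at the end of the run.
    """
    cfg = config.copy()
    n = cfg.n_cells
    if n < 2:
        raise CellMatchError("no movable vertex: need at least 2 cells per row")
    record_every = settings.record_every or 2 * (n - 1)
    n_records = settings.n_steps // record_every
    if n_records < 1:
        raise ConfigurationError("n_steps must allow at least one recorded sample")

    rng = np.random.default_rng(settings.seed)
    x = cfg.vertices
    types64 = cfg.types.astype(np.int64)
    eps = params.eps_matrix
    rec_m = np.empty(n_records)
    rec_e = np.empty(n_records)

    e_current = total_energy(cfg, params)
    n_acc_total = 0
    written = 0
    steps_run = 0
    converged = False
    window = max(settings.convergence_window, 10)
    chunk_records = window
    dummy_x = np.empty((1, 2, x.shape[1]))
    while written < n_records:
        todo = min(chunk_records, n_records - written)
        n_acc, n_rec, e_current = _kernels.run_mcmc(
            x, types64, cfg.rest_lengths, eps, params.K, settings.E0,
            settings.deltaX, todo * record_every, record_every, rng,
            rec_m, rec_e, written, e_current, dummy_x, False,
        )
        n_acc_total += n_acc
        written += n_rec
        steps_run += todo * record_every
        if (
            settings.early_stop
            and written >= 2 * window
            and steps_run >= settings.min_fraction * settings.n_steps
        ):
            tail = rec_m[written - window : written]
            slope = np.polyfit(np.arange(window), tail, 1)[0]
            if abs(slope) < settings.convergence_slope_tol:
                converged = True
                break
    if written == n_records and not converged and settings.early_stop:
        tail = rec_m[max(0, written - window) : written]
        if len(tail) >= 10:
            slope = np.polyfit(np.arange(len(tail)), tail, 1)[0]
            converged = abs(slope) < settings.convergence_slope_tol

    # internal consistency: incremental energy vs full recomputation
    e_full = total_energy(cfg, params)
    if not np.isclose(e_current, e_full, rtol=1e-8, atol=1e-6):
        raise CellMatchError(
            f"incremental energy drifted from full recomputation "
            f"({e_current} vs {e_full})"
        )

    steps = (np.arange(written) + 1) * record_every
    return MCMCTrajectory(
        steps=steps,
        tissue_mismatch=rec_m[:written].copy(),
        total_energy=rec_e[:written].copy(),
        acceptance_rate=n_acc_total / steps_run if steps_run else 0.0,
        final_config=cfg,
        converged=converged,
        n_steps_run=steps_run,
    )


def sample_positions(
    config: TissueConfiguration,
    params: AdhesionParameters,
    settings: MCMCSettings,
    thin: int = 10,
    burn_in: int = 0,
) -> np.ndarray:
    """Sample vertex configurations from the chain's stationary distribution.

    Runs ``settings.n_steps`` proposals and snapshots the full vertex array
    every ``thin`` proposals after ``burn_in`` proposals.  Returns an array of
    shape ``(n_samples, 2, N+1)``.  Used to compare the empirical stationary
    distribution against exact Boltzmann weights on small systems.
    """
    cfg = config.copy()
    rng = np.random.default_rng(settings.seed)
    types64 = cfg.types.astype(np.int64)
    eps = params.eps_matrix
    e_current = total_energy(cfg, params)
    dummy_x = np.empty((1, 2, cfg.vertices.shape[1]))
    if burn_in > 0:
        _kernels.run_mcmc(
            cfg.vertices, types64, cfg.rest_lengths, eps, params.K, settings.E0,
            settings.deltaX, burn_in, burn_in + 1, rng,
            np.empty(1), np.empty(1), 0, e_current, dummy_x, False,
        )
        e_current = total_energy(cfg, params)
    n_samples = settings.n_steps // thin
    rec_m = np.empty(n_samples)
    rec_e = np.empty(n_samples)
    rec_x = np.empty((n_samples, 2, cfg.vertices.shape[1]))
    _kernels.run_mcmc(
        cfg.vertices, types64, cfg.rest_lengths, eps, params.K, settings.E0,
        settings.deltaX, n_samples * thin, thin, rng,
        rec_m, rec_e, 0, e_current, rec_x, True,
    )
    return rec_x


# --------------------------------------------------------------- statistics
def steady_state_mismatch(
    trajectory: MCMCTrajectory, tail_fraction: float = 0.5
) -> tuple[float, float]:
    """Mean and SEM of the tissue mismatch over the trajectory tail.

    The SEM accounts for autocorrelation between recorded samples through the
    integrated autocorrelation time (initial-positive-sequence estimator).
    """
    if not 0 < tail_fraction <= 1:
        raise ConfigurationError("tail_fraction must lie in (0, 1]")
    m = trajectory.tissue_mismatch
    if len(m) == 0:
        raise InsufficientDataError("trajectory too short for the requested tail")
    n_tail = max(1, int(round(len(m) * tail_fraction)))
    tail = m[len(m) - n_tail :]
    mean = float(tail.mean())
    if n_tail < 2:
        return mean, 0.0
    var = tail.var(ddof=1)
    if var == 0.0:
        return mean, 0.0
    tau = _integrated_autocorr_time(tail - mean)
    n_eff = max(1.0, n_tail / (2.0 * tau + 1.0))
    return mean, float(np.sqrt(var / n_eff))


def _integrated_autocorr_time(x: np.ndarray, max_lag: int | None = None) -> float:
    n = len(x)
    if max_lag is None:
        max_lag = min(n - 1, 1000)
    var = np.dot(x, x) / n
    if var == 0:
        return 0.0
    tau = 0.0
    for lag in range(1, max_lag + 1):
        rho = np.dot(x[:-lag], x[lag:]) / ((n - lag) * var)
        if rho <= 0:
            break
        tau += rho
    return tau
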