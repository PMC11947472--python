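"""Overdamped dynamic vertex model of the two-row interface.

Each interior vertex moves with velocity F/ξ, where the force combines the
interfacial tensions of the two interface segments flanking the vertex and
log-elastic restoring forces of the two adjacent cells:

    ξ dx/dt = (T_right - T_left) + K log(L_right/L0_right) - K log(L_left/L0_left)

Tensions are looked up per interface type (SS, TT, ST); adhesion is a
*negative* tension, which extends favourable contacts.  The logarithmic
elastic force matches K(L - L0) for small deformations but diverges as a cell
shrinks, preventing collapse.  Integration is synchronous explicit Euler with
a default timestep of 0.01 min; the dynamics are deterministic given the
initial configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import ConfigurationError, DegenerateGeometryError, TimestepError
from .geometry import TissueConfiguration
from .mismatch import tissue_mismatch

#: Minimum cell length (μm) enforced during integration.  The exact dynamics
#: cannot collapse a cell (the log force diverges); the floor only guards the
#: discretisation.
LENGTH_FLOOR = 1e-6


@dataclass(frozen=True)
class VertexDynamicsParameters:
    """Tensions (pN; negative = contact-extending), per-row-or-cell elastic
    coefficient K (pN), friction ξ (pN·min/μm) and integration controls.

    ``K`` may be a scalar (uniform), a pair (per row), or a (2, N) array
    (per cell), enabling asymmetric-stiffness studies.
    """

    T_SS: float = 0.0
    T_TT: float = 0.0
    T_ST: float = 0.0
    K: float | tuple[float, float] | np.ndarray = 100.0
    xi: float = 1000.0
    dt: float = 0.01
    t_end: float = 600.0

    def __post_init__(self) -> None:
        if not self.xi > 0:
            raise ConfigurationError("xi must be > 0")
        if not self.dt > 0:
            raise ConfigurationError("dt must be > 0")
        if not self.t_end > 0:
            raise ConfigurationError("t_end must be > 0")

    def tension_matrix(self) -> np.ndarray:
        """2x2 lookup by type codes (0 = S, 1 = T)."""
        return np.array([[self.T_SS, self.T_ST], [self.T_ST, self.T_TT]])

    @classmethod
    def from_t0(cls, t0: float, **kwargs) -> "VertexDynamicsParameters":
        """Single-knob tensions: T_SS = T_TT = -t0, T_ST = 0."""
        return cls(T_SS=-t0, T_TT=-t0, T_ST=0.0, **kwargs)

    def k_per_cell(self, config: TissueConfiguration) -> np.ndarray:
        """(2, N) elastic coefficients resolved against a configuration."""
        n = config.n_cells
        K = self.K
        if np.isscalar(K):
            if not K > 0:
                raise ConfigurationError("K must be > 0")
            return np.full((2, n), float(K))
        arr = np.asarray(K, dtype=np.float64)
        if arr.shape == (2,):
            arr = np.repeat(arr[:, None], n, axis=1)
        if arr.shape != (2, n):
            raise ConfigurationError(f"K must be scalar, (2,) or (2, {n})")
        if not (arr > 0).all():
            raise ConfigurationError("all K values must be > 0")
        return arr


@dataclass
class DynamicsTrace:
    """Mismatch time series (and optional snapshots) of one integration."""

    times: np.ndarray
    tissue_mismatch: np.ndarray
    final_config: TissueConfiguration
    n_clamped: int = 0
    snapshots: list[TissueConfiguration] | None = None

    def __len__(self) -> int:
        return len(self.times)


# ------------------------------------------------------------------- forces
def vertex_force(
    config: TissueConfiguration, row: int, i: int, params: VertexDynamicsParameters
) -> float:
    """Net force (pN) on interior vertex ``i`` (0-based) of ``row``."""
    n = config.n_cells
    if not 1 <= i <= n - 1:
        raise ConfigurationError(f"vertex {i} is not interior (1..{n - 1})")
    r = row - 1
    s = 1 - r
    v = config.vertices
    ll = v[r, i] - v[r, i - 1]
    lr = v[r, i + 1] - v[r, i]
    if ll <= 0 or lr <= 0:
        raise DegenerateGeometryError(f"non-positive cell length at vertex {i}")
    Kc = params.k_per_cell(config)
    f = Kc[r, i] * np.log(lr / config.rest_lengths[r, i]) - Kc[r, i - 1] * np.log(
        ll / config.rest_lengths[r, i - 1]
    )
    tension = params.tension_matrix()
    pos = v[r, i]
    jr = int(np.clip(np.searchsorted(v[s], pos, side="right") - 1, 0, n - 1))
    jl = int(np.clip(np.searchsorted(v[s], pos, side="left") - 1, 0, n - 1))
    f += tension[config.types[r, i], config.types[s, jr]]
    f -= tension[config.types[r, i - 1], config.types[s, jl]]
    return float(f)


def euler_step(
    config: TissueConfiguration, params: VertexDynamicsParameters
) -> TissueConfiguration:
    """One synchronous explicit-Euler step; returns a new configuration.

    All forces are evaluated on the pre-step state.  A displacement larger
    than an adjacent cell signals instability (reduce ``dt``); displacements
    that would shrink a cell below the length floor are clamped to half the
    available gap, which preserves vertex ordering.
    """
    cfg = config.copy()
    n = cfg.n_cells
    forces = np.zeros((2, n + 1))
    for r in (1, 2):
        for i in range(1, n):
            forces[r - 1, i] = vertex_force(config, r, i, params)
    dx = params.dt / params.xi * forces
    lengths = np.diff(config.vertices, axis=1)
    if (np.abs(dx[:, 1:-1]) > np.maximum(lengths[:, :-1], lengths[:, 1:])).any():
        raise TimestepError("|dx| exceeded a cell length; reduce dt")
    max_r = np.maximum(0.0, 0.5 * (lengths[:, 1:] - LENGTH_FLOOR))
    max_l = np.maximum(0.0, 0.5 * (lengths[:, :-1] - LENGTH_FLOOR))
    dx[:, 1:-1] = np.clip(dx[:, 1:-1], -max_l, max_r)
    cfg.vertices[:, 1:-1] += dx[:, 1:-1]
    return cfg


def run_dynamics(
    config: TissueConfiguration,
    params: VertexDynamicsParameters,
    record_every: int = 100,
) -> DynamicsTrace:
    """Integrate to ``params.t_end``, recording mismatch every
    ``record_every`` steps.  Deterministic given the initial configuration;
    the input is not modified."""
    if record_every < 1:
        raise ConfigurationError("record_every must be >= 1")
    cfg = config.copy()
    n_steps = int(round(params.t_end / params.dt))
    if n_steps < 1:
        raise ConfigurationError("t_end must cover at least one step")
    n_records = n_steps // record_every
    rec_m = np.empty(n_records + 1)
    rec_m[0] = tissue_mismatch(cfg)
    types64 = cfg.types.astype(np.int64)
    Kc = params.k_per_cell(cfg)
    n_rec, n_clamped = _kernels.run_dynamics_kernel(
        cfg.vertices, types64, cfg.rest_lengths, params.tension_matrix(), Kc,
        params.xi, params.dt, n_steps, record_every, rec_m, 1, LENGTH_FLOOR,
    )
    times = np.concatenate([[0.0], (np.arange(n_rec) + 1) * record_every * params.dt])
    return DynamicsTrace(
        times=times,
        tissue_mismatch=rec_m[: n_rec + 1].copy(),
        final_config=cfg,
        n_clamped=int(n_clamped),
    )


def time_to_min_mismatch(
    trace: DynamicsTrace, tol_fraction: float = 0.05
) -> tuple[float, bool]:
    """First time the mismatch enters ``(1 + tol) * min``; flags censoring.

    Returns ``(time, censored)`` where ``censored`` is True when the minimum
    sits at the end of the horizon, i.e. the trace may still be decreasing.
    """
    m = trace.tissue_mismatch
    if len(m) == 0:
        raise ConfigurationError("empty trace")
    m_min = m.min()
    threshold = (1.0 + tol_fraction) * m_min
    idx = int(np.argmax(m <= threshold))
    censored = int(np.argmin(m)) == len(m) - 1 and len(m) > 1
    return float(trace.times[idx]), bool(censored)
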