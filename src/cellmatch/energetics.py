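"""Energy bookkeeping for the equilibrium interface model.

The total energy is elastic plus adhesive:

    E = sum_cells K (L - L0)^2  -  sum_segments eps(pair) * segment_length

Elastic energy penalises deviations of each cell's leading-edge length from
its rest length with compressibility ``K``.  The adhesion term runs over the
*interface segments* obtained by merging and sorting both rows' vertices;
each segment is covered by exactly one cell per row and is typed SS, TT or ST
by that pair.  The sign convention makes ``eps >= 0`` favourable adhesion, so
larger same-type adhesion lowers the energy of aligned configurations.

The single control parameter of the model is

    gamma = ((eps_TT - eps_ST) + (eps_SS - eps_ST)) / K      [μm]

the typical length change that adhesion differences can impose on one cell
against its elastic cost.  gamma = 0 means cell types are energetically
indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .errors import CellMatchError, ConfigurationError
from .geometry import CODE_TO_LABEL, TissueConfiguration


@dataclass(frozen=True)
class AdhesionParameters:
    """Adhesion energies per unit length (E/μm) and compressibility K (E/μm²).

    ``eps_SS``, ``eps_TT`` and ``eps_ST`` are the favourable adhesion energies
    of S-S, T-T and S-T contact; K must be positive.
    """

    eps_SS: float = 0.0
    eps_TT: float = 0.0
    eps_ST: float = 0.0
    K: float = 1.0

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ConfigurationError(f"K must be > 0, got {self.K}")
        for name in ("eps_SS", "eps_TT", "eps_ST"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")

    @cached_property
    def eps_matrix(self) -> np.ndarray:
        """2x2 lookup by type codes: eps_matrix[a, b] for pair (a, b)."""
        return np.array(
            [[self.eps_SS, self.eps_ST], [self.eps_ST, self.eps_TT]], dtype=np.float64
        )


@dataclass(frozen=True)
class InterfaceSegment:
    """One maximal interval covered by a fixed (row-1, row-2) cell pair."""

    start: float
    end: float
    pair_type: str  # "SS", "TT" or "ST"

    @property
    def length(self) -> float:
        return self.end - self.start


def gamma(params: AdhesionParameters) -> float:
    """Order parameter gamma = ((eps_TT - eps_ST) + (eps_SS - eps_ST)) / K, μm."""
    return ((params.eps_TT - params.eps_ST) + (params.eps_SS - params.eps_ST)) / params.K


def params_from_gamma(
    gamma_value: float,
    K: float = 1.0,
    eps_ST: float = 0.0,
    split: float = 0.5,
) -> AdhesionParameters:
    """Construct an adhesion triple realising a given gamma.

    The differential adhesion budget ``gamma * K`` is split between the two
    same-type energies (``split`` is the S-S share), on top of a common
    cross-type baseline ``eps_ST``.  Any split with the same gamma collapses
    onto the same equilibrium mismatch.
    """
    if not 0.0 <= split <= 1.0:
        raise ConfigurationError("split must lie in [0, 1]")
    budget = gamma_value * K
    return AdhesionParameters(
        eps_SS=eps_ST + split * budget,
        eps_TT=eps_ST + (1.0 - split) * budget,
        eps_ST=eps_ST,
        K=K,
    )


# ------------------------------------------------------------- segmentation
def interface_segments(config: TissueConfiguration) -> list[InterfaceSegment]:
    """Tile the interface into maximal segments of constant cell-type pair.

    Breakpoints are the sorted union of both rows' vertices; each non-empty
    segment is attributed half-open ``[start, end)`` to the cell covering its
    midpoint in each row.  Segments tile the span exactly.
    """
    v1, v2 = config.vertices
    breaks = np.unique(np.concatenate([v1, v2]))
    out: list[InterfaceSegment] = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b <= a:
            continue
        mid = 0.5 * (a + b)
        c1 = int(np.clip(np.searchsorted(v1, mid, side="right") - 1, 0, config.n_cells - 1))
        c2 = int(np.clip(np.searchsorted(v2, mid, side="right") - 1, 0, config.n_cells - 1))
        t1 = CODE_TO_LABEL[int(config.types[0, c1])]
        t2 = CODE_TO_LABEL[int(config.types[1, c2])]
        pair = t1 + t2 if t1 <= t2 else t2 + t1
        out.append(InterfaceSegment(float(a), float(b), pair))
    return out


# ------------------------------------------------------------------ energies
def elastic_energy(config: TissueConfiguration, K: float) -> float:
    """Sum over both rows of K (L - L0)^2."""
    if not K > 0:
        raise ConfigurationError(f"K must be > 0, got {K}")
    dev = np.diff(config.vertices, axis=1) - config.rest_lengths
    return float(K * np.sum(dev * dev))


def adhesion_energy(config: TissueConfiguration, params: AdhesionParameters) -> float:
    """-sum over interface segments of eps(pair_type) * length."""
    eps = params.eps_matrix
    v1, v2 = config.vertices
    breaks = np.unique(np.concatenate([v1, v2]))
    lens = np.diff(breaks)
    mids = 0.5 * (breaks[:-1] + breaks[1:])
    c1 = np.clip(np.searchsorted(v1, mids, side="right") - 1, 0, config.n_cells - 1)
    c2 = np.clip(np.searchsorted(v2, mids, side="right") - 1, 0, config.n_cells - 1)
    e = eps[config.types[0][c1].astype(int), config.types[1][c2].astype(int)]
    return float(-np.sum(e * lens))


def total_energy(config: TissueConfiguration, params: AdhesionParameters) -> float:
    """Elastic plus adhesive energy of the configuration."""
    return elastic_energy(config, params.K) + adhesion_energy(config, params)


# ------------------------------------------------------------- incremental dE
def move_is_allowed(config: TissueConfiguration, row: int, i: int, dx: float) -> bool:
    """Whether displacing interior vertex ``i`` (0-based) of ``row`` by ``dx``
    keeps cells from flipping or overlapping within the row.

    A positive move may not exceed the right cell's length and a negative move
    may not exceed the left cell's length (strict inequalities: a move that
    shrinks a cell exactly to zero length is allowed).
    """
    n = config.n_cells
    if not 1 <= i <= n - 1:
        return False
    v = config.vertices[row - 1]
    if dx > 0:
        return not dx > (v[i + 1] - v[i])
    if dx < 0:
        return not -dx > (v[i] - v[i - 1])
    return True


def delta_energy(
    config: TissueConfiguration,
    move: tuple[int, int, float],
    params: AdhesionParameters,
) -> float:
    """Energy change of displacing one interior vertex, computed incrementally.

    Only the two cells sharing the vertex and the interface stretch swept by
    the move contribute; the result matches a full recomputation of
    ``total_energy`` to 1e-9 relative tolerance.

    ``move`` is ``(row, i, dx)`` with ``row`` in {1, 2} and ``i`` the 0-based
    vertex index (interior: 1..N-1).
    """
    row, i, dx = move
    if row not in (1, 2):
        raise ConfigurationError(f"row must be 1 or 2, got {row}")
    if not move_is_allowed(config, row, i, dx):
        raise CellMatchError(f"move {move} violates the no-flip constraint")
    if dx == 0.0:
        return 0.0
    r = row - 1
    s = 1 - r
    v = config.vertices[r]
    l0 = config.rest_lengths[r]
    K = params.K

    # elastic: cells i-1 (left) and i (right) of this row
    ll, lr = v[i] - v[i - 1], v[i + 1] - v[i]
    d_el = K * (
        (ll + dx - l0[i - 1]) ** 2
        - (ll - l0[i - 1]) ** 2
        + (lr - dx - l0[i]) ** 2
        - (lr - l0[i]) ** 2
    )

    # adhesion: the swept interval flips this row's covering type between the
    # two flanking cells; integrate the eps difference over the opposing
    # row's segmentation of the interval.
    t_left = int(config.types[r, i - 1])
    t_right = int(config.types[r, i])
    if t_left == t_right:
        return float(d_el)
    a, b = (v[i], v[i] + dx) if dx > 0 else (v[i] + dx, v[i])
    # moving right: interval was covered by the right cell, now by the left
    t_new, t_old = (t_left, t_right) if dx > 0 else (t_right, t_left)
    eps = params.eps_matrix
    vo = config.vertices[s]
    n = config.n_cells
    j = int(np.clip(np.searchsorted(vo, a, side="right") - 1, 0, n - 1))
    d_adh = 0.0
    lo = a
    while lo < b:
        hi = min(b, vo[j + 1]) if j + 1 <= n else b
        if hi > lo:
            t_opp = int(config.types[s, j])
            if r == 0:
                d_adh -= (eps[t_new, t_opp] - eps[t_old, t_opp]) * (hi - lo)
            else:
                d_adh -= (eps[t_opp, t_new] - eps[t_opp, t_old]) * (hi - lo)
        lo = hi
        j = min(j + 1, n - 1)
        if hi >= b:
            break
    return float(d_el + d_adh)
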