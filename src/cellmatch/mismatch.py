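"""Mismatch metrics for two-row interface configurations.

A cell's mismatch is the fraction of its leading-edge length that does not
overlap its *sister* — the cell with the same index on the opposing row:

    m_i = (L_i - overlap(i, sister)) / L_i,   m_i in [0, 1].

0 means the cell perfectly faces its sister, 1 means no contact at all.  The
pair mismatch averages the two sisters, and the tissue mismatch averages
pairs along the row.  Zero-length cells (possible transiently during
Monte-Carlo moves that shrink a cell to a point) have zero overlap with
anything and take the limiting value 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidIntervalError
from .geometry import TissueConfiguration


def overlap_length(cell_i: tuple[float, float], cell_j: tuple[float, float]) -> float:
    """Length of the intersection of two intervals (0 if disjoint)."""
    (a0, a1), (b0, b1) = cell_i, cell_j
    if a0 > a1 or b0 > b1:
        raise InvalidIntervalError(f"reversed interval: {cell_i}, {cell_j}")
    return max(0.0, min(a1, b1) - max(a0, b0))


def cell_mismatch(config: TissueConfiguration, row: int, i: int) -> float:
    """Mismatch of cell ``i`` (1-based) on ``row`` against its sister."""
    if not 1 <= i <= config.n_cells:
        raise ConfigurationError(f"cell index {i} out of range 1..{config.n_cells}")
    r = row - 1
    if row not in (1, 2):
        raise ConfigurationError(f"row must be 1 or 2, got {row}")
    s = 1 - r
    own = (config.vertices[r, i - 1], config.vertices[r, i])
    sister = (config.vertices[s, i - 1], config.vertices[s, i])
    length = own[1] - own[0]
    if length <= 0.0:
        return 1.0  # limit: a point cell overlaps nothing
    return float((length - overlap_length(own, sister)) / length)


def pair_mismatch(config: TissueConfiguration, i: int) -> float:
    """Average mismatch of sister cells ``i`` on the two rows."""
    return 0.5 * (cell_mismatch(config, 1, i) + cell_mismatch(config, 2, i))


def pair_mismatches(config: TissueConfiguration) -> np.ndarray:
    """Vectorised per-pair mismatches, one value per column of sisters."""
    v1, v2 = config.vertices
    l1, l2 = np.diff(v1), np.diff(v2)
    ov = np.maximum(0.0, np.minimum(v1[1:], v2[1:]) - np.maximum(v1[:-1], v2[:-1]))
    m1 = np.where(l1 > 0, (l1 - ov) / np.where(l1 > 0, l1, 1.0), 1.0)
    m2 = np.where(l2 > 0, (l2 - ov) / np.where(l2 > 0, l2, 1.0), 1.0)
    return 0.5 * (m1 + m2)


def tissue_mismatch(config: TissueConfiguration) -> float:
    """Mean pair mismatch over the whole tissue; 0 iff perfectly aligned."""
    return float(pair_mismatches(config).mean())


@dataclass(frozen=True)
class MismatchProfile:
    """Mean mismatch at one position of the repeating pattern unit."""

    position_in_unit: int
    label: str
    mean_mismatch: float
    sem: float
    n: int


def spatial_profile(
    configs: Iterable[TissueConfiguration],
    pattern_unit: str,
    by: str = "position",
) -> list[MismatchProfile]:
    """Per-position (or per-type) mismatch profile pooled over an ensemble.

    Pools pair mismatches over complete repeats of ``pattern_unit`` and over
    replicates.  ``by="position"`` keeps the unit's positions 1..len(unit)
    separate; ``by="type"`` pools all positions sharing a label.  Incomplete
    trailing units are excluded.
    """
    if by not in ("position", "type"):
        raise ConfigurationError(f"by must be 'position' or 'type', got {by!r}")
    u = len(pattern_unit)
    pooled: dict[int, list[float]] = {p: [] for p in range(u)}
    expected_codes = None
    for cfg in configs:
        m = pair_mismatches(cfg)
        codes = tuple(cfg.types[0])
        if expected_codes is None:
            expected_codes = codes
        elif codes != expected_codes:
            raise ConfigurationError("configs must share one pattern to be pooled")
        n_full = cfg.n_cells // u
        for k in range(n_full):
            for p in range(u):
                pooled[p].append(float(m[k * u + p]))
    if expected_codes is None:
        raise ConfigurationError("empty ensemble")

    if by == "type":
        groups: dict[str, list[float]] = {}
        for p in range(u):
            groups.setdefault(pattern_unit[p], []).extend(pooled[p])
        out = []
        for idx, (lab, vals) in enumerate(sorted(groups.items()), start=1):
            arr = np.asarray(vals)
            out.append(
                MismatchProfile(idx, lab, float(arr.mean()), _sem(arr), arr.size)
            )
        return out

    out = []
    for p in range(u):
        arr = np.asarray(pooled[p])
        out.append(
            MismatchProfile(p + 1, pattern_unit[p], float(arr.mean()), _sem(arr), arr.size)
        )
    return out


def profile_frame(profiles: Sequence[MismatchProfile], replicate: int = 0) -> pd.DataFrame:
    """Tidy profile table: ``replicate,position,type,mean,sem,n``."""
    return pd.DataFrame(
        dict(
            replicate=replicate,
            position=[p.position_in_unit for p in profiles],
            type=[p.label for p in profiles],
            mean=[p.mean_mismatch for p in profiles],
            sem=[p.sem for p in profiles],
            n=[p.n for p in profiles],
        )
    )


def _sem(arr: np.ndarray) -> float:
    if arr.size < 2:
        return 0.0
    return float(arr.std(ddof=1) / np.sqrt(arr.size))
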