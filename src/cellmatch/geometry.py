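"""Two-row 1D interface geometry.

The tissue is modelled as two contralateral rows of ``N`` cells each, meeting
along a single 1D interface.  A cell ``i`` on row ``r`` is the interval between
consecutive vertices ``(x_i, x_{i+1})`` of that row; its type is one of two
labels, ``"S"`` (Svp-like) and ``"T"`` (Tin-like).  The first and last vertices
of the two rows coincide (pinned ends), so both rows span the same total
length.

Initial configurations are built by random sequential deposition: each row's
rest lengths are drawn from type-specific Gaussians, and the second row is
re-drawn until its total length matches the first row's within a small
tolerance, after which it is rescaled so the ends coincide exactly.  Cells
start at their rest length, and rest lengths are held fixed for the entire
simulation.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidPatternError, SamplingError

#: Canonical cell-type labels.  ``S`` maps to integer code 0, ``T`` to 1.
LABELS = ("S", "T")
LABEL_TO_CODE = {"S": 0, "T": 1}
CODE_TO_LABEL = {0: "S", 1: "T"}


@dataclass(frozen=True)
class TypeLengthParams:
    """Gaussian rest-length parameters for one cell type.

    Parameters
    ----------
    mean : float
        Mean leading-edge rest length, in μm.  Must be positive.
    std : float
        Standard deviation of the rest length, in μm.  Must be non-negative.
    """

    mean: float
    std: float

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ConfigurationError(f"rest-length mean must be > 0, got {self.mean}")
        if self.std < 0:
            raise ConfigurationError(f"rest-length std must be >= 0, got {self.std}")


#: Placeholder defaults for the two cardioblast types.  The underlying
#: experimental distributions are published only graphically, so these values
#: are *not* canonical: Svp-like cells are taken slightly smaller with a larger
#: relative spread than Tin-like cells (CV 15% vs 10%), which reproduces the
#: qualitative asymmetry between the two types.  Override for quantitative use.
DEFAULT_LENGTH_PARAMS: Mapping[str, TypeLengthParams] = {
    "S": TypeLengthParams(mean=4.0, std=0.6),
    "T": TypeLengthParams(mean=5.0, std=0.5),
}

#: Wild-type cardioblast row: repeats of four Tin-like then two Svp-like cells.
WILDTYPE_PATTERN = "TTTTSS"
#: Number of cardioblasts per row in the embryonic heart.
WILDTYPE_N_CELLS = 52


@dataclass
class TissueConfiguration:
    """State of the two-row interface evolved by both simulators.

    Attributes
    ----------
    vertices : (2, N+1) float array
        Vertex positions per row, μm, non-decreasing within each row.  The
        first and last columns are equal across rows (pinned ends).
    types : (2, N) int8 array
        Cell-type codes (0 = S, 1 = T).
    rest_lengths : (2, N) float array
        Per-cell rest lengths L0, μm, strictly positive; fixed during runs.
    """

    vertices: np.ndarray
    types: np.ndarray
    rest_lengths: np.ndarray
    pattern_unit: str | None = field(default=None)
    check: InitVar[bool] = True

    def __post_init__(self, check: bool = True) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.types = np.ascontiguousarray(self.types, dtype=np.int8)
        self.rest_lengths = np.ascontiguousarray(self.rest_lengths, dtype=np.float64)
        if check:
            self.validate()

    # ---------------------------------------------------------------- views
    @property
    def n_cells(self) -> int:
        return self.types.shape[1]

    @property
    def span(self) -> float:
        """Total interface length (identical for both rows)."""
        return float(self.vertices[0, -1] - self.vertices[0, 0])

    def lengths(self, row: int) -> np.ndarray:
        """Current cell lengths of row ``row`` (1 or 2)."""
        v = self.vertices[_row_index(row)]
        return np.diff(v)

    def labels(self, row: int) -> list[str]:
        return [CODE_TO_LABEL[int(c)] for c in self.types[_row_index(row)]]

    def copy(self) -> "TissueConfiguration":
        return TissueConfiguration(
            self.vertices.copy(),
            self.types.copy(),
            self.rest_lengths.copy(),
            pattern_unit=self.pattern_unit,
        )

    # ----------------------------------------------------------- invariants
    def validate(self) -> None:
        v, t, l0 = self.vertices, self.types, self.rest_lengths
        if v.ndim != 2 or v.shape[0] != 2:
            raise ConfigurationError("vertices must have shape (2, N+1)")
        n = v.shape[1] - 1
        if t.shape != (2, n) or l0.shape != (2, n):
            raise ConfigurationError("types/rest_lengths inconsistent with vertices")
        if n < 1:
            raise ConfigurationError("need at least one cell per row")
        if not (np.diff(v, axis=1) >= -1e-12).all():
            raise ConfigurationError("vertices must be non-decreasing within rows")
        if not (np.isclose(v[0, 0], v[1, 0]) and np.isclose(v[0, -1], v[1, -1])):
            raise ConfigurationError("end vertices must coincide across rows")
        if not (l0 > 0).all():
            raise ConfigurationError("rest lengths must be strictly positive")

    # -------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cell table: ``row,index,type,x_left,x_right,L0``."""
        recs = []
        for r in (1, 2):
            ri = _row_index(r)
            for i in range(self.n_cells):
                recs.append(
                    dict(
                        row=r,
                        index=i + 1,
                        type=CODE_TO_LABEL[int(self.types[ri, i])],
                        x_left=self.vertices[ri, i],
                        x_right=self.vertices[ri, i + 1],
                        L0=self.rest_lengths[ri, i],
                    )
                )
        return pd.DataFrame.from_records(recs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TissueConfiguration":
        n = int(df["index"].max())
        vertices = np.zeros((2, n + 1))
        types = np.zeros((2, n), dtype=np.int8)
        l0 = np.zeros((2, n))
        for r in (1, 2):
            sub = df[df["row"] == r].sort_values("index")
            if len(sub) != n:
                raise ConfigurationError("rows must have equal cell counts")
            vertices[r - 1, 0] = sub["x_left"].iloc[0]
            vertices[r - 1, 1:] = sub["x_right"].to_numpy()
            types[r - 1] = [LABEL_TO_CODE[s] for s in sub["type"]]
            l0[r - 1] = sub["L0"].to_numpy()
        return cls(vertices, types, l0)


def _row_index(row: int) -> int:
    if row not in (1, 2):
        raise ConfigurationError(f"row must be 1 or 2, got {row}")
    return row - 1


# ---------------------------------------------------------------- patterns
def make_pattern(pattern_spec: str | Sequence[str], n_cells: int) -> list[str]:
    """Tile a repeating unit of cell-type labels to ``n_cells`` labels.

    ``pattern_spec`` is a string over {"S", "T"} (e.g. ``"TTTTSS"`` for the
    wild-type 4-Tin/2-Svp unit), a sequence of labels, or one of the tokens
    ``"all-S"`` / ``"all-T"`` for a single-type tissue.  The unit is tiled
    from the first position and truncated at ``n_cells``; for the wild-type
    unit at N = 52 this yields 36 T and 16 S cells.
    """
    if n_cells < 1:
        raise InvalidPatternError(f"n_cells must be >= 1, got {n_cells}")
    if isinstance(pattern_spec, str):
        if pattern_spec == "all-S":
            unit: Sequence[str] = "S"
        elif pattern_spec == "all-T":
            unit = "T"
        else:
            unit = pattern_spec
    else:
        unit = list(pattern_spec)
    if len(unit) == 0:
        raise InvalidPatternError("pattern_spec must be non-empty")
    bad = set(unit) - set(LABELS)
    if bad:
        raise InvalidPatternError(f"unknown labels in pattern: {sorted(bad)}")
    reps = -(-n_cells // len(unit))
    return (list(unit) * reps)[:n_cells]


def sample_rest_lengths(
    labels: Sequence[str],
    params: Mapping[str, TypeLengthParams],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one rest length per label from its type's Gaussian.

    Non-positive draws are redrawn (truncation by rejection), so sampled
    lengths are strictly positive while the bulk of the distribution stays
    Gaussian for realistic coefficients of variation.
    """
    for lab in set(labels):
        if lab not in params:
            raise ConfigurationError(f"no length parameters for label {lab!r}")
    if len(labels) == 0:
        return np.empty(0)
    means = np.array([params[lab].mean for lab in labels])
    stds = np.array([params[lab].std for lab in labels])
    out = rng.normal(means, stds)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(means[bad], stds[bad])
        bad = out <= 0
    return out


# ------------------------------------------------- random sequential deposition
def deposit_rows(
    labels_row1: Sequence[str],
    labels_row2: Sequence[str],
    params: Mapping[str, TypeLengthParams] = DEFAULT_LENGTH_PARAMS,
    rng: np.random.Generator | None = None,
    max_attempts: int = 200_000,
    pattern_unit: str | None = None,
) -> TissueConfiguration:
    """Build an initial two-row configuration by random sequential deposition.

    Row-1 rest lengths are sampled once.  Row-2 rest lengths are re-sampled
    until the two row totals agree within ``eps = mu * 1e-3``, where ``mu`` is
    the smaller of the type-specific average sampled lengths in the
    configuration; row 2 is then rescaled uniformly so the totals match
    exactly, which lets the end vertices be pinned identically.  Cells start
    at their rest lengths, so vertices are the cumulative sums from a common
    origin at 0.

    For the rare row-1 draws whose total sits far in the tail of the row-2
    sum distribution, plain rejection becomes arbitrarily slow; in that case
    the closest candidate is projected onto the constraint surface using the
    exact Gaussian conditional of the lengths given their sum (the
    distributional limit of the rejection scheme as its tolerance shrinks),
    so deposition succeeds for every seed without biasing the law.

    Raises
    ------
    SamplingError
        If the constraint cannot be satisfied at all, e.g. zero-variance
        rows whose type compositions force unequal totals; the error carries
        the best residual reached.
    """
    if rng is None:
        rng = np.random.default_rng()
    if len(labels_row1) != len(labels_row2):
        raise ConfigurationError("both rows must have the same cell count")
    if max_attempts < 1:
        raise ConfigurationError("max_attempts must be >= 1")

    l0_row1 = sample_rest_lengths(labels_row1, params, rng)
    total1 = l0_row1.sum()

    # mu: smaller of the empirical type-averaged lengths of the fixed row
    type_means = [
        l0_row1[[lab == want for lab in labels_row1]].mean()
        for want in LABELS
        if want in labels_row1
    ]
    mu = float(min(type_means))
    eps = mu * 1e-3

    best = np.inf
    best_cand = None
    l0_row2 = None
    for _ in range(max_attempts):
        cand = sample_rest_lengths(labels_row2, params, rng)
        resid = abs(cand.sum() - total1)
        if resid < best:
            best = resid
            best_cand = cand
        if resid < eps:
            l0_row2 = cand
            break
    if l0_row2 is None:
        # conditional-Gaussian projection: X | sum(X) = s shifts each length
        # by the residual weighted by its variance share
        variances = np.array([params[lab].std ** 2 for lab in labels_row2])
        var_total = variances.sum()
        if var_total > 0:
            shifted = best_cand + (total1 - best_cand.sum()) * variances / var_total
            if (shifted > 0).all():
                l0_row2 = shifted
    if l0_row2 is None:
        raise SamplingError(
            f"equal-length constraint |dL| < {eps:.3g} unmet after "
            f"{max_attempts} attempts (best residual {best:.3g})",
            best_residual=best,
        )
    # exact end pinning: uniform rescale of row 2 (relative change < 1e-3)
    l0_row2 = l0_row2 * (total1 / l0_row2.sum())

    vertices = np.zeros((2, len(labels_row1) + 1))
    vertices[0, 1:] = np.cumsum(l0_row1)
    vertices[1, 1:] = np.cumsum(l0_row2)
    vertices[1, -1] = vertices[0, -1]  # guard against roundoff in the cumsum
    types = np.array(
        [[LABEL_TO_CODE[s] for s in labels_row1], [LABEL_TO_CODE[s] for s in labels_row2]],
        dtype=np.int8,
    )
    return TissueConfiguration(
        vertices, types, np.vstack([l0_row1, l0_row2]), pattern_unit=pattern_unit
    )


def make_tissue(
    pattern: str = WILDTYPE_PATTERN,
    n_cells: int = WILDTYPE_N_CELLS,
    params: Mapping[str, TypeLengthParams] = DEFAULT_LENGTH_PARAMS,
    rng: np.random.Generator | int | None = None,
    pattern_row2: str | None = None,
) -> TissueConfiguration:
    """Convenience wrapper: pattern both rows and deposit them.

    Both rows share one pattern instance by default (sister cells have
    matching types, as in the wild-type heart); pass ``pattern_row2`` to give
    the second row a different pattern, e.g. for cell-number defects.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    labels1 = make_pattern(pattern, n_cells)
    labels2 = make_pattern(pattern_row2, n_cells) if pattern_row2 else list(labels1)
    unit = pattern if pattern in ("all-S", "all-T") or pattern_row2 else pattern
    return deposit_rows(labels1, labels2, params, rng, pattern_unit=unit)


def config_from_csv(path_or_buf) -> TissueConfiguration:
    """Build a configuration from measured leading-edge lengths.

    Expects columns ``row,index,type,length_um``.  Lengths become both the
    rest lengths and the initial cell lengths; row 2 is rescaled uniformly so
    the two totals coincide (pinned ends).
    """
    df = pd.read_csv(path_or_buf)
    required = {"row", "index", "type", "length_um"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"CSV must have columns {sorted(required)}")
    n = int(df["index"].max())
    l0 = np.zeros((2, n))
    types = np.zeros((2, n), dtype=np.int8)
    for r in (1, 2):
        sub = df[df["row"] == r].sort_values("index")
        if len(sub) != n:
            raise ConfigurationError("rows must have equal cell counts")
        l0[r - 1] = sub["length_um"].to_numpy()
        types[r - 1] = [LABEL_TO_CODE[s] for s in sub["type"]]
    if (l0 <= 0).any():
        raise ConfigurationError("measured lengths must be positive")
    l0[1] *= l0[0].sum() / l0[1].sum()
    vertices = np.zeros((2, n + 1))
    vertices[0, 1:] = np.cumsum(l0[0])
    vertices[1, 1:] = np.cumsum(l0[1])
    vertices[1, -1] = vertices[0, -1]
    return TissueConfiguration(vertices, types, l0)
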