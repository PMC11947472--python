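"""Ensemble studies over the two simulators.

This module packages the in-silico experiment battery: size scaling of the
no-adhesion mismatch, the gamma sweep and its master curve, effective
temperature sweeps, spatial profiles, genotype-to-parameter mapping with
gamma inference, cell-number defect runs, and stiffness sweeps of the dynamic
model.  All ensembles derive their replicate seeds from a single master seed
by fixed increments, so every statistic is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .energetics import AdhesionParameters, gamma as gamma_of, params_from_gamma
from .errors import ConfigurationError
from .geometry import (
    DEFAULT_LENGTH_PARAMS,
    TissueConfiguration,
    TypeLengthParams,
    WILDTYPE_N_CELLS,
    WILDTYPE_PATTERN,
    make_tissue,
)
from .metropolis import MCMCSettings, run, steady_state_mismatch
from .mismatch import MismatchProfile, pair_mismatches, spatial_profile, tissue_mismatch
from .vertex_dynamics import (
    DynamicsTrace,
    VertexDynamicsParameters,
    run_dynamics,
    time_to_min_mismatch,
)

#: Default replicate count per condition ("simulated embryos").
DEFAULT_N_REPLICATES = 30

#: Offset separating geometry seeds from Markov-chain seeds derived from one
#: master seed, keeping all derived seeds well below 2**31 for small masters.
_CHAIN_SEED_OFFSET = 500_000

ConfigFactory = Callable[[int], TissueConfiguration]


def tissue_factory(
    pattern: str = WILDTYPE_PATTERN,
    n_cells: int = WILDTYPE_N_CELLS,
    length_params: Mapping[str, TypeLengthParams] = DEFAULT_LENGTH_PARAMS,
    pattern_row2: str | None = None,
) -> ConfigFactory:
    """A seed -> configuration factory for ensemble runs."""

    def make(seed: int) -> TissueConfiguration:
        return make_tissue(
            pattern, n_cells, length_params, rng=seed, pattern_row2=pattern_row2
        )

    return make


@dataclass
class EnsembleResult:
    """Steady-state summary of one simulated condition."""

    params: AdhesionParameters
    gamma: float
    replicate_seeds: list[int]
    mismatches: np.ndarray          # per-replicate steady-state means
    replicate_sems: np.ndarray
    converged: np.ndarray           # per-replicate convergence flags
    final_configs: list[TissueConfiguration] = field(repr=False, default_factory=list)
    initial_mismatches: np.ndarray | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.mismatches)

    @property
    def mean(self) -> float:
        return float(self.mismatches.mean())

    @property
    def sem(self) -> float:
        if self.n_replicates < 2:
            return 0.0
        return float(self.mismatches.std(ddof=1) / np.sqrt(self.n_replicates))


def run_ensemble(
    config_factory: ConfigFactory,
    params: AdhesionParameters,
    settings: MCMCSettings,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
    tail_fraction: float = 0.5,
    keep_configs: bool = True,
    drop_nonconverged: bool = False,
) -> EnsembleResult:
    """Equilibrate ``n_replicates`` independent geometries and aggregate.

    Replicate ``k`` uses geometry seed ``master_seed + k`` and chain seed
    ``master_seed + 500000 + k``.  Non-converged replicates are flagged and,
    only if ``drop_nonconverged``, excluded from the aggregate.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    seeds, means, sems, conv, inits, finals = [], [], [], [], [], []
    for k in range(n_replicates):
        geom_seed = master_seed + k
        cfg = config_factory(geom_seed)
        inits.append(tissue_mismatch(cfg))
        traj = run(cfg, params, replace(settings, seed=master_seed + _CHAIN_SEED_OFFSET + k))
        m, s = steady_state_mismatch(traj, tail_fraction)
        seeds.append(geom_seed)
        means.append(m)
        sems.append(s)
        conv.append(traj.converged)
        if keep_configs:
            finals.append(traj.final_config)
    means_a = np.asarray(means)
    conv_a = np.asarray(conv)
    if drop_nonconverged and conv_a.any():
        keep = conv_a
        means_a = means_a[keep]
    return EnsembleResult(
        params=params,
        gamma=gamma_of(params),
        replicate_seeds=seeds,
        mismatches=means_a,
        replicate_sems=np.asarray(sems),
        converged=conv_a,
        final_configs=finals,
        initial_mismatches=np.asarray(inits),
    )


# ------------------------------------------------------------- size scaling
def initial_mismatches(
    n_cells: int,
    pattern: str = "all-T",
    length_params: Mapping[str, TypeLengthParams] = DEFAULT_LENGTH_PARAMS,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
) -> np.ndarray:
    """Per-replicate mismatch of freshly deposited configurations.

    With zero adhesion and cells at rest length there is nothing to
    equilibrate: the initial condition *is* the steady state, so the
    no-adhesion (gamma = 0) mismatch level is read off directly.
    """
    factory = tissue_factory(pattern, n_cells, length_params)
    return np.array(
        [tissue_mismatch(factory(master_seed + k)) for k in range(n_replicates)]
    )


def sweep_size(
    n_values: Sequence[int],
    pattern: str = "all-T",
    length_params: Mapping[str, TypeLengthParams] = DEFAULT_LENGTH_PARAMS,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
) -> pd.DataFrame:
    """No-adhesion initial mismatch versus row size N.

    Boundary pinning aligns only the two ends; in between, independent cell
    widths accumulate offsets like a Brownian bridge, so the mismatch grows
    with N.
    """
    rows = []
    for n in n_values:
        if n < 2:
            raise ConfigurationError("system sizes must be >= 2")
        m = initial_mismatches(n, pattern, length_params, n_replicates, master_seed)
        rows.append(
            dict(
                n_cells=n,
                mean=m.mean(),
                sem=m.std(ddof=1) / np.sqrt(len(m)) if len(m) > 1 else 0.0,
                n_replicates=len(m),
            )
        )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- gamma sweep
@dataclass
class MasterCurve:
    """Monotone-regularised mismatch-vs-gamma curve used for inference."""

    gamma: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    mean_isotonic: np.ndarray

    @classmethod
    def from_results(cls, results: Sequence[EnsembleResult]) -> "MasterCurve":
        order = np.argsort([r.gamma for r in results])
        g = np.array([results[i].gamma for i in order])
        m = np.array([results[i].mean for i in order])
        s = np.array([results[i].sem for i in order])
        iso = isotonic_regression(m, increasing=False).x
        return cls(gamma=g, mean=m, sem=s, mean_isotonic=np.asarray(iso))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(gamma=self.gamma, mean=self.mean, sem=self.sem,
                 mean_isotonic=self.mean_isotonic)
        )


def sweep_gamma(
    gamma_grid: Sequence[float] | None = None,
    params_list: Sequence[AdhesionParameters] | None = None,
    K: float = 1.0,
    eps_ST: float = 0.0,
    config_factory: ConfigFactory | None = None,
    settings: MCMCSettings | None = None,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
) -> list[EnsembleResult]:
    """Equilibrium mismatch across a gamma grid (or explicit epsilon triples).

    All conditions share the same geometry seed set, so points differ only in
    their adhesion parameters.  Pass ``params_list`` to probe different
    (eps_SS, eps_TT, eps_ST) splits — equal-gamma splits collapse onto the
    same curve.
    """
    if (gamma_grid is None) == (params_list is None):
        raise ConfigurationError("provide exactly one of gamma_grid or params_list")
    if params_list is None:
        params_list = [params_from_gamma(g, K=K, eps_ST=eps_ST) for g in gamma_grid]
    if not params_list:
        raise ConfigurationError("empty parameter grid")
    config_factory = config_factory or tissue_factory()
    settings = settings or MCMCSettings()
    return [
        run_ensemble(config_factory, p, settings, n_replicates, master_seed)
        for p in params_list
    ]


def sweep_temperature(
    E0_grid: Sequence[float],
    params: AdhesionParameters,
    settings: MCMCSettings | None = None,
    config_factory: ConfigFactory | None = None,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Steady-state mismatch versus effective temperature at fixed gamma."""
    settings = settings or MCMCSettings()
    config_factory = config_factory or tissue_factory()
    rows = []
    for e0 in E0_grid:
        if not e0 > 0:
            raise ConfigurationError("E0 values must be > 0")
        res = run_ensemble(
            config_factory, params, replace(settings, E0=e0), n_replicates, master_seed
        )
        rows.append(dict(E0=e0, mean=res.mean, sem=res.sem, gamma=res.gamma))
    return pd.DataFrame(rows)


# --------------------------------------------------------- genotype mapping
GENOTYPES = (
    "WT",
    "svp_null",
    "fas3_null",
    "tenm_null",
    "double_null",
    "svp_gal4_fas3_oe",
    "svp_gal4_fas3_rnai",
)


@dataclass(frozen=True)
class GenotypeSpec:
    """A genotype and the adhesion-component gammas that parameterise it.

    ``gamma_fas3`` and ``gamma_tenm`` are the contributions of the two
    adhesion molecules to the wild-type gamma (μm); the wild type carries
    their sum, and each mutant keeps only the components whose differential
    expression pattern survives.
    """

    name: str
    gamma_fas3: float = 0.25
    gamma_tenm: float = 0.25
    K: float = 1.0
    pattern_override: str | None = None

    def __post_init__(self) -> None:
        if self.name not in GENOTYPES:
            raise ConfigurationError(
                f"unknown genotype {self.name!r}; expected one of {GENOTYPES}"
            )
        if self.gamma_fas3 < 0 or self.gamma_tenm < 0:
            raise ConfigurationError("component gammas must be >= 0")


def genotype_to_params(
    spec: GenotypeSpec,
) -> tuple[str, float, AdhesionParameters]:
    """Map a genotype to (pattern, gamma, adhesion parameters).

    Loss of a molecule removes its differential-adhesion contribution; loss
    of the Svp fate (``svp_null``) or of both molecules flattens all
    differences (gamma = 0).  Uniform Fas3 overexpression removes the Fas3
    differential but keeps Ten-m's; Fas3 RNAi in Svp cells removes Fas3 from
    cells that barely expressed it, leaving gamma near wild type.  The
    epsilon triple splits gamma * K evenly between eps_SS and eps_TT with
    eps_ST = 0.
    """
    gf, gt = spec.gamma_fas3, spec.gamma_tenm
    mapping = {
        "WT": (WILDTYPE_PATTERN, gf + gt),
        "svp_null": ("all-T", 0.0),
        "fas3_null": (WILDTYPE_PATTERN, gt),
        "tenm_null": (WILDTYPE_PATTERN, gf),
        "double_null": (WILDTYPE_PATTERN, 0.0),
        "svp_gal4_fas3_oe": (WILDTYPE_PATTERN, gt),
        "svp_gal4_fas3_rnai": (WILDTYPE_PATTERN, gf + gt),
    }
    pattern, g = mapping[spec.name]
    if spec.pattern_override is not None:
        pattern = spec.pattern_override
    return pattern, g, params_from_gamma(g, K=spec.K)


@dataclass(frozen=True)
class GammaEstimate:
    """Inverse-interpolated gamma with an interval and a saturation flag."""

    value: float
    lower: float
    upper: float
    flag: str  # "ok", "clamped_zero" (above the curve) or "lower_bound" (plateau)


def infer_gamma(
    mismatch: float,
    error: float,
    curve: MasterCurve,
) -> GammaEstimate:
    """Read gamma off the master curve for a measured mismatch ± error.

    The curve is monotone-regularised (non-increasing) before inversion.  A
    mismatch above the gamma = 0 level clamps to 0; one below the plateau
    returns the largest grid gamma flagged as a lower bound (the curve is too
    flat there to resolve gamma).
    """
    if len(curve.gamma) == 0:
        raise ConfigurationError("empty master curve")
    g, iso = curve.gamma, curve.mean_isotonic

    def invert(m: float) -> tuple[float, str]:
        if m >= iso[0]:
            return float(g[0]), "clamped_zero" if m > iso[0] else "ok"
        if m <= iso[-1]:
            return float(g[-1]), "lower_bound" if m < iso[-1] else "ok"
        # iso is non-increasing; reverse for np.interp
        return float(np.interp(m, iso[::-1], g[::-1])), "ok"

    value, flag = invert(mismatch)
    sem_local = float(np.interp(value, g, curve.sem))
    total = float(np.hypot(error, sem_local))
    upper, _ = invert(mismatch - total)
    lower, _ = invert(mismatch + total)
    return GammaEstimate(value=value, lower=lower, upper=upper, flag=flag)


# ------------------------------------------------------------ defect studies
@dataclass
class DefectReport:
    """Before/after alignment of type boundaries for mismatched patterns."""

    ensemble: EnsembleResult
    boundary_offsets_initial: np.ndarray   # per replicate, mean |offset| (μm)
    boundary_offsets_final: np.ndarray
    n_boundaries: int


def _type_boundary_positions(config: TissueConfiguration, row: int) -> np.ndarray:
    t = config.types[row - 1]
    idx = np.nonzero(np.diff(t.astype(int)) != 0)[0] + 1
    return config.vertices[row - 1][idx]


def boundary_offsets(config: TissueConfiguration) -> np.ndarray:
    """|x_boundary_row1 - x_boundary_row2| for order-paired type boundaries."""
    b1 = _type_boundary_positions(config, 1)
    b2 = _type_boundary_positions(config, 2)
    n = min(len(b1), len(b2))
    if n == 0:
        return np.empty(0)
    return np.abs(b1[:n] - b2[:n])


def defect_experiment(
    pattern_row1: str,
    pattern_row2: str,
    params: AdhesionParameters,
    settings: MCMCSettings | None = None,
    n_cells: int = WILDTYPE_N_CELLS,
    length_params: Mapping[str, TypeLengthParams] = DEFAULT_LENGTH_PARAMS,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
) -> DefectReport:
    """Equilibrate rows carrying different cell-type patterns.

    Sister pairing stays by index even when the patterns differ; the
    defect-specific readout is how far the corresponding type boundaries on
    the two rows sit from each other before and after equilibration.
    """
    settings = settings or MCMCSettings()
    factory = tissue_factory(pattern_row1, n_cells, length_params, pattern_row2)
    init_offsets = []
    for k in range(n_replicates):
        cfg = factory(master_seed + k)
        off = boundary_offsets(cfg)
        init_offsets.append(off.mean() if off.size else np.nan)
    result = run_ensemble(factory, params, settings, n_replicates, master_seed)
    fin_offsets = []
    n_b = 0
    for cfg in result.final_configs:
        off = boundary_offsets(cfg)
        n_b = max(n_b, off.size)
        fin_offsets.append(off.mean() if off.size else np.nan)
    return DefectReport(
        ensemble=result,
        boundary_offsets_initial=np.asarray(init_offsets),
        boundary_offsets_final=np.asarray(fin_offsets),
        n_boundaries=n_b,
    )


# --------------------------------------------------------- dynamics ensembles
@dataclass
class DynamicsEnsemble:
    """Aligned mismatch traces of dynamic runs over an ensemble of geometries."""

    times: np.ndarray
    mismatch: np.ndarray           # (n_replicates, n_times)
    final_configs: list[TissueConfiguration] = field(repr=False, default_factory=list)
    n_censored: int = 0

    @property
    def mean(self) -> np.ndarray:
        return self.mismatch.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = self.mismatch.shape[0]
        if n < 2:
            return np.zeros(self.mismatch.shape[1])
        return self.mismatch.std(axis=0, ddof=1) / np.sqrt(n)


def run_dynamics_ensemble(
    config_factory: ConfigFactory,
    params: VertexDynamicsParameters,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
    record_every: int = 100,
) -> DynamicsEnsemble:
    """Integrate the vertex model over an ensemble of deposited geometries."""
    traces: list[DynamicsTrace] = []
    for k in range(n_replicates):
        traces.append(run_dynamics(config_factory(master_seed + k), params, record_every))
    times = traces[0].times
    mm = np.vstack([t.tissue_mismatch for t in traces])
    n_cens = sum(time_to_min_mismatch(t)[1] for t in traces)
    return DynamicsEnsemble(
        times=times,
        mismatch=mm,
        final_configs=[t.final_config for t in traces],
        n_censored=int(n_cens),
    )


def sweep_stiffness(
    K_grid: Sequence[float],
    mode: str = "global",
    t0: float = 5.0,
    xi: float = 50.0,
    dt: float = 0.01,
    t_end: float = 60.0,
    fixed_K: float = 100.0,
    fixed_type: str = "T",
    config_factory: ConfigFactory | None = None,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
    record_every: int = 100,
    tol_fraction: float = 0.05,
) -> pd.DataFrame:
    """Final mismatch and time-to-minimum versus elastic stiffness.

    ``mode="global"`` applies each K to every cell.  ``mode="asymmetric"``
    keeps cells of ``fixed_type`` at ``fixed_K`` and applies the grid K to
    the other type, probing whether one compliant cell population suffices
    for matching.

    The default tension and friction place the K grid astride the optimum
    within the ~1 h morphogenetic window: sister-boundary offsets are
    cumulative sums of per-cell width differences, so a tissue at stiffness K
    can absorb offsets of order N * t0 * L0 / K — far below the typical
    offset at the grid's top (rigid cells stall near their initial mismatch)
    and ample at the intermediate K — while the elastic relaxation time
    xi / K exceeds the window at the grid's bottom (compliant cells are too
    slow).  The closure speed t0 / xi covers the typical offset within the
    window.
    """
    if mode not in ("global", "asymmetric"):
        raise ConfigurationError("mode must be 'global' or 'asymmetric'")
    config_factory = config_factory or tissue_factory()
    rows = []
    for K in K_grid:
        if not K > 0:
            raise ConfigurationError("K values must be > 0")
        finals, t_mins, censored, inits = [], [], 0, []
        for k in range(n_replicates):
            cfg = config_factory(master_seed + k)
            if mode == "global":
                Kcell: float | np.ndarray = float(K)
            else:
                fixed_code = 1 if fixed_type == "T" else 0
                Kcell = np.where(cfg.types == fixed_code, fixed_K, float(K))
            p = VertexDynamicsParameters.from_t0(t0, K=Kcell, xi=xi, dt=dt, t_end=t_end)
            trace = run_dynamics(cfg, p, record_every)
            inits.append(trace.tissue_mismatch[0])
            finals.append(trace.tissue_mismatch[-1])
            t_min, cens = time_to_min_mismatch(trace, tol_fraction)
            t_mins.append(t_min)
            censored += cens
        finals_a = np.asarray(finals)
        rows.append(
            dict(
                K=K,
                mode=mode,
                final_mean=finals_a.mean(),
                final_sem=finals_a.std(ddof=1) / np.sqrt(len(finals_a))
                if len(finals_a) > 1 else 0.0,
                initial_mean=float(np.mean(inits)),
                time_to_min_mean=float(np.mean(t_mins)),
                censored_fraction=censored / n_replicates,
            )
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------ spatial profile
def ensemble_profile(
    result: EnsembleResult,
    pattern_unit: str = WILDTYPE_PATTERN,
    by: str = "position",
) -> list[MismatchProfile]:
    """Spatial mismatch profile over an ensemble's final configurations."""
    if not result.final_configs:
        raise ConfigurationError("ensemble was run with keep_configs=False")
    return spatial_profile(result.final_configs, pattern_unit, by=by)
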