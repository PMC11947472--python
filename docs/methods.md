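# Methods

## Geometry and the mismatch metric

The tissue is two rows of `N` cells on a shared 1D interface. A cell is the
interval between consecutive vertices of its row; the first and last
vertices of the two rows coincide and never move, so the total span is a
conserved quantity of every simulation (checked to machine precision in the
tests). Initial configurations come from random sequential deposition: row-1
rest lengths are drawn from type-specific Gaussians (non-positive draws are
redrawn, which preserves approximate normality at realistic coefficients of
variation rather than creating an atom at zero); row 2 is re-drawn until its
total rest length matches row 1 within `µ·10⁻³` (µ = the smaller
type-average length), then rescaled uniformly so the two totals coincide
exactly — required for exact end pinning, and a relative distortion below
10⁻³. For the rare seeds whose row-1 total lands several σ out in the row-2
sum distribution, rejection becomes arbitrarily slow; the sampler then
projects its closest candidate onto the constraint surface with the exact
Gaussian conditional of the lengths given their sum, which is the
distributional limit of the rejection scheme as the tolerance shrinks, so
every feasible seed deposits without bias. Cells start at rest length, and
rest lengths stay fixed for the whole run.

The per-cell mismatch is the fraction of a cell's length not overlapping its
sister (same index, opposing row). A transiently zero-length cell (possible
in the Metropolis chain, which allows moves that shrink a cell exactly to a
point) has zero overlap with anything and takes the limit value 1. The
tissue mismatch averages sister-pair means; spatial profiles pool pair
values by position within the repeating pattern unit over complete units
only.

## Equilibrium model

Energy: `E = Σ K (L−L0)² − Σ ε(pair)·len` over cells and interface segments.
The sign convention makes `ε ≥ 0` favourable adhesion, so the order
parameter `γ = (ε_TT − ε_ST + ε_SS − ε_ST)/K` (µm) is positive when
same-type contact is preferred and larger γ favours matching; an
unfavourable-adhesion formulation is recovered by negating ε. Segments are
attributed half-open to the cell covering their midpoint; zero-length
segments carry no energy either way.

Sampling is single-vertex Metropolis: a uniformly chosen interior vertex
(end vertices excluded), a Gaussian displacement with `δX = 0.05 µm`, and
acceptance `min(1, exp(−ΔE/E0))`. Moves that would push a vertex past a
same-row neighbour are rejected outright (strict inequalities: shrinking a
cell exactly to zero length is allowed, crossing is not). The effective
temperature defaults to `E0 = 0.1·K µm²`, an energy scale small against the
elastic cost of order-1 deformations; it models mechanical noise from
filopodia activity. ΔE is computed incrementally — two elastic terms plus
the ε-difference integrated over the swept interval against the opposing
row's segmentation — and the compiled kernel's running total is checked
against a full recomputation at the end of every run. One "iteration" is one
proposal; trajectories are recorded every `2(N−1)` proposals (≈ one sweep).

**Step budget and convergence.** At N = 52 and γ ≈ 0.5 the mismatch
transient spans roughly 2×10⁶ proposals, so the default budget is 4×10⁶ with
the steady-state statistic taken over the final half of the recorded series
(autocorrelation-corrected SEM via the initial-positive-sequence estimator).
A sliding-window slope test (window 1000 recorded samples, tolerance 2×10⁻⁵
per sample, chosen just above the measured slope noise of an equilibrated
series) may stop a run after at least half the budget; runs that never
flatten are flagged non-converged.

## Dynamic vertex model

`ξ dx/dt = (T_right − T_left) + K log(L_r/L0_r) − K log(L_l/L0_l)` per
interior vertex, synchronous explicit Euler at `dt = 0.01 min`. The two
tension terms belong to the interface segments immediately flanking the
vertex, each typed by the flanking own-row cell and the opposing row's cell
on that side; this reduces to a plain `T_{i+1} − T_i` difference when the
two rows' breakpoints coincide, and makes a negative tension extend the
contact it belongs to. The logarithmic elastic force matches `K(L−L0)` for
small deformations and diverges as a cell shrinks, preventing collapse in
the exact dynamics; a discretisation guard clamps any step to half the
adjacent gap above a 10⁻⁶ µm length floor (clamp events are counted and
exposed), and a step larger than a whole adjacent cell raises a timestep
error. Halving `dt` moves the final mismatch by < 10⁻³ at the default
parameters. The dynamics contain no stochastic forcing: a run is a
zero-temperature quench, deterministic given the initial configuration.

Defaults follow the kinetics studies: `K = 100 pN`, `ξ = 1000 pN·min/µm`,
tensions `T_SS = T_TT = −t0`, `T_ST = 0` with `t0` up to 2000 pN, horizon
600 min. Per-cell K is supported for asymmetric-stiffness studies; the
asymmetric sweep fixes one *cell type* (default T at K = 100) and varies the
other type's stiffness, since the two rows are symmetric by construction
while the two types are not.

**Stiffness-sweep regime.** Sister-boundary offsets are cumulative sums of
per-cell width differences, so a tissue at stiffness K can absorb offsets of
order `N·t0·L̄/K` by many small coherent deformations: observing a high-K
stall within a fixed grid `K ∈ {1, 10², 10⁴}` therefore requires
`t0 ≪ K_max/(N·L̄)`. The sweep defaults (`t0 = 5 pN`, `ξ = 50 pN·min/µm`,
60-min window) satisfy this while keeping the closure speed `t0/ξ` large
enough to finish within the window at the intermediate K, and the relaxation
time `ξ/K` longer than the window at the lowest K. With these conditions the
grid straddles the optimum: rigid tissue stays near its initial mismatch,
compliant tissue is too slow, the intermediate stiffness aligns best.

## Synthetic geometry generator

Rest-length distributions of the two types are configurable; the package
defaults (S: 4.0 ± 0.6 µm, T: 5.0 ± 0.5 µm) are placeholders chosen so that
the smaller Svp-like cells carry the larger relative variability — the
regime in which the spatial mismatch profile inverts at small γ — and are
*not* calibrated to measured cardioblast data, whose published distributions
exist only graphically. Statistical analyses in the tests and the acceptance
script use CV-10% geometry (std = 0.1·mean) where a common disorder level
matters. A CSV of measured leading-edge lengths (`row,index,type,length_um`)
can replace the Gaussian sampler entirely.

What the generator does *not* emulate: correlated cell sizes along a row, 2D
cell outlines and volume constraints, migration before contact, and
measurement noise. Passing tests therefore demonstrate properties of the
energy model under idealised i.i.d. geometric disorder, not agreement with
any particular measured heart.

## Ensembles, seeds and inference

Ensembles default to 30 replicates ("simulated embryos"); replicate k draws
its geometry from `master_seed + k` and its chain from
`master_seed + 500000 + k`, making every statistic bit-reproducible from one
master seed. The mismatch-vs-γ master curve is regularised by isotonic
(non-increasing) regression before inverse interpolation, since raw
Monte-Carlo noise breaks invertibility; inferred γ intervals combine the
stated measurement error with the curve's local SEM, mismatches above the
γ = 0 level clamp to 0, and values below the plateau return the largest grid
γ as a lower bound. Genotypes map to γ by keeping the components
(`γ_Fas3`, `γ_Tenm`, defaults 0.25 µm each) whose differential expression
survives; the ε triple splits `γ·K` evenly between `ε_SS` and `ε_TT` with
`ε_ST = 0`, which is immaterial at fixed γ by the collapse property.

## Numerical choices and caveats

- Incremental-vs-full energy agreement is asserted against a `math.fsum`
  recomputation with relative error anchored at the unit energy scale
  (`|Δ| ≤ 10⁻⁹·max(1, |ΔE|)`): a plain float64 subtraction of two O(10²)
  totals has ~10⁻¹³ absolute cancellation noise, which would dominate a pure
  relative comparison for the many proposals with |ΔE| < 10⁻⁴. The
  incremental path agrees with the fsum oracle to ~10⁻¹³.
- The Boltzmann validation enumerates exp(−E/E0) on a 30×30 grid with 4×4
  subcell integration (bin-centre weights alone leave an O(bin²/σ²)
  discretisation bias larger than the sampling noise at the coldest
  temperature).
- Two known systematic gaps, both structural rather than numerical: (i) a
  2-cell Svp block inside the tissue mismatches ~30–40% more than an
  isolated 2-cell no-adhesion system, because deposition's equal-total
  constraint suppresses cross-row offset variance in the isolated reference
  but acts only globally in the tissue; (ii) the deterministic vertex model
  settles ~0.006 mismatch *below* the equilibrium sampler at matched γ, the
  thermal broadening of the E0/K = 0.1 steady state that a zero-temperature
  quench lacks. Both comparisons are reported as ratios to 2× pooled SEM by
  the acceptance script rather than hidden.
- Kernel and reference paths (pure NumPy/Python implementations of the same
  operations) are cross-checked in the tests; the compiled kernels are the
  production path for long runs (~10⁷ proposals/s at N = 52).

## Limitations

1D leading-edge geometry only; no cell rearrangements, neighbour exchanges
or collective moves (the model's premise is that matching occurs without
them); no viscoelastic rest-length relaxation or active noise in the dynamic
model; heterogeneous per-cell K only in the dynamic model. The six-parameter
molecular decomposition of the adhesion energies is exposed only at the
level of component γs.
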