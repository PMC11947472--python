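# cellmatch

Simulators of **cell matching at a 1D tissue–tissue interface**, built around
the question of how two facing rows of cells find their correct partners
despite cell-size variability. The motivating system is the embryonic
*Drosophila* heart: two contralateral rows of 52 cardioblasts (a repeating
pattern of four Tin-positive and two Svp-positive cells) migrate into contact
and must align each cell with its contralateral sister before lumen
formation. The package is for biophysicists and developmental biologists who
want to explore when interfacial energy constraints alone are sufficient to
align cells, and to place measured alignment defects on a model scale.

## Model

Each cell `i` on row `r` is an interval between interface vertices,
`L_i = x_{i+1} - x_i`, with a type-specific Gaussian rest length `L0_i`. The
two rows share pinned end vertices. Alignment is scored by the **mismatch
ratio**

```
m_i = (L_i − overlap(i, sister_i)) / L_i  ∈ [0, 1],
```

averaged over sister pairs and the tissue. Two complementary simulators
evolve the same configuration:

**Equilibrium model.** Total energy

```
E = Σ_cells K (L_i − L0_i)²  −  Σ_segments ε(type pair) · segment length
```

with compressibility `K` and favourable adhesion energies `ε_SS, ε_TT, ε_ST`
per unit length of same-type and mixed interface segments. A Metropolis
chain proposes Gaussian vertex moves (`δX = 0.05 µm`) accepted with
probability `min(1, exp(−ΔE/E0))` at effective temperature `E0/K = 0.1 µm²`,
modelling filopodia-driven fluctuations. The steady-state mismatch depends
on the parameters only through the order parameter

```
γ = ((ε_TT − ε_ST) + (ε_SS − ε_ST)) / K    [µm],
```

the length change that adhesion differences can impose on a cell against its
elastic cost.

**Dynamic vertex model.** Overdamped dynamics
`ξ dx/dt = (T_right − T_left) + K log(L_right/L0_right) − K log(L_left/L0_left)`
with per-interface-type tensions (negative tension extends a contact),
integrated by explicit Euler (`dt = 0.01 min`). It resolves the *kinetics*
of matching: a fast tension-driven boundary-closing phase and a slow,
adhesion-independent elastic phase, with an optimal intermediate range of
cell stiffness inside a fixed morphogenetic time window.

## Worked example

```python
import cellmatch as cm

cfg = cm.make_tissue(rng=1)                 # 52 cells/row, TTTTSS pattern
params = cm.params_from_gamma(0.5)          # ε_SS = ε_TT = 0.25, ε_ST = 0, K = 1
traj = cm.run(cfg, params, cm.MCMCSettings(seed=2))
print(cm.tissue_mismatch(cfg), cm.steady_state_mismatch(traj))
```

prints (`examples/02_equilibrate.py`):

```
initial mismatch:       0.2262
steady-state mismatch:  0.1174 +- 0.0033
proposals run:          2040000  (converged: True)
```

Starting from purely geometric disorder (mismatch 0.23), adhesion at
γ = 0.5 µm halves the steady-state mismatch; the residual reflects cell-size
variability plus thermal fluctuations. Sweeping γ
(`examples/03_gamma_master_curve.py`) yields the monotone master curve —
0.27 at γ = 0 falling to a plateau of 0.09 by γ = 2 µm — and inverse
interpolation places a "measured" mismatch of 0.133 at
γ = 0.48 µm [0.38, 0.72]. The other examples cover size scaling of the
no-adhesion mismatch, vertex-model kinetics, genotype-to-γ mapping, and
cell-number defects.

A thin CLI wraps the same library for shell use:
`cellmatch equilibrate|dynamics|sweep-size|sweep-gamma|sweep-temperature|genotype|defects|sweep-stiffness --config cfg.yaml --out prefix`,
writing tidy CSVs plus a JSON manifest that replays the run bit-identically.

## Documentation

`docs/methods.md` describes the models, parameter choices, the synthetic
geometry generator and its limits, and known numerical caveats.
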