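# polyseg

Nonequilibrium phase-separation modelling of polysome-driven nucleoid
segregation in *Escherichia coli*, together with the single-cell
quantification statistics used to measure polysome/nucleoid asymmetries in
fluorescence microscopy, and a ground-truthed synthetic-data layer that
stands in for the microscopy so every analysis stage is testable.

## The science

In *E. coli*, the chromosome folds into a membrane-less organelle — the
nucleoid — that must be compacted, split and segregated to the two daughter
cells each division cycle, without any spindle. `polyseg` implements a
minimal mechanistic explanation: translating ribosome–mRNA complexes
(polysomes) are produced inside the nucleoid, sterically repel the DNA, and
are degraded everywhere, so the cytoplasm operates as a driven two-component
mixture that phase-separates and does mechanical work on the chromosome.

The mixture of nucleoid (local volume fraction *n*), polysomes (*p*) and
remaining cytosol (*s* = 1 − *p* − *n*) carries a Flory–Huggins free-energy
density

```
f(n, p) = p/v_p ln p + n/v_n ln n + s ln s
          + χ_p p s + χ_n n s + χ_np n p
          − κ_p ∇p·∇s − κ_n ∇n·∇s − κ_np ∇n·∇p,      κ_ij = λ² χ_ij
```

and evolves by Cahn–Hilliard transport plus linear reaction kinetics on the
rescaled cell axis x̃ = x/L(t) ∈ (0, 1) with no-flux boundaries:

```
∂p/∂t = ∂x̃ (M̃_p ∂x̃ μ_p) + k₁ n − (k₋₁ + γ) p
∂n/∂t = ∂x̃ (M̃_n ∂x̃ μ_n),        μ = δF/δ(field),  M̃ = v D (field) / L²
```

The cell grows exponentially, L(t) = L(0)·e^{γt}; growth dilutes polysomes
at rate γ while production compensates as k₁ = k₁₀(1 + γ/k₋₁).  Out of this
minimal loop come, with no further ingredients: mid-cell nucleoid
compaction in non-growing cells, polysome accumulation at mid-nucleoid
during growth, nucleoid splitting by spinodal decomposition once the
mid-cell polysome fraction crosses the spinodal, poleward migration of the
sister nucleoids, the negative trend of relative splitting time with growth
rate, a nearly constant cell length at splitting, and — for slowly relaxing
nucleoids — the new-pole/old-pole asymmetries newborn cells inherit from
their mother's mid-cell polysome accumulation.

The quantification layer implements the bespoke single-cell statistics used
to measure these effects in images: sub-pixel medial-axis cell coordinates,
polarity (new vs old pole) and the six lineage age classes, axial intensity
profiles with demographs/kymographs, peak–trough accumulation statistics,
three-Gaussian (polysome) and two-Gaussian (nucleoid) profile
decompositions with the derived asymmetries

```
Poly_asym  = log10(Area_new / Area_old)          Area = A σ √(2π)
Nuc_pos    = (l_new + l_old)/2 · l_cell/2
Nuc_comp   = A_new / A_old
Poly_space = (l_new − l_mid) / (l_mid − l_old)
```

rotated-2D-Gaussian particle localization, nucleoid counting/fusion
classification, rate estimators on tracked nucleoid segregation cycles,
and principal-component (total-least-squares) regression.

## Worked example

```python
import polyseg as ps

# one slow-growth generation from the symmetric steady state
cfg = ps.ModelConfig(growth=ps.GrowthSpec(gamma=0.25, L0=2.2))
init = ps.initial_steady_state(cfg)
traj = ps.simulate_generation(cfg, init)
event = ps.detect_splitting(traj)
print(f"split at t = {event.t_split:.0f} s "
      f"({100*event.relative_timing:.0f}% of the cycle), "
      f"L = {event.L_at_split:.2f} um")
```

prints

```
split at t = 9140 s (92% of the cycle), L = 4.12 um
```

— at a growth rate of 0.25 h⁻¹ the nucleoid splits late (92% into the
cycle) at a cell length of 4.1 μm.  Sweeping the ten growth rates
0.25–1.2 h⁻¹ with `ps.growth_rate_sweep()` shows the relative timing
falling monotonically from 0.92 to 0.52 while the splitting length stays
within a 2% coefficient of variation (4.12–4.39 μm), and the newborn cells
emerge with ~4% more polysome signal at the new pole and the nucleoid
centroid offset ~0.09 μm toward it.

A command-line interface covers the standard workflows:

```bash
polyseg simulate --config model.yaml --out run/
polyseg sweep    --config sweep.yaml --out sweep/
polyseg synth    --config synth.yaml --out bundle/ --seed 1
polyseg quantify --inputs bundle/ --out stats/
```

## Layout

- `polyseg.params` / `polyseg.fields` / `polyseg.energy` — parameter sets,
  field state and the free-energy functional;
- `polyseg.simulate` — the IMEX integrator, growth, division, chaining and
  the multi-species extension;
- `polyseg.experiments` — splitting detection, growth-rate and diffusivity
  sweeps, ectopic-production scenarios;
- `polyseg.geometry` — medial axes, pixel maps, polarity, age classes,
  nucleoid-cycle tracking;
- `polyseg.profiles` / `polyseg.gaussians` / `polyseg.particles` /
  `polyseg.fusion` / `polyseg.rates` — the quantification statistics;
- `polyseg.synth` — ground-truthed synthetic data;
- `polyseg.io` / `polyseg.cli` — configs, tidy tables, commands.

See `docs/methods.md` for the model assumptions, numerical scheme and the
design decisions behind the quantification layer.
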