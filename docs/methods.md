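# Methods

## The model

The cytoplasm is treated as a ternary regular solution of nucleoid material
(volume fraction *n*), polysomes (*p*, a single effective species covering
monosomes through long polysomes) and the remaining cytosol
(*s* = 1 − *p* − *n*).  The non-dimensionalised free-energy density is
Flory–Huggins with square-gradient interfacial terms,

    f = p/v_p ln p + n/v_n ln n + s ln s + χ_p p s + χ_n n s + χ_np n p
        − κ_p ∇p·∇s − κ_n ∇n·∇s − κ_np ∇n·∇p,        κ_ij = λ² χ_ij,

where v_p, v_n are the molecular volume factors of the elementary
translational units, the χ are dimensionless interaction parameters (χ_np
carries the DNA–polysome steric repulsion) and λ is a characteristic
interface width.  Dynamics combine conserved Cahn–Hilliard transport with
linear reaction kinetics: polysomes are produced inside the nucleoid at
rate k₁ and degraded uniformly at k₋₁; the nucleoid is transported but not
produced or degraded (replication keeps nucleoid amount proportional to
cell size, which the rescaled description absorbs).  Mobilities are
M_p = v_p D_p p and M_n = v_n D_n n, the dilute-limit forms that recover
Fick diffusion for non-interacting species.

Growth is exponential, L(t) = L(0)e^{γt}, and the problem is reduced to
the long axis rescaled to the unit interval, x̃ = x/L(t).  In rescaled
coordinates mobilities gain a factor L⁻², the interface width becomes
λ̃ = λ/L, and dilution appears as an extra −γp loss.  Production
compensates dilution as k₁ = k₁₀(1 + γ/k₋₁), which keeps nucleoid length
proportional to cell length across growth rates.  Chemical potentials are
the variational derivatives of F (the implementation drops the additive
entropy constants, which never enter the dynamics).

Defaults (changeable in `ModelConfig`): χ_p = 0.2, χ_n = 0.4, χ_np = 1.2,
v_p = 5, v_n = 10, λ = 0.03 μm, D_p = 0.023 μm²/s, D_n = 10⁻³ μm²/s
(with 5·10⁻⁴ and 5·10⁻³ used in the diffusivity sweep), k₁₀ = 2·10⁻³ s⁻¹,
k₋₁ = 3·10⁻³ s⁻¹ (a ~5 min mRNA half-life).  Birth length follows the
empirical regression L(0) = 2.00·exp(γ/2.81 h⁻¹) μm.

## Numerics

Space: N = 128 cell-centred grid points on (0, 1); no-flux boundaries are
realised by reflective ghost points, and all transport operators are in
conservative flux form with zero boundary fluxes, so the discrete integral
of a transported field is conserved to round-off.  A uniform state plus the
reaction balance is an exact fixed point of the discretisation.

Time: Δt = 0.05 s by default (halved automatically and the run restarted
if a field leaves (0,1) beyond the clipping band).  The stepper is a
linearised implicit–explicit (Rosenbrock-type backward Euler) scheme: the
own-field part of each transport operator — the quasi-linear second-order
term ∂x̃(M f''(u) ∂x̃ u) and the fourth-order interface term, with
mobilities and local curvature f'' frozen at the current state — is solved
implicitly as a pentadiagonal system; cross-field couplings and reactions
are explicit.  Writing J for the frozen Jacobian, the update is
u⁺ = u + (I − ΔtJ)⁻¹ Δt N(u), which leaves fixed points exactly invariant.
A simpler splitting that treats only a constant-coefficient bound of the
fourth-order term implicitly is unconditionally stable but quantitatively
wrong at this Δt: the global-bound filter also suppresses the genuine
interface motion (~20×), stalling relaxation; the frozen-Jacobian form does
not.  Logarithms are regularised by clipping fractions to [10⁻⁶, 1−10⁻⁶].

Division cuts the predivisional profiles at mid-domain, resamples the kept
half onto the full grid by linear interpolation with an exact integral
restoration, halves L and orients the daughter with its new pole (the
former division plane) at x̃ = 1.  When chaining across growth rates the
daughter is linearly rescaled to the next birth length.

Steady states are computed at frozen length (the growth rate still enters
the reaction terms) by iterating until max|Δfield|/Δt < 10⁻⁸ s⁻¹.  This
tolerance, and the initial condition of the compaction benchmark, are the
two choices the ~10³ s compaction-time anchor is sensitive to; both are
exposed in the API.  The benchmark cell is 2.2 μm long (the illustrative
slow-growth birth length; the birth-length regression is not extrapolated
to γ = 0, which lies outside its fitted range) with mean nucleoid fraction
0.30 spread as a broad central Gaussian (σ = 0.30 of cell length) and
polysomes homogeneous at the production–degradation balance.  A perfectly
flat nucleoid plateau is NOT used: it fragments by spinodal decomposition
into several blobs that coarsen extremely slowly, which is not the
compaction pathway the benchmark describes; a centrally peaked spread
compacts directly.

Multi-species polysomes (different diffusion coefficients for different
ribosome loads) each carry their own translational entropy,
μ_j = v_p⁻¹ ln p_j − ln s + interaction/interfacial terms in total p.  This
ideal-mixing form is essential: if the species shared literally one
potential, the composition field would be advected without any restoring
diffusion and develop grid-scale shocks.  The interfacial terms couple all
species through total p, so the implicit update solves one k·N banded
system.  With the default ±20% spread in D the species' normalised
profiles agree within ~5% of peak.

## In-silico experiments

Nucleoid splitting is detected when the nucleoid fraction at the central
grid point falls ≥30% below its running maximum since birth (the running
maximum makes the criterion robust to the initial transient; the obvious
alternative reference — the birth value — differs only during the
transient).
Relative timing is the split time over the birth-to-division interval.

The growth-rate sweep runs one generation per rate (0.25…1.2 h⁻¹), the
first from the symmetric steady state at its birth length, each subsequent
rate chained from the previous predivisional half so polarity asymmetries
propagate.  The diffusivity sweep compares the newborn (post-division)
profiles at γ = 0.57 h⁻¹ to the fixed-length steady state at the same
birth length; the deviation is the L² distance on the rescaled domain,
summed over both fields.  The steady state itself is independent of D_n
(which only sets relaxation speed), so the reference is relaxed once with
the largest D_n of the sweep.  Ectopic production adds k_ect(x) to the
polysome source — 0.8·k₁ within 0.8 μm of one pole, or 0.5·k₁ within
0.4 μm of mid-cell, both with nucleoid-templated production halved — and
is compared to a source-free control grown from the same initial state.

## Cell geometry

The medial axis of a segmented cell is extracted by taking the
morphological skeleton's longest path (the locus of points most distant
from the boundary, with spurs pruned), resampling it at 0.5 px, refining
every node to the sub-pixel ridge of the distance transform along the
local normal, fitting x and y separately as polynomials of the node number
with degree d = max(1, ⌊0.1·N_nodes − 5⌋), and extending linearly through
the pole caps — aimed at the centroid of each cap's pixels (mirror
symmetry puts that centroid on the axis) up to the sub-pixel boundary (the
0.5 contour of the interpolated distance transform).  The final axis is
resampled at 0.1 px arc spacing.  On synthetic bent rods (3–4.5 μm,
curvature up to 0.2 μm⁻¹) the axis is within 0.5 px of the true
centerline; short (≈2 μm) strongly bent cells are limited to ~0.8 px by
the degree rule itself (d = 1).

Pixels map to (length, signed width): arc position of the nearest axis
node and distance to it, signed by the cross product of the local axis
tangent with the projection-to-pixel vector.  (A centroid-referenced cross
product identifies the side only through the centroid's off-axis offset
and degenerates for straight cells.)

Polarity: the daughter pole closest to the mother's division site (the
interval edge shared by the sisters) is the new pole; relative coordinates
run old pole (−1) → centre (0) → new pole (+1).  Age classes follow the
six-lineage rules relative to the oldest mothers: class-1 same-polarity
daughters stay class 1, the opposite-polarity daughter founds class 2;
class-2 daughters found 3 (opposite) and 4 (same); class-3 daughters found
5 (same) and 6 (opposite); deeper branches are labelled beyond-6.

Nucleoid segregation cycles run from the end of one splitting event (the
frame where two objects are first resolved) to the end of the tracked
object's own splitting, possibly across a division, where the new-pole
nucleoid continues in the opposite-polarity daughter (inheritance group
±1) and the old-pole nucleoid in the same-polarity daughter (±2); the sign
encodes the daughter's own orientation.  Cycles interrupted by gaps or the
end of the recording are flagged incomplete and excluded from rate
analyses.

## Profile statistics

Axial profiles average the fluorescence of pixels within ±3 px of the axis
into ⌊(100/4.3)·l_cell⌋ bins (100 bins for a 4.3 μm cell), filling empty
bins by linear interpolation; optional smoothing is a moving average (edge
bins untouched) or a univariate spline.  Mean-percent scaling divides by
the whole-cell mean (×100), removing per-cell intensity variability.
Demographs stack profiles sorted by cell length; kymographs average
profiles per relative-cycle-time bin.

Peak–trough statistics take, for the nucleoid channel, the mean of the two
lobe maxima minus the trough between them, and for the polysome channel
the mid-cell maximum minus the mean of the flanking minima; extrema are
interior local extrema after light smoothing, and a profile lacking the
required extrema returns NaN (a flat profile returns 0).

Gaussian decompositions least-squares fit three (polysome: old pole, mid,
new pole; initialised at −0.9, 0, +0.9) or two (nucleoid lobes; ∓0.5)
Gaussians over a constant baseline, amplitudes ≥ 0 and means within
[−1, 1]; a fit is accepted when the residual RMS is below 15% of the
profile range (the acceptance threshold is a package choice).  The asymmetry statistics and their closed forms are in
the README.  Particle localization fits the rotated 2D Gaussian in a 7×7
window; masks above 90 px are split at the 90th intensity percentile
before fitting.  Nucleoid counting smooths the axial profile with a
fourth-order univariate spline (smoothing factor 10³) and counts peaks
above 125 a.u. — both tied to the original intensity scale and therefore
configurable.  Rates are OLS slopes per minute over the 40–90% window of
the nucleoid cycle (mid-nucleoid signals, 5 px window) or the quartiles of
the split-to-division interval (mid-cell polysome, ln inter-nucleoid
distance, ln cell length), excluding windows with <5 points, cycles with
negative elongation and cells born with two nucleoids.
Principal-component regression standardises both variables, takes the
first principal axis and maps it back — equivalent to reduced-major-axis
regression: slope sign(ρ)·σ_y/σ_x, exact on noiseless lines and symmetric
under axis exchange.

## Synthetic data

The generator emulates what the analysis assumes about microscopy-derived
inputs, with the script stored as ground truth: exponential single-cell
growth (γ ~ 0.57 h⁻¹ mean, 10% CV; birth length from the empirical
regression), division at mid-cell with recorded polarity over ≥2
generations; a polysome-like channel (baseline + two polar Gaussians with
a scripted new/old area ratio of 1.3 + a mid-cell component rising
linearly through the cycle) and a nucleoid-like channel (one lobe
splitting into two at 60% of the cycle with compaction asymmetry 1.25);
multiplicative lognormal per-cell intensity factors and additive Gaussian
noise (both default to zero so noiseless limits are exact); bent-rod
capsule masks with known sub-pixel centerlines; and rotated-Gaussian
particle spots matching the localization forward model exactly.

What the generator does not emulate: the microscope point-spread function
(which in real images attenuates mid-cell polysome accumulations),
segmentation errors, photobleaching, background gradients, or biological
cell-to-cell variability in the component *shapes*.  Passing the recovery
tests therefore demonstrates the correctness of the estimators on data
obeying their assumptions, not robustness to real-image artefacts.

## Problem sizes and limitations

The shipped experiments use the full N = 128 grid at Δt = 0.05 s; unit
tests run the same code at N = 32–64.  The growth-rate sweep (ten
generations, ~43,000 s of model time) runs in a few minutes on one core;
the compaction benchmark in ~10 s.  Known limitations: the model is 1D
(no width-direction physics, no transertion or membrane coupling), thermal
fluctuations are absent (symmetric states stay symmetric indefinitely, so
symmetry breaking must come from initial or inherited asymmetries), the
splitting-time anchor is sensitive to the unstated convergence criterion
and benchmark initial condition, and the medial axis degrades to ~0.8 px
on very short, strongly bent cells where the node-count degree rule forces
a linear fit.
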