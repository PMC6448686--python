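# Methods

## Scattering model

The equatorial small-angle intensity of wood is modelled as

I(q) = A·I_cyl(q) + B·exp(−q²/2σ²) + C·q^(−α),

with the three terms assigned to the cellulose microfibrils of the S2 cell
wall layer, larger pores / unassigned low-q features, and surface
scattering from pore and lumen walls respectively.

### Cylinder–lattice term

The microfibrils are treated as infinitely long circular cylinders on a 2D
hexagonal lattice with paracrystalline distortion of the second kind:
lattice-vector lengths fluctuate with SD Δa and the fluctuations
accumulate, so long-range order decays and the interference peaks broaden
with increasing order.  The decoupled composition

I_cyl = ⟨f²⟩_R − ⟨f⟩_R² + ⟨f⟩_R²·Z̃(q)

separates the diffuse polydispersity term from the coherent lattice term.
Assumptions built into this form: circular cross sections; radius and
position disorder independent; uniform rotation of crystallites about the
fibril axis (hence the plain arithmetic ψ-average); no instrumental
smearing (wavelength spread and collimation are out of scope).

- **Form factor.** f(q,R) = πR²·2J₁(qR)/(qR), the 2D Fourier transform of
  a disc.  A radius of exactly zero (a clipped quadrature node of a very
  wide distribution) contributes zero amplitude.
- **Normalisation.** I_cyl is divided by ⟨f(0)²⟩ = ⟨(πR²)²⟩, making it
  dimensionless and O(1).  This is a deliberate convention: it puts the
  fitted scale A on the same footing as B and C (all three contributions
  are comparable in magnitude on real curves, with the power law dominating
  the lowest q), and it leaves every structural parameter unaffected.  Any
  contrast and number-density constants are absorbed into A.
- **Radius quadrature.** 11 equally spaced nodes on
  [max(0, R̄ − 3ΔR), R̄ + 3ΔR], weighted by the Gaussian density and
  renormalised to sum to 1.  The truncation multiple k = 3 is a
  configurable choice; at the polydispersities of interest (ΔR/R̄ ≈ 0.2)
  the clipped tail is negligible.
- **Lattice factor.** Z(q,ψ) = Z₁·Z₂ with
  Z_k = (1−g²)/(1 − 2g·cos(qa·cos(ψ−ψ_k)) + g²), g = exp(−q²Δa²/2),
  basis directions at ψ₁ = 0 and ψ₂ = 60°.  The orientational average uses
  1001 uniform ψ values on [0, 2π); the 6-fold symmetry would permit a
  smaller grid, but the full grid is cheap and kept as the reference
  convention.  The average depends only on the reduced pair (q·a, Δa/a),
  which the implementation exploits throughout.

### Low-q modification

The paracrystalline factor diverges towards q → 0 (at ψ ≈ 90° the
denominator of Z_k collapses), an artefact of the ideal-paracrystal
algebra rather than physics.  The remedy: locate the first local minimum
q₀ of the ψ-averaged factor when scanning upward in q, and continue the
factor below q₀ as the constant Z̃(q₀).  The total intensity is then
continuous at q₀ by construction (the two-sided difference vanishes
linearly with the evaluation offset — there is no step), and the modified
and unmodified factors agree exactly for q ≥ q₀.

q₀ is found numerically at call time: a coarse scan in reduced units
(q·a from 0.1 to 9, step 0.02) brackets the first interior minimum, and a
bounded scalar minimisation refines it to 1e-10.  Because q₀·a is a
function of Δa/a alone, results are memoised on the reduced distortion
ratio; no precomputed polynomial is needed (one could be fitted from this
machinery as a cache, but the direct search costs ~1 ms).  A distortion
ratio in the working range (0.05–0.9) always yields a minimum near
q₀·a ≈ 2.7; note the *location* is nearly independent of Δa/a — it is the
plateau value Z̃(q₀) that rises steeply with distortion, which is how peak
broadening expresses itself here.

### Units

Internal computation uses ångström and Å⁻¹.  The flat parameter mapping
used by the fitting engine, file formats and CLI reports lengths in nm
(`d_mean` — mean fibril *diameter* 2R̄, `a` — lattice spacing) with
dimensionless relative widths `dR_rel` = ΔR/R̄ and `da_rel` = Δa/a, the
convention of results tables in this field.

## Pattern reduction

ϕ is measured counter-clockwise from detector +x in degrees; with the
fibre axis vertical, the equatorial maxima sit near ϕ = 0/180°.  The exact
mapping q = 4π·sin θ/λ with θ = ½·arctan(r/L) is used — no small-angle
approximation.  The separation assumes fibre symmetry (two arcs 180°
apart) and that the isotropic contribution is the azimuthal minimum at
each q; the latter is an approximation that biases slightly low in the
presence of counting noise (a minimum statistic) and breaks down if the
"isotropic" background is itself oriented.

Steps: (1) azimuthal profile on a thin annulus, (2) wrapped double-Gaussian
fit with a constant baseline anchored at the profile minimum → sector
centre ϕ₀ (mod 180°); a slope-free baseline is the default, (3) radial
average over the two opposite 25°-wide sectors, (4) subtraction of the
isotropic (per-q azimuthal minimum) curve, interpolated onto the sector
grid if needed; uncertainties propagate in quadrature and negative excess
values are retained as noise.  Curves from different detector distances
are merged by least-squares scale matching on the overlap and rebinned to
a log-spaced grid.

## Fitting

Bounded Levenberg–Marquardt (MINPACK via lmfit) on the residual
(I_obs − I_model)/(0.02·I_obs): every point carries a 2% relative error.
This weighting makes structural parameters exactly invariant under an
overall intensity rescaling.  1-SD uncertainties come from the Jacobian
covariance at the optimum and are reported only for free parameters; fixed
parameters are returned bit-identical to their recipe values.  Default
bounds are generous but physical (diameter 0.5–8 nm, spacing 1–10 nm,
Δa/a 0.02–0.9, α 3–5.5, σ ≤ 0.2 Å⁻¹).

Recipes encode the conventions for each curve type:

- **SANS**: ΔR/R̄ fixed (default 0.2) — the form-factor shoulder is too
  weak in SANS to constrain it; for dry samples the diameter may
  additionally be fixed at 2.0 nm.
- **SAXS (wet softwood)**: Gaussian term disabled; everything else free.
- **Drying series**: α fixed to 4 and σ bounded above by 0.08, reflecting
  the limited q range of a single short detector distance; each fit
  warm-starts from the previous converged result, and non-converged fits
  are flagged and kept (never silently dropped), with the next fit
  warm-starting from the last converged one.

Initialisation defaults are the wet-softwood reference rows in
`presets.py`; the optimiser is deterministic given data and recipe.

## WAXS

Least-squares fit of three crystalline Gaussians (initial centres 1.09,
1.21, 1.61 Å⁻¹, windowed ±0.12), an amorphous Gaussian (centre bounded to
1.1–1.7 Å⁻¹) and a line, on q ∈ [0.5, 2.25] Å⁻¹.  Residuals are
unweighted, so d and L are invariant under intensity scaling.  A result
whose fitted centres are not in ascending 1-10 < 110 < 200 order is
flagged (`ordered = False`).  Scherrer sizes use L = 2πK/Δq with the
integral-breadth convention Δq = SD·√(2π) and K = 1 (configurable and
recorded in the output); no instrumental-broadening deconvolution is
applied, so L is a lower-limit estimate of the true crystal dimension.

## Synthetic data

The generator produces: (i) 1D curves from the model with multiplicative
Gaussian noise (I_obs = I_model·(1+ε), ε ~ N(0, 2%) by default, matching
the weighting convention; σ_I stores the true 2% of I_model), (ii) 2D
fibre patterns — isotropic radial profile plus equatorial Gaussian arcs at
ϕ₀ and ϕ₀+180°, Poisson-sampled at a configurable exposure (doubling the
photon budget reduces relative noise by √2), on a SANS-like geometry
(λ = 6 Å, 1.5 m, 7.5 mm pixels, 128², covering q ≲ 0.3 Å⁻¹) — and
(iii) drying series whose truth ramps the spacing from 4.2 to 3.3 nm
(~20% contraction, softwood-like) and the diameter from 2.5 to 2.2 nm
while the power-law scale rises.  All outputs are deterministic per seed.

Because curves are drawn from the fitted model family itself, recovery
tests validate the estimator (bias, stability under ±20% start offsets,
correct uncertainty scale), not model adequacy on real wood; and the 2D
generator has ideal geometry — no detector point-spread, flat-field error,
parasitic scattering or wavelength smearing.  Passing tests therefore
demonstrate that the pipeline is self-consistent and numerically correct,
not that the model is the right description of any particular sample.

## Validation problem sizes

The recovery benchmarks use 20 replicates of 200-point curves
(SANS-like on q ∈ [0.005, 0.35] Å⁻¹, SAXS-like on [0.01, 0.5] Å⁻¹) at 2%
noise; the azimuthal-centre benchmark uses 100 Poisson patterns of 128²
pixels; the brute-force model oracle uses 10× denser ψ and radius grids on
50 q points.  These sizes give sub-percent Monte-Carlo error on the
reported means while keeping a full validation run around a minute.

## Known limitations

- No absolute-intensity calibration, resolution smearing or
  detector-specific corrections (assumed done upstream).
- Circular cross sections only; elliptical fibrils are not modelled.
- The isotropic-minimum separation underestimates the isotropic level
  slightly for noisy data, and the lowest-q annuli of small patterns
  suffer pixelation bias.
- The exact truncation of the radius grid (k = 3) and the constant
  continuation below q₀ are conventions; alternative shapings below q₀
  would change the lowest-q cylinder term but not the fitted structural
  parameters at the correlation peak.
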