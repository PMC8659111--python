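# Methods

This note records the models implemented in `nitroxkit`, the numerical
choices behind them, and what the synthetic-data tests do and do not
establish.

## Scope and division of labour

`nitroxkit` is the analysis layer of a composite protocol for nitroxide
radicals. Everything that requires an electronic-structure program —
geometry optimization, relaxed scans, Hessians, VPT2 force fields, spin
densities, PCM solvent shifts — is treated as *input*: tabulated scans,
frequency quadruples, coupling constants, or the packaged reference
tables. The package owns what happens after: geometric descriptors, the
1D variational treatment of the inversion motion, thermal averaging, the
cos²θ hyperfine model with its composite corrections, and the hybrid
frequency composition.

## Geometric descriptors

The out-of-plane angle θ is defined as 90° minus the angle between the
N→O vector and the normal of the C1–N–C2 plane, reported unsigned in
[0, 90]. The sign of the pyramidalization is dropped deliberately: the
two mirror minima of the inversion are physically equivalent and every
downstream model depends on θ only through cos²θ. The C1–C2–N–O improper
dihedral uses the standard atan2 torsion convention and is reported as
|τ| in (0, 180] (180° = planar). Both descriptors are provided, but no
algebraic conversion between them is asserted: the dihedral also depends
on the valence angles, so θ ≠ 180° − |τ| in general.

Ring puckering follows the original Cremer–Pople prescription: origin at
the geometric centre of the ring, mean plane normal to R′ × R″ with
R′ = Σ rⱼ sin(2πj/n), R″ = Σ rⱼ cos(2πj/n). This choice (rather than a
least-squares plane) guarantees Σzⱼ = 0 and the vanishing of the m = 1
Fourier components, hence Q² = Σ q_m² exactly. Ring sizes 5 and 6 are
supported; the m = n/2 alternation mode of an even ring is an amplitude
without a phase.

No bond perception is performed anywhere: the caller supplies core and
ring indices explicitly. This removes all cheminformatics ambiguity at
the cost of a little verbosity. A soft warning (not an error) fires when
the N–O distance exceeds 1.6 Å, the usual sign of a mis-assigned core.

## The inversion potential

The double well along θ is represented either by a tabulated scan (CSV,
degrees vs cm⁻¹, re-zeroed to its minimum on construction) or by the
two-parameter quartic V(θ) = B((θ/θ_eq)² − 1)². The quartic is an
explicit stand-in for an unpublished scan grid and is labelled as such in
CLI output; B ≈ 290–400 cm⁻¹ and θ_eq ≈ 25–26° are the relevant regime
for dialkyl nitroxides.

*Fitting.* `fit_quartic` is a bounded least-squares fit of (B, θ_eq) plus
a nuisance offset. The offset matters: a tabulated scan is re-zeroed to
its *sampled* minimum, which generally sits slightly above the true well
bottom, and without the offset the fit is biased even on noise-free data.
A scan whose interior shows no barrier between two minima raises a
dedicated error rather than returning a meaningless fit.

*Interpolation.* Tabulated scans are evaluated on DVR grids through a C²
cubic spline with not-a-knot end conditions. Natural ends were rejected:
they force zero curvature at the scan endpoints, exactly where a double
well is stiffest, and cost ~10 cm⁻¹ there at 21-point density, versus
< 0.05 cm⁻¹ interior error for not-a-knot. Extrapolation beyond the scan
range is refused.

*Barrier correction.* Transferring a higher-level barrier onto a
lower-level curve is implemented as uniform multiplicative scaling by
(target barrier)/(current barrier). This is the simplest scheme that
preserves the minima positions, keeps the wells at zero, and makes the
corrected barrier exact; it is isolated behind one function so a
shape-preserving alternative could be swapped in. Scaling composes
multiplicatively and is the identity at the current barrier.

## Sinc-DVR solver and thermal averaging

The 1D Hamiltonian uses the Colbert–Miller sinc-DVR for an unbounded
coordinate on a uniform grid: diagonal potential, closed-form kinetic
matrix with prefactor ħ²/2I = 16.8576292/I cm⁻¹ (θ in radians, I in
amu·Å²). The full dense symmetric matrix is diagonalized; grids here are
a few hundred points, so sparse machinery would be overhead. With
`auto_extend` the point count is doubled until the lowest ten eigenvalues
move by < 0.01 cm⁻¹.

Eigenvalues are reported relative to the potential as given, *not*
re-zeroed to the sampled grid minimum: scans are already normalized at
their nodes and the quartic's minimum is exactly zero, whereas
subtracting the sampled minimum injects a grid-phase-dependent offset of
order the potential's curvature times the squared off-grid distance of
θ_eq (~0.005 cm⁻¹ here), which is larger than the solver's own
convergence error and breaks eigenvalue monotonicity under refinement.
On the reference double well the solver agrees with an independent
4001-point fourth-order finite-difference diagonalization to < 10⁻³ cm⁻¹
and is converged to ~10⁻¹⁰ cm⁻¹ by ≈ 100 grid points.

**Effective inertia.** The kinetic prefactor of the inversion path is
system-specific and is a required argument — there is no defensible
universal default. Where this package needs a concrete number (tests,
examples) it uses I = m_O·r_NO² ≈ 16.0 × 1.280² ≈ 26.2 amu·Å², the
rigid-arm picture of the oxygen swinging about a fixed CNC frame. This is
an order-of-magnitude physical estimate chosen a priori; consequently the
thermally averaged numbers downstream (level spacings, the ~2 MHz a_N
correction, the ~4° inward shift of ⟨|θ|⟩) are checked as
order-of-magnitude gates (0.5–5 MHz), not as precise reproductions.

**Populations.** pᵢ ∝ exp(−(Eᵢ−E₀)/k_B T) with k_B = 0.6950348 cm⁻¹/K,
normalized over the computed levels lying below 90% of the grid's
potential range — levels near the grid ceiling are basis artifacts and
are excluded from Z. The reporting threshold for "retained" levels
defaults to 0.5%. Thermal averages use *all* populated levels, not only
the retained ones; retention is a presentation concept. Averages use the
DVR quadrature directly (unit weights, orthonormal vectors), which makes
⟨const⟩ exact and ⟨P⟩ linear and bounded by the range of P on the grid.

## Hyperfine model

The three (a, b) parameter sets of a_N(θ) = a·cos²θ + b ship as named
constants (CC: −71.65/102.35; B2: −78.78/108.53; B3: −78.53/103.47 MHz).
Only the published 2-decimal values are available, so comparisons against
the tabulated correction column carry a documented ±0.01 MHz tolerance
(the table was evidently generated from unrounded coefficients).
`delta_theta` defaults to the CC − B2 pair, i.e. 7.13·cos²θ − 6.18 MHz.
`delta_tm` is a plain difference of two user-supplied template couplings;
preparing the template geometry at the target's θ is a data-preparation
step outside this package. `fit_cos_squared` is closed-form OLS on the
regressor cos²θ with textbook standard errors; with few points those SEs
carry the t-distribution's heavier tails (7 dof at 9 points → ≈ 96%
joint coverage of the ±3·SE box, not the normal 99.7%).

Composite assembly adds base + Δvib + exactly one of {Δθ, ΔTM} + optional
Δsolv, with rounding (half-away-from-zero, matching printed tables)
applied only at presentation. On the packaged ledger the two correction
routes agree within 0.35 MHz for every molecule (one row reaches 0.34).

## Frequencies

ν_H = ω_B2 + (ν_B3 − ω_B3) is computed from unrounded inputs; against
integer-printed references a ±1 cm⁻¹ residue can survive because the
three inputs were rounded independently before printing (two of the
fifteen packaged rows show it). The B3 anharmonic shifts of all packaged
nitroxides fall in 28–34 cm⁻¹, which is why the constant −30 cm⁻¹ scheme
works. Error summaries report both the signed mean and the MAE, overall
and per family (acyclic; six-ring; saturated and unsaturated/aromatic
five-ring — the published family-level "mean error" figures are not
reconstructible from the table alone, and no statistic here claims to
match them). Mode selection keeps |K_iij|/ω_i ≥ threshold, strongest
first, with the NO stretch always included; it is monotone in the
threshold by construction.

## Synthetic data

Generators exist to make ground truth exact: cores are *constructed* so
the five descriptors equal the requested values (placement in canonical
frames, so the descriptor code is tested against geometry, not against
itself); rings are displaced along one pure Cremer–Pople mode so Q equals
the requested amplitude identically; coupling sets keep a ±10%-of-
threshold margin around the selection boundary so membership is
unambiguous; scans and a_N samples add iid Gaussian noise to closed-form
curves. Noise is iid Gaussian everywhere because the real inputs are
deterministic quantum-chemistry outputs — the noise exists to exercise
estimators, not to model an instrument. All generators are deterministic
given a seed.

What passing tests therefore show: the descriptors, solver, estimators
and composition rules are correct on inputs whose truth is known, and
the table-derived pipeline reproduces the printed reference numbers.
What they do not show: accuracy of the underlying electronic-structure
data, transferability of the cos² correction beyond the tabulated θ
range (0–23°), or the true effective inertia of any real inversion path.

## Problem sizes

Default test and acceptance runs use 21–41-point scans, DVR grids of
129–385 points (one 4001-point finite-difference oracle), 200–500-seed
Monte-Carlo loops, and the two 15-row packaged tables; the full suite
runs in a few seconds on one core.

## Known limitations

- 1D treatment only: no position-dependent inertia, no coupling of the
  inversion to other modes, no multi-well reaction-path Hamiltonian.
- The quartic stand-in is symmetric; genuinely asymmetric scans must be
  supplied as tables.
- ΔTM consumes numbers; it cannot validate that the supplied template
  couplings were computed at a matching geometry.
- Printed-precision parameters put a hard ±0.01 MHz floor under any
  comparison involving the packaged cos² constants.
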