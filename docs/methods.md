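# Methods

This note records the models, conventions and numerical choices behind
`spinline`, in the order the pipeline runs.

## Magnetic frames and conventions

A nitroxide's magnetic frame is built from its atomic geometry: z is the
unit cross product of the two N−C ring-bond unit vectors (the π-orbital
direction), x is the unit projection of the N−O bond onto the plane normal
to z, and y = z × x. Rotation matrices store the magnetic axes as columns in
lab coordinates, so a tensor with principal values `diag(T)` becomes
`R diag(T) Rᵀ` in the lab frame.

The cross-product sign depends on the order of the two ring carbons; the
package orders them by ascending atom index. Every observable downstream is
quadratic in the axes — P₂-based order parameters and autocorrelation
functions, and the spin Hamiltonian through `R diag(T) Rᵀ` — so this sign
convention never affects results; it only makes outputs bit-reproducible.

Directors are per leaflet: +z for the top leaflet, −z for the bottom,
assigned for MD input by the sign of the nitroxide N z-coordinate relative
to the bilayer midplane in the first frame (fixed box normal; instantaneous
leaflet normals are deliberately not computed — the bilayers this targets
are planar). Bond vectors from wrapped MD coordinates use the
minimum-image convention before normalization.

## Synthetic trajectory generator

The generator substitutes a single-body stochastic model for all-atom MD: a
rigid body carrying the magnetic frame, with axial rotational diffusion
tensor (D_par about the ordering axis, D_perp transverse, units rad²/ns) in
a uniaxial Maier–Saupe potential U/k_BT = −λ·P₂(cosθ) against the leaflet
director. This is the minimal model whose orientational ACFs have the
biexponential-plus-plateau shape the analysis layer fits, with plateau
S₀(λ)² given by the Boltzmann average that `equilibrium_order_parameter`
evaluates by quadrature. An optional cage sub-model lets the local director
itself diffuse (D_cage, λ_cage) about the global one, producing two well
separated decay times, as for a probe whose fast internal motion rides on
slow reorientation of its lipid surroundings.

Choices that matter:

- **Integrator.** Body-frame Euler–Maruyama: Gaussian angular increments of
  variance 2·D_i·dt about each body axis plus the deterministic torque
  −D_i ∂(U/k_BT)/∂φ_i, composed exactly (Rodrigues) and re-orthonormalized
  by modified Gram–Schmidt every step (orthonormality stays at machine
  precision). The invariant measure of Euler–Maruyama carries an O(dt)
  bias; at the default dt_internal = 1 ps it is below the sampling error of
  every test, and the integrator-consistency test (halving dt_internal)
  checks exactly this.
- **Initialization.** Orientations are drawn from the equilibrium
  distribution (rejection sampling in cosθ), so burn-in defaults to 0; a
  burn-in parameter exists for users who prefer to discard early frames.
- **Seeding.** One `SeedSequence` child stream per probe, spawned from the
  master seed, so increasing the probe count never reshuffles existing
  probes; identical parameters and seed give bit-identical trajectories.
- **Defaults** mirror the conditions the generator emulates: frames every
  20 ps, 12 probes (6 per leaflet) × 5000 frames (100 ns), i.e. a 1.2 µs
  concatenated record.
- **Frozen ensembles.** For rigid-limit work, `static_isotropic_trajectory`
  places the applied-field direction (in the magnetic frame) on a spherical
  Fibonacci grid — a deterministic, nearly uniform powder quadrature that
  reaches smooth powder patterns with ~10³ orientations where random
  sampling needs ~10⁵.

What the generator does **not** emulate: chemistry-specific effects
(hydrogen bonding, cholesterol contacts, internal chain isomerization).
These enter only through effective (λ, D) choices, so passing tests show the
spin-dynamics and analysis machinery is correct on trajectories with known
statistics — not that any particular lipid system is described.

## Spin propagation and line shapes

Electron S = 1/2 ⊗ ¹⁴N I = 1, rotating frame at the g_iso Larmor frequency,
high-field secular approximation with pseudo-secular hyperfine retained:

    H(t) = ΔB_g(t)·S_z + S_z·Σ_j a_j(t)·I_j,   a = n̂ᵀ A_lab,   [Gauss]
    ΔB_g = (n̂ᵀ g_lab n̂ − g_iso)/g_iso · B_center.

Non-secular S± terms are dropped, as is the nuclear Zeeman term (≤ 0.3 G at
X band). H block-diagonalizes into ±K with K = (ΔB_g + a·I)/2, so the
electron coherence block evolves as ρ → U ρ U with U = exp(−iγK·dt) — one
analytic 3×3 eigendecomposition per frame interval, which is also how
forbidden-transition mixing from the pseudo-secular terms enters. M(t) =
Tr ρ(t) starting from ρ(0) = 1/3 (equilibrium transverse condition,
M(0) = 1).

- **Piecewise-constant Hamiltonian** per frame interval, no interpolation:
  the phase error per step is bounded by γ·(anisotropy)·dt ≈ 0.012 rad for
  35 G and 20 ps.
- **Sliding window.** Window starts advance by `stride` frames (default 10)
  and never cross a probe boundary; the default window is 200 ns or the
  shortest block, whichever is smaller. M(t) is damped by exp(−t/T₂) with
  1/T₂ = γ·(√3/2)·residual_linewidth, so `residual_linewidth` (default
  1.0 G) is the peak-to-peak Lorentzian width it contributes to the
  derivative line.
- **FFT and field mapping.** Zero-padded FFT of M(t); a frequency offset Δω
  maps to field as ΔB = −Δω/γ about the center field hν/(g_iso β) — linear,
  adequate over a 100–200 G sweep; g anisotropy enters through the offset
  term. The last quarter of M(t) gets a cos² roll-off before the FFT: it
  suppresses truncation ringing from signal the damping has not yet
  removed and leaves fully decayed FIDs untouched. Windows of at least
  3·T₂ (≈ 200 ns at 1.0 G) keep the roll-off's own broadening negligible.
- **Support check.** If more than 1% of the peak absorption falls outside
  the requested field grid the spectrum is flagged `clipped` and a warning
  is raised. The default grid (3320–3420 G, 512 points at 9.55 GHz)
  brackets the center field; rigid-limit patterns need a wider window
  (≈ 3300–3500 G), which the tests set explicitly.
- **Powder (MOMD) averaging.** Gauss–Legendre quadrature in cosβ on [0, 1]
  (uniaxial symmetry halves the sphere), default 20 nodes; n_tilts = 1 is
  the aligned-membrane spectrum at β = 0. Absorptions are averaged before
  differentiation.
- **Normalization.** `max` divides the derivative by its global absolute
  maximum; `area` divides by the double integral of the derivative curve,
  so the area-normalized spectrum double-integrates to one by construction.

## Analysis layer

- **ACF.** C(lag) = ⟨P₂(v(τ)·v(τ+lag))⟩ averaged over all start times
  within blocks and over probes, on a log-spaced integer lag grid (default
  160 lags) capped at a third of the shortest block — the cap equalizes the
  sampling quality of the largest lags. Per-block curves can be kept for
  across-probe standard errors; for tight statistical tests the blocks are
  further split into ~100 ns segments (many more degrees of freedom for the
  error estimate).
- **Biexponential fit.** Nonlinear least squares in (S₀², w₁, ln τ₁, ln τ₂)
  with w₂ = 1 − w₁ eliminated, bounds 0 ≤ S₀² ≤ 1, 0 ≤ w₁ ≤ 1; initial τ₁
  from the 1/e crossing, τ₂ from the tail log-slope, plus 8 perturbed
  restarts with the best residual kept (biexponential fits are riddled with
  local minima). Fits are returned in canonical order τ₁ ≤ τ₂, with
  τ_eff = w₁τ₁ + w₂τ₂ exact by construction. A flat curve returns the
  plateau with the time constants flagged unidentifiable; non-convergence
  returns a flagged result with diagnostics, never an exception. The
  plateau gives only S₀²; the sign of S₀ is taken from the direct ⟨P₂⟩
  estimate.
- **Hubbell–McConnell splittings.** 2A′∥ is the separation of the outermost
  prominence-filtered low-field maximum and high-field minimum of the
  derivative curve (optionally refined by parabolic interpolation). The
  inner splitting 2A′⊥ is read from the absorption maxima flanking the
  central line, where the central line is the absorption peak nearest the
  absorption centroid (robust against the g-anisotropy skew of the outer
  extrema). If no flanking maxima are resolved — typical for fast spectra —
  A′⊥ falls back to trace preservation, (3a_iso − A′∥)/2, and the result is
  flagged. In the fast-motion regime the estimate recovers the imposed
  order parameter to a few hundredths; for τ ≳ 5 ns it overestimates it,
  because the formula assumes fast partial averaging of the tensors — both
  behaviors are asserted in the tests.
- **S_CD profiles** average P₂ of the C−H angle against the normal per
  carbon, per leaflet; hydrogens must be mapped explicitly (no
  reconstruction).
- **Projected RDFs** histogram minimum-image pair distances in the bilayer
  plane (2d) or in 3d, normalized by the ideal-gas annulus/shell and the
  partner density, excluding self-pairs for identical selections.
- **Flip-flop detection** uses hysteresis debouncing: a leaflet transition
  counts only when cosθ stays beyond ∓threshold for `dwell` consecutive
  frames.

## Problem sizes and seeds

Tests and the acceptance script generate everything at run time. Sizes were
chosen so each oracle is decisive at its stated tolerance: rigid-limit
powder 1024 Fibonacci orientations × 512 frames against 10⁵ random-stick
summation; motional-narrowing and splitting-regime fixtures 12 × 12 000
frames (240 ns per probe); order-parameter recovery at λ ∈ {0, 1, 3, 5}
12 × 60 000 frames with dt_internal = 0.25 ps (the λ = 0 case needs the
most data, since S₀ = √plateau amplifies plateau noise near zero);
convergence and cage fixtures 12 × 20 000 frames. All randomness flows
from explicit integer seeds (in the acceptance script, sub-seeds spawned
from `--seed`).

## Known limitations

- No saturation or modulation-amplitude distortion (2 mW, 1.0 G modulation
  assumed non-perturbing); X band only; ¹⁴N only.
- The frequency-to-field mapping is linear about the center field; fine for
  ≤ 200 G sweeps, not for multifrequency work.
- The Euler–Maruyama generator is first-order; its O(dt) equilibrium bias,
  while below sampling error at default steps, makes it a poor choice for
  high-precision free-energy work.
- The Hubbell–McConnell inner-splitting reader assumes a resolvable central
  line; heavily overlapped slow-motional spectra fall back to the
  trace-preservation estimate (flagged).
- `scd_profile` and `rdf_projected` operate on coordinate arrays; they do
  not unwrap molecules split across periodic boundaries beyond the
  minimum-image convention on pair vectors.
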