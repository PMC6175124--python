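# spinline

Trajectory-based simulation and analysis of nitroxide spin-probe CW EPR
spectra for lipid bilayers.

Continuous-wave EPR of nitroxide spin probes (5-PC and 16-PC doxyl
phosphatidylcholines, the cholestane probe CSL) reports on both the ordering
and the rotational dynamics of lipid membranes, but reading molecular detail
out of a line shape usually means fitting it with simplified motional models.
`spinline` goes the other way: given an orientational trajectory of the
probe's magnetic frame — extracted from an all-atom MD simulation or produced
by the package's own rotational Brownian-dynamics generator — it predicts the
X-band first-derivative spectrum directly, with no line-shape fitting, and
provides the accompanying trajectory and spectral analyses.

The package is aimed at membrane-biophysics and EPR groups who want to
connect MD simulations of spin-labelled bilayers to measured spectra, or to
study how ordering and dynamics shape nitroxide line forms on synthetic
trajectories with known ground truth.

## What it computes

**Spin dynamics.** The electron spin (S = 1/2) couples to the ¹⁴N nucleus
(I = 1) through anisotropic g and hyperfine tensors, so the resonance depends
on the orientation of the magnetic frame relative to the applied field. In
the rotating frame at the g_iso Larmor frequency, with the high-field secular
approximation (pseudo-secular hyperfine terms retained),

    H(t) = ΔB_g(t)·S_z + S_z · (n̂ᵀ A_lab(t)) · I      [Gauss],

the density matrix is propagated analytically (3×3 eigendecomposition per
20 ps frame interval), the transverse magnetization M(t) is averaged with
the sliding-time-window technique over all window start points and probes,
and the FFT of M(t), mapped linearly from frequency offset to field, gives
the absorption and its field derivative. Director (MOMD) averaging over
isotropically distributed bilayer normals is available for vesicle samples.

**Trajectory analysis.** Orientational autocorrelation functions
C(t) = ⟨P₂(v(τ)·v(τ+lag))⟩ with sliding-window averaging, fitted with

    C(t) = (1 − S₀²)[w₁ e^(−t/τ₁) + w₂ e^(−t/τ₂)] + S₀²,
    τ_eff = w₁τ₁ + w₂τ₂,

direct order parameters S₀ = ⟨(3cos²θ − 1)/2⟩ against the per-leaflet
director, and flip-flop detection.

**Spectral and structural analysis.** The Hubbell–McConnell estimate
S₀ = (A′∥ − A′⊥)/(A_zz − (A_xx + A_yy)/2) from the outer/inner hyperfine
splittings of a spectrum, deuterium order profiles S_CD(n), and radial
distribution functions projected onto the bilayer plane.

**Synthetic trajectories.** A seeded Euler–Maruyama integrator for a rigid
body with an axial rotational diffusion tensor in a Maier–Saupe potential
U/k_BT = −λ·P₂(cosθ), with an optional slowly diffusing local director
("cage") for two-timescale dynamics. The equilibrium order parameter
S₀(λ) is available independently by quadrature for ground-truth tests.

## Worked example

Twelve probes of 100 ns at 20 ps frame spacing (the concatenated record is
1.2 µs), moderately ordered and slow-tumbling:

```python
from spinline import (BrownianModelParams, SpinParameters, generate_trajectory,
                      powder_average, hubbell_mcconnell, acf_of_axis,
                      fit_biexponential, trajectory_order_parameter)

params = BrownianModelParams(
    D_parallel=0.5, D_perp=0.05, lambda_order=2.0,
    n_frames=5000, n_probes=12, seed=42,
)
traj = generate_trajectory(params)
acf = acf_of_axis(traj, "z")
s0_direct = trajectory_order_parameter(traj, "z")
fit = fit_biexponential(acf, sign_source=s0_direct)
print(f"direct S0          = {s0_direct:.3f}")
print(f"fitted S0 (ACF)    = {fit.S0:.3f}")
print(f"tau1, tau2         = {fit.tau1:.2f} ns, {fit.tau2:.2f} ns")
print(f"tau_eff            = {fit.tau_eff:.2f} ns  (w1 = {fit.w1:.2f})")

spin = SpinParameters(field_range=(3330.0, 3475.0), n_field_points=512)
spec = powder_average(traj, spin, n_tilts=12, window=60.0, stride=20)
m = hubbell_mcconnell(spec, spin, refine=True)
print(f"outer splitting 2A'par = {2*m.A_par_eff:.1f} G")
print(f"order parameter (HM)   = {m.S0_hm:.3f}")
```

prints

```
direct S0          = 0.413
fitted S0 (ACF)    = 0.410
tau1, tau2         = 1.15 ns, 3.15 ns
tau_eff            = 2.99 ns  (w1 = 0.08)
outer splitting 2A'par = 57.9 G
order parameter (HM)   = 0.751
```

The ACF plateau and the direct time average agree on S₀ ≈ 0.41. With
τ_eff ≈ 3 ns the probe is in the slow-motional regime: the outer splitting
(57.9 G) sits between the fully averaged (2a_iso ≈ 30 G) and rigid
(2A_zz = 67 G) limits, and the Hubbell–McConnell estimate — which assumes
fast partial averaging of the tensors — overestimates the order parameter
(0.75 vs 0.41), the characteristic low-temperature failure mode of the
splitting-based estimate.

A `spinline` command-line tool wraps the same pipeline
(`spinline run --config config.yaml`, plus `gen-traj`, `extract`,
`spectrum`, `analyze` and `fixtures` subcommands); every artifact is written
with a JSON provenance sidecar carrying the config hash, seeds and package
version.

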