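# Methods

## Physical model

N identical spherical particles (radius R, mass density ρ_m, volume
V = 4πR³/3) are fixed on a finite planar square lattice with
nearest-neighbor distance d (surface density ρ = 1/d², open boundaries, no
periodic images). Each carries a rigid point dipole μ**e**ᵢ locked to the
particle body; reorientation happens only by rotation of the whole
particle. The fluid enters through the Stokes rotational friction
ζ = 6ηV and a delta-correlated thermal torque of strength 2ζk_BT
(fluctuation–dissipation pairing), i.e. an underdamped rotational Langevin
equation per particle with the magnetic torque μ**e**ᵢ × **B**ᵢ. The local
field **B**ᵢ sums the point-dipole fields of all neighbors within a
real-space cutoff (default 100 nm — at contact density this truncates the
per-particle coupling energy by less than 0.02 k_BT, which the test suite
and acceptance script verify).

Deliberately excluded: internal (Néel) relaxation over finite anisotropy
barriers, translational motion, and hydrodynamic inter-particle coupling.
The Knudsen number K_n = Λ/(d − 2R), with Λ = 2.5 Å the water mean free
path, is reported per run and a warning is raised for K_n ≥ 0.1, where the
continuum-damping assumption becomes questionable (particles near
contact).

Default parameters (SI internally; config files use nm/ps/μ_B keys):

| parameter | default | meaning |
|---|---|---|
| T | 320 K | bath temperature |
| η | 7·10⁻⁴ Pa·s | water viscosity near 320 K |
| ρ_m | 5·10³ kg·m⁻³ | iron-oxide mass density |
| μ | 1.3·10⁵ μ_B | particle moment |
| R | 5 nm | hydrodynamic radius |
| dt | 10 ps | integration step |
| cutoff | 100 nm | dipolar interaction range |

Derived: inertia I = (2/5)ρ_m V R² (uniform solid sphere — the standard
convention for a homogeneous nanoparticle), angular-momentum relaxation
I/ζ = ρ_m R²/(15η) ≈ 12 ps at R = 5 nm, Brownian time
τ_B = 3ηV/k_BT ≈ 0.25 μs.

## Integrator

dt = 10 ps is *comparable* to I/ζ, so the angular-velocity process is
marginally underdamped over one step and naive Euler–Maruyama noise is
measurably biased. The integrator is a symmetric splitting:

1. **B** half-kick: ω += (dt/2)(μ**e** × **B**)/I with torques at the
   current orientations;
2. **AO** exact free flight: per axis, the pair (ω(t+dt), ∫ω dt) is drawn
   from the exact joint Gaussian solution of the free Langevin equation
   (Ornstein–Uhlenbeck process and its integral, with the classical
   covariances c = e^{−ζdt/I}, Var ω′ = (k_BT/I)(1−c²),
   Var Δθ = (k_BT/I)γ⁻²(2γdt − 3 + 4c − c²), Cov = (k_BT/I)γ⁻¹(1−c)²);
3. **R** rigid rotation of **e** by the accumulated angle vector
   (Rodrigues formula), followed by a renormalization safety net at the
   10⁻¹² level;
4. **B** half-kick with torques at the new orientations (reused as the
   first half-kick of the next step).

Because step 2 is exact, the stationary velocity variance (equipartition
⟨Iω²⟩ = k_BT) and the free-rotor orientational diffusion are reproduced
exactly at any dt ≤ I/ζ; constructing the parameters rejects larger steps.
Rotating by the *integrated* angle rather than ω·dt matters: the latter
overestimates the rotational diffusion coefficient by ~6% at dt = 10 ps,
R = 5 nm. The small-γdt regime uses series expansions of the covariances
(the closed forms cancel catastrophically); γ = 0 degenerates to velocity
Verlet, which the deterministic-limit tests (energy conservation,
reference ODE solve) exercise. Non-commutativity of the per-step rotations
is O(|Δθ|³) with |Δθ| ~ 6·10⁻³ rad and is negligible.

Noise comes from a counter-based generator (numpy Philox) seeded per run,
drawn in chunks of shape (steps, N, 3); runs are bit-reproducible for a
fixed seed and particle count. Positions never move, so the neighbor table
and per-pair geometry (unit vectors, 1/r³) are computed once and consumed
by a compiled (numba) kernel.

Burn-in defaults to max(10 τ_B/dt, 10⁵) steps; the recording stride
defaults to ≥ 50 samples per predicted relaxation time. Both are
overridable and logged in the run diagnostics, alongside the
equipartition estimator, Knudsen number and final energy.

## FDT pipeline

The tensor correlation C_kl(t) = ⟨M_k(t)M_l(0)⟩ is estimated by the
time-averaged, mean-removed, lag-unbiased FFT estimator (Wiener–Khinchin;
optional Welch segment averaging), symmetrized in (k,l) — exact in
equilibrium by time reversal. A direct O(n²) lag sum is kept as the test
oracle. The estimator uses the ergodic time average (not an un-normalized
infinite-time convolution) because the ω = 0 term of the susceptibility
requires the equilibrium moment ⟨M_k M_l⟩.

The susceptibility

    α_kl(ω) = C_kl(0)/(Nk_BT) + (iω/Nk_BT) ∫₀^∞ C_kl(t) e^{+iωt} dt

uses the e^{+iωt} sign convention so that Im α_kk ≥ 0 (positive
dissipation); an exponential C(t) = C₀e^{−t/τ} then gives exactly the
Debye form α = βC₀/(1 − iωτ). The one-sided integral is evaluated by a
Filon-type quadrature exact for piecewise-linear C(t) at every frequency
(plain trapezoid degrades once ω·Δt ~ 1), plus an analytic
exponential-tail continuation beyond the last lag, fitted on the decayed
part of each diagonal component. The default grid is 200 log-spaced
frequencies from 10⁻²/τ̂ to min(10³/τ̂, half the sampling Nyquist rate),
with τ̂ the integral correlation time of the trace. A Kramers–Kronig
reconstruction of Re α from Im α is provided as an internal consistency
check.

Debye fits minimize least squares of A·ωτ/(1+(ωτ)²) over the log-spaced
grid (uniform weights ≈ logarithmic frequency weighting) and report the
rms residual relative to the peak; a missing interior maximum is an error,
not a silent extrapolation.

For interacting (anisotropic) systems, spectra are reported in the
principal frame of the static tensor ⟨M_kM_l⟩/(Nk_BT): the two in-plane
eigendirections sorted by susceptibility (n = strongest, p = weakest) and
the lattice normal z. Eigenvalues, not axis labels, are reported for the
ellipsoid representation because the weakly-coupled in-plane pair is
quasi-degenerate.

The additive rate law 1/τ = 1/τ_B + a·U(ρ)/ζ uses the nearest-neighbor
coupling scale U(ρ) = μ₀μ²ρ^{3/2}/4π; the single dimensionless prefactor
a absorbs the lattice sum over all neighbors and is fitted (in log-rate
space) when comparing with simulations. In the simulations it comes out
a ≈ 4 — the in-plane lattice-sum enhancement over a single
nearest-neighbor bond. The law is asymptotic in the coupling-dominated
regime (predicted τ_U ≲ τ_B/5): at weak coupling the in-plane components
actually relax *slower* than τ_B (ferromagnetic short-range correlation
enhances the static susceptibility above the Curie value before
antiferromagnetic ordering suppresses it), a collective effect an additive
rate cannot represent.

## Synthetic surrogates

`make_surrogate_trace` builds stationary Gaussian AR(1) components whose
autocorrelation is C₀e^{−t/τ} *exactly* on the sample grid — the
statistical structure the Debye law assumes — giving the downstream
pipeline a closed-form oracle independent of any dynamics. What surrogates
do not emulate: anisotropy, cross-correlations, non-Gaussian saturation
(|M| ≤ Nμ), and multi-time-scale relaxation; pipeline tests on surrogates
therefore validate the estimator chain, not the physics, which is covered
by the simulation-backed tests.

## Problem sizes and statistical design of the test suite

Statistical errors of correlation estimators from a total-magnetization
trace are governed by the run length in units of τ (cross-particle terms
dominate, so more particles do not help): the relative error is
~√(2τ/T_run). The suite therefore uses few particles and long runs:
noninteracting benchmarks run 16 independent dipoles for 800–2000 τ_B
(radius-dependent dt, always ≤ I/ζ); the density sweep uses the 10×10
lattice for 250–600 predicted relaxation times per density. With these
sizes the fitted τ at ρ = 0 scatters by ~3% (verified against matched
AR(1) surrogates), comfortably inside the 10% comparison band, and the
χ²-based Boltzmann-distribution check has > 3000 effectively independent
orientation samples. Full-scale runs (2000 relaxation times per sweep
point) remain available behind the CLI `--full-scale` flag.

## Known limitations

- Rigid-dipole assumption: no Néel channel, so results apply to
  thermally-blocked particles (large anisotropy barriers).
- Stokes rotational friction with a scalar ζ; no hydrodynamic coupling —
  the K_n warning only flags, it does not correct.
- Finite open lattices: edge particles see fewer neighbors; ordering at
  high density forms domains rather than a single antiferromagnetic
  ground state, and order parameters are correspondingly partial.
- The mass-concentration estimate depends on the chosen cell convention
  (cubic vs spherical cell per particle); both are exposed because the
  convention is genuinely ambiguous for irregular aggregates.
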