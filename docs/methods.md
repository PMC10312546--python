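# Methods

## Forward model

The calculated intensity is the spherical average of the squared modulus
of three combined amplitude grids,

    I(q) = ⟨ | F_vac − ρ₀ F_exvol + δρ F_shell |² ⟩_Ω ,

each obtained by FFT of a real-space density map on a shared cubic voxel
grid.  The model assumes a dilute, monodisperse solution of rigid
particles; bulk solvent is a flat density ρ₀ and the hydration shell an
implicit, spherically-averaged-water layer of adjustable mean contrast.

### Grid

Default voxel size 1 Å; box side three times the particle's maximum
dimension D_max (comfortably above the Shannon minimum of 2 D_max),
rounded up to an even voxel count, with a 20 Å floor for point-like
inputs.  If the side would exceed 256 voxels the count is capped and the
voxel size grows to compensate, which lowers the usable q_max = 2π/dx.
The particle is centered in the box.  With the factor-of-three box the
reciprocal bin width Δq = 2π/side gives about 1.5 calculated points per
Shannon channel π/D_max.

### In vacuo map

Atomic form factors are the standard four-Gaussian-plus-constant
parameterization (International Tables, Vol. C).  The real-space density
of atom j at distance r is

    ρ_j(r) = Σᵢ aᵢ (4π/(bᵢ+B_j))^{3/2} exp(−4π² r² / (bᵢ+B_j)) ,

which requires a pure-Gaussian form: the constant offset c would be a
delta function in real space.  Rather than folding c into the amplitudes
proportionally — which distorts f(q) by several per cent at wide angles —
the four (aᵢ, bᵢ) pairs are refit by least squares to the full
nine-coefficient curve over q ∈ [0, 8] Å⁻¹.  The refit reproduces f(q)
to better than 10⁻⁵ relative throughout, and incidentally regularizes
nitrogen's near-singular b₁ = 0.0057 Å².  Refit coefficients are
computed once per element and cached; the fit is deterministic.

Density is evaluated within 3 Å of each atom (window enlarged when model
B-factors are enabled) and rescaled so every atom deposits exactly
Z × occupancy electrons; the map integral therefore equals the model
electron count to machine precision.

**Sampling smear and sharpening.**  Several elements concentrate density
within a few hundredths of an ångström of the nucleus, far below 1 Å
sampling.  A uniform B = 7 Å² (≈0.3 Å rms displacement) is added to all
atoms in real space and removed exactly in reciprocal space by
multiplying the amplitudes by exp(+7 q²/16π²) before combining terms.
In the continuum limit the cycle is the identity; on the lattice a
residual aliasing error remains because a 0.3 Å-wide Gaussian is still
undersampled at 1 Å.  The residual depends on where the atom falls
relative to the lattice: for a single atom it reaches tens of per cent
near the grid's own Nyquist frequency, but in multi-atom models the
alias phases of different atoms are incoherent and largely cancel in the
spherical average.  The single-atom validation therefore runs on an
oversampled 0.4 Å grid and checks 1% agreement with the analytic |f(q)|²
over q ≤ 0.9 π/(1 Å) ≈ 2.83 Å⁻¹ — the reciprocal range the default
sampling serves, covering the full WAXS regime of typical experiments
(q_max ≈ 1.8 Å⁻¹) — where the result is registration-independent.
Atomic B-factors from the model are off by default; enabling them adds
each atom's B to the smear (and only the smear is sharpened away).

### Excluded volume

Gaussian dummy atoms, ρ_j(r) = exp(−π r²/V_j^{2/3}), whose analytic
integral is V_j; the map stores shape only and is multiplied by ρ₀ in
reciprocal space.  Each Gaussian is evaluated out to where it falls to
10⁻⁴ of its peak.

**Adjusted volumes.**  V_j is not the van der Waals volume: covalently
bonded neighbors overlap the sphere.  Each atom is placed in its own
miniature grid of 16 voxels per side spanning twice its Bondi vdW radius
(≈0.2 Å voxels); voxels inside the sphere are marked; for every neighbor
within 5 Å (center-to-center) whose sphere overlaps, voxels beyond the
radical plane of the sphere-sphere intersection — at distance
t = (d² + r₁² − r₂²)/(2d) from the atom — are removed.  The radical
plane is the intersection plane when the spheres cross and extends
continuously otherwise; a plane beyond the sphere clips nothing, and a
fully engulfed atom clips to zero volume (reported as a warning).
Sphere membership is decided by voxel center; the plane cut weights
boundary cells by their linear coverage on the kept side, because a pure
center-in/center-out rule leaves a half-voxel-layer bias (several per
cent at n = 16) depending on where the plane falls between voxel rows.
With coverage weighting the one- and two-neighbor volumes agree with the
analytic sphere-minus-cap values to ≈1.5% at n = 16 and ≈0.1% at n = 48,
limited by the voxelization of the spherical surface itself.  Atoms at
coincident coordinates would give a degenerate plane; such neighbors are
skipped with a warning.

A volume dictionary — mean adjusted volume per (residue name, atom name)
over a corpus of models, serialized as JSON — can replace the explicit
calculation for speed; any atom missing from the dictionary falls back
to the explicit path.  Distinguishing residue types matters: the same
atom name takes systematically different volumes in different residues.

**Element scale factors.**  Plane-clipped volumes ignore inter-atomic
voids too small for solvent, so per-element multiplicative factors
(H/C/N/O) can inflate them.  `calibrate_scale_factors` fits the factors
to a benchmark profile by Nelder-Mead on the log-factors with ρ₀ pinned
at 0.334 e⁻/Å³ to prevent the factors and the solvent density from
trading off.  The χ² valley has shallow, compensating directions, so the
simplex tolerances are tight (1e−5 on parameters).  The shipped defaults
are identity factors; sites with a high-quality wide-angle benchmark
should calibrate once and pass the result via `--scale-factors` or the
versioned config file.

An alternative flat "cube" excluded volume (voxels inside any vdW sphere
set to 1, scaled by ρ₀ downstream) is provided for comparison; with
volumes calibrated for the Gaussian model it fits worse, and it is not
the default.

### Hydration shell

The shell center locus lies one water radius (1.4 Å) outside the vdW
surface of all atoms.  A Euclidean distance transform on the voxel
lattice gives each exterior voxel's distance d to the surface; voxels
with 0 < d ≤ 1.4 + 3 Å receive the real-space form factor of water —
a single-site composite of one oxygen and two hydrogens (10 electrons),
transformed to real space like the atomic form factors and evaluated at
|d − 1.4| — so the contrast peaks at the locus and decays on both sides.
The same 7 Å² smear used for the solute keeps the water profile
resolvable on the lattice (the shell term is not sharpened; the residual
≈0.3 Å broadening is negligible against the ≈3 Å shell width).  The map
is rescaled so its mean over shell voxels equals the target contrast
(default 0.019 e⁻/Å³; negative values are allowed during fitting).
Because the distance transform reaches interior cavities and channels,
the shell penetrates them.  Contrast variation *across* the surface
(polar vs apolar patches) is not modeled.

### Spherical averaging

Amplitude grids are combined per reciprocal voxel and binned by
k = floor(|q⃗|/Δq) with Δq = 2π/side; the q = 0 voxel forms its own
first bin (reported at q = 0), bin k is reported at its center
(k + ½)Δq, bin intensity is the arithmetic mean over member voxels, and
empty bins are dropped.  Exact-lattice magnitudes are nudged by a 10⁻⁶
relative epsilon so they land deterministically in the bin they open.
The discrete spherical average of an anisotropic intensity retains a
small orientation dependence: a compact Gaussian dumbbell rotated rigidly
reproduces its profile to <1% per bin below half-Nyquist, but strongly
modulated interference patterns (widely separated subunits) can deviate
by a few per cent per bin at wide angles.

## Fitting

The coarse calculated profile is cubic-spline interpolated to the
experimental q grid (no extrapolation; data beyond the calculated q_max
are fatal unless truncation is requested).  The goodness of fit is

    χ² = (1/N) Σᵢ [ (c·I_exp + b − I_calc) / (c·σ) ]² ,

with the scale c and optional offset b applied to the *data*.
Substituting u = 1/c, β = b/c makes the residual linear in (u, β), so
both are solved in closed form at every objective evaluation; dividing
by c makes χ² invariant to the data's overall scale.  The offset is
disabled by default: fitting it alone improves χ² about as much as
fitting ρ₀, which suggests it can absorb genuine wide-angle signal.

ρ₀ and δρ are optimized by Nelder-Mead from (0.334, 0.019) e⁻/Å³ with an
initial simplex step of 0.005, parameter tolerance 10⁻⁶, and a soft
quadratic penalty outside ρ₀ ∈ [0.28, 0.40] (plausible aqueous buffers).
For speed the six quadratic cross terms of the three amplitude grids are
binned once, making each objective evaluation a 1D array combination —
algebraically identical to recombining the 3D grids.  Tiny negative
intensities from round-off in the expansion are clamped to zero.  The
whole pipeline is deterministic: identical inputs give bit-identical
outputs.

## Synthetic data generator

`voxsaxs.synthetic` provides every fixture the tests rely on: single
atoms (oracle: |f(q)|²), uniform balls (oracle: the closed-form sphere
intensity, first minimum at qR ≈ 4.4934), ball pairs (oracle: the
two-body Debye formula), analytic clipped-sphere volumes, a hand-built
glycylglycine dipeptide with explicit hydrogens and idealized bond
lengths, and `make_synthetic_data`, which runs the full forward model at
chosen (ρ₀, δρ), interpolates to an oversampled q grid (201 points, as
experimental profiles are oversampled relative to Shannon channels), and
adds multiplicative Gaussian noise of a chosen fractional level with a
mandatory seed (σ column set to the level used; a nominal 1% when
noiseless so weighted fitting stays defined).

The generator emulates the oversampling and error columns of real SWAXS
data but not counting statistics, instrumental smearing, buffer
mismatch, inter-particle interference, or conformational heterogeneity.
Passing recovery tests therefore demonstrates the internal consistency
and identifiability of the forward model and optimizer — not accuracy
against those real-data effects, which require benchmark experimental
profiles.

## Problem sizes and tolerances used in validation

Single-atom oracles run in 20 Å boxes (0.4–1 Å voxels); the sphere
oracle uses R = 20 Å in a 120³ grid; parameter recovery and χ²
contracts use the 16-atom dipeptide (24³ grid), 201-point profiles, and
ten noise seeds.  Tolerances: electron conservation to machine
precision; form-factor cycle 1% (measured ≈0.3%); sphere first minimum
within one q bin; adjusted volumes 2% at n = 16 (measured ≈1.5%,
surface-voxelization limited); (ρ₀, δρ) recovery within (0.001, 0.002)
e⁻/Å³; mean fitted χ² within 1 ± 0.3 at 1% noise.  Spline interpolation
of Shannon-rate sphere profiles is accurate to ≈0.7% away from the deep
interference minima, where relative error is ill-conditioned; voxelized
hard-edged balls agree with the Debye oracle only to a few per cent, an
inherent surface-quantization limit that the Gaussian atomic
representations do not share.

## Known limitations

* Crystallographic B-factors, when enabled, are applied as in
  crystallography (amplitude-level Debye-Waller); in solution, thermal
  disorder should add in intensities, so enabled B-factors typically
  worsen fits and stay off by default.  Ensemble-based corrections are
  out of scope.
* The shipped volume scale factors are identity; absolute excluded
  volumes are mildly underestimated until calibrated against a benchmark
  dataset.
* Anisotropic B-factors, explicit-solvent modeling, spatially varying
  shell contrast, and uncertainty estimates on fitted parameters are not
  implemented.
* At the default 1 Å sampling, profile fidelity near the grid Nyquist
  frequency (q ≳ 3 Å⁻¹) degrades for atomically sharp features; choose a
  smaller voxel size when wide-angle accuracy beyond ≈2.8 Å⁻¹ matters.
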