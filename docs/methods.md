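# Methods

This note documents the models behind `dantespace`: what is simulated, the
parameters that matter, the numerical choices, and where the models stop
being faithful to real acquisitions.

## Echo-train model (flipangle_design)

The SPACE readout is modelled with the extended phase graph (EPG)
formalism: instantaneous hard pulses, ideal CPMG phase (excitation 90°
about x, refocusing about y), and relaxation applied over each half
echo-spacing. Configuration states are stored for all orders k ∈ [−K, K]
with one order shift per half echo-spacing; the echo is the magnitude of
F₀ midway between pulses. With all refocusing angles at 180° this reduces
exactly to exp(−t/T2), which the tests assert to 10⁻⁶. Defaults follow the
7T vessel-wall protocol: echo spacing 4.6 ms, ETL 345 ms (75 echoes),
TE_equiv 165 ms (k-space centre at echo 36, 0-based index 35).

**Prescribed evolution.** The T2-weighted target is an initial
mono-exponential decay, a plateau, and a final decay. The prescription is
a fixed *shape* in time normalized to the echo-train length: time constants
of 17.5 and 29 ms and durations of 11.9 and 46.5 ms **per 100 ms of ETL**
(so 60.4 / 100.1 ms at ETL 345 ms). Reading the time constants as literal
milliseconds instead makes the plateau unattainably steep and produces a
pure-target PSF of 1.83 px — incompatible with any scheme reaching ~1.3 px
— so the normalized-shape reading is used. Explicitly passed time
constants are taken as literal ms.

**Flip-angle solver.** Angles are solved sequentially: given the EPG state
from all previous echoes, the current angle is bracketed on a 49-point grid
over (0°, 180°] and refined by bisection (tolerance 10⁻⁶ rad) so the next
echo equals `scale × target`. The echo response is *not* globally monotone
in the angle once earlier small-angle pulses have stored magnetization in
longitudinal and unrefocused configurations — stimulated-echo recall peaks
below 180° — which is why the solver brackets on a grid instead of
bisecting from 180°. When no angle reaches the target the closest match
(the response maximum, refined by ternary search) is taken. Where several
angles meet the target the smallest is chosen (it stores the most
magnetization and minimizes SAR); late in long trains this can produce
small angles even for a pure-CPMG target, because T1-regrown longitudinal
magnetization offers a low-angle path to a tiny target echo.

The absolute level of the prescription is free. A binary search finds the
largest global scale for which no echo suffers reach-up failure; for the
wall design (1500/40 ms) that scale is ~0.37 and the target is met to
better than 10⁻³ everywhere. For the 940/100 ms design, passive stimulated
echoes overshoot the steep initial decay at any scale, so the early echoes
are closest-match only (a RuntimeWarning reports the residual). The vendor
train itself is proprietary; re-deriving it with the same designer at
940/100 ms reproduces its qualitative form (high first angles, dip, rise)
but not its exact values, and this is the dominant uncertainty in the
default-scheme PSF width (measured 1.88 px here; the width varies smoothly
between ~1.5 and ~1.9 px across plausible plateau scales).

## PSF analysis (psf_analysis)

Echoes are mapped to integer k-space lines in linear ascending order with
k = 0 at the TE_equiv echo, covering the full phase-encode extent of one
train; parallel-imaging gaps are ignored (reconstruction is assumed to
restore nominal sampling, so the modulation envelope defines sharpness).
The magnitude of the oversampled discrete Fourier transform (≥16×, default
64×) is the PSF; the FWHM is read off by linear interpolation in
reconstructed-pixel units (sampled extent / number of lines). Because the
PSF is a magnitude, shifting the k-centre by whole echoes multiplies the
spectrum by a linear phase and changes nothing — the centre-placement
sensitivity is exactly zero, which the tests assert. A real-part PSF
convention would be centre-sensitive and slightly narrower for asymmetric
MTFs; magnitude is used because magnitude images are what is measured.

## DANTE preparation (dante_bloch)

Each pulse is an instantaneous rotation by the nominal flip angle about a
fixed transverse axis (no phase cycling); between pulses every isochromat
precesses by its interval phase and relaxes over τ_D (defaults: τ_D 1.6 ms,
τ_G 1.4 ms, gradients 28/20/40 mT/m, γ = 267.513×10⁶ rad s⁻¹ T⁻¹).

`phase_increment` implements the closed-form interval phase
γ**G**·**r**₀τ_G + γ(n−½)**G**·**v**τ_G². The *simulator* instead advances
position continuously between pulses: the constant term is evaluated at the
position reached after n−1 interpulse periods, giving a per-interval slope
γ**G**·**v**·τ_G·τ_D plus the within-lobe term γ**G**·**v**·τ_G²/2. The
distinction matters: the τ_G² closed form places a 20 cm/s spin at the
stated gradients within 0.3% of a 4π/3 phase-increment resonance, an
artifact of compressing the interpulse advance into the gradient duration.

**Ensemble.** The constant term winds many cycles across a voxel, so
intravoxel position reduces to a uniform phase in [0, 2π), sampled at 128
midpoints. The dynamics depend on velocity only through **G**·**v**; the
per-axis uniform dispersions (mean ± 2.5%) are therefore collapsed into
the exact distribution of **G**·**v** (numerical convolution of the axis
boxes) and sampled at 513 equal-probability quantiles. Everything is
deterministic — no Monte Carlo. Doubling both sample counts changes
|⟨M_z⟩| by less than 10⁻³ (tested); this resolution is needed because the
ensemble response has resonance features on the 2π/n scale in the phase
slope.

**Behaviour and its limits.** Static tissue approaches a steady state;
with ideal spoiling (transverse zeroed each interval, available as an
option) it equals the spoiled-GRE value (1−E1)/(1−E1·cos α) to 10⁻⁶. The
velocity response is monotone in the mm/s band (the DANTE sensitivity
regime: |⟨M_z⟩| at 150 pulses falls from ~0.87 static to ~0.07 at 1 mm/s)
but **not** globally: beyond ~1 mm/s per-pulse dephasing saturates and the
response develops a resonance structure analogous to the RF-spoiling
phase-increment curve, so e.g. 0.5 cm/s can crush slightly harder than
2 cm/s at 150 pulses. Likewise blood (20 cm/s, T1/T2 = 2290/100 ms) is
crushed faster than CSF (2 cm/s z + 0.5 cm/s transverse, 4019/311 ms) only
in the velocity-dominated transient (~50 pulses); at larger pulse counts
blood's shorter T1 recovers more longitudinal magnetization and its
quasi-steady floor lies *above* CSF's (0.086 vs 0.050 of M₀ at 7°), so a
"crosses 5% first" comparison inverts. Statements about fast-moving spins
always crushing faster hold only before T1 recovery and coherence
resonances take over.

Readout coupling is by scaling the readout's initial longitudinal
magnetization with the end-of-train ⟨M_z⟩ (no transverse carry-over,
consistent with strong spoilers between preparation and readout). B1
inhomogeneity is represented only through the user-set flip-angle range
(7–12°); diffusion, pulsatility and banding artifacts are not modelled.

## Image metrics (image_metrics)

**Line profiles.** Wall sharpness is measured as in practice: the profile
maximum is the response centre, the 5 samples centred there are fit with a
Gaussian plus baseline (least squares), FWHM = 2√(2 ln 2)·σ. The baseline
term absorbs the non-zero magnitude background. Noiseless Gaussians are
recovered to 10⁻⁶.

**Pseudo multiple replica.** Correlated noise (Cholesky factor of the coil
covariance) is repeatedly added to the acquired k-space samples; every
replica runs through the identical reconstruction; per-pixel SNR is the
true-reconstruction magnitude over the replica standard deviation, and
g = (SNR_full / SNR_accel) / √R. Two reconstructions are provided:

* `grappa` — the application pipeline (1-D acceleration, kernel 4 acquired
  ky lines × 5 readout columns, 24 ACS lines, Tikhonov 10⁻⁴,
  root-sum-of-squares combine). For g-factor work the pure acceleration
  grid is reconstructed and the ACS block is used for calibration only.
  GRAPPA kernels regularize toward the calibration signal subspace, so
  their noise amplification is not bounded by the unbiased-reconstruction
  limit and GRAPPA g-maps may legitimately dip below 1.
* `sense` — per-pixel unfolding from the known sensitivities, the unbiased
  reconstruction whose g-factor has the closed form
  g = √([(CᴴΨ⁻¹C)⁻¹]ₚₚ[CᴴΨ⁻¹C]ₚₚ). The Monte Carlo estimator agrees with
  this closed form to <5% RMS at 256 replicas, validating the machinery.

The unaccelerated reference SNR defaults to the closed form (the full
sampled reconstruction is linear, so its noise has an exact expression),
halving the Monte Carlo variance of the g estimate; a replica-based
reference is available. g-maps are meaningful where signal exists; in
signal-free background the SNR ratio is 0/0-like, which is why the scalar
G of Eq. SNR_t = S_t/(G·σ_noise) is computed from maps generated on noisy
data, as with measured scans.

**Reports.** Compartment SNR uses ROI means of magnitude images (no Rician
bias correction), σ from a corner noise ROI, CNR as SNR differences and SR
as signal ratios for wall/CSF and wall/lumen.

## Phantom generator (phantom_synth)

An annular vessel (lumen, wall, CSF ring, background) is rasterized on an
8× sub-voxel grid, giving area-weighted partial volume at every boundary —
the sub-voxel-wall regime of real vessel-wall imaging. Optional 1-D
convolution with a supplied PSF along phase encode emulates echo-train
blurring at the sub-voxel resolution before voxel averaging. Masks are
voxel-centre classifications (an exact partition); partial-volume fraction
maps are returned alongside. Coil sensitivities are smooth complex Gaussian
lobes on the FOV perimeter (default 8 coils); the noise covariance is a
seeded Hermitian positive-definite coupling around the identity.
Acquisitions are centred orthonormal FFTs, sampled on an every-R-lines plus
centred-ACS mask, with correlated noise on the acquired samples and a fully
sampled RF-free noise companion for covariance estimation. Everything is
deterministic given the seed.

The `"space"` / `"dante-space"` contrast presets set compartment values to
ρ₀ · |M_z(end of preparation)| · MTF(k=0) from the package's own
simulations. The static echo-train model cannot produce the readout's
intrinsic flow-induced black-blood effect, so the lumen value carries an
explicit flow-suppression factor (default 0.1) in both presets; only the
*relative* change between presets is meaningful. What passing end-to-end
tests show is the direction of effect — DANTE raises wall/CSF signal ratio
and contrast while lowering wall/lumen contrast — not in-vivo magnitudes,
which depend on pulsatile flow, B1 profiles and anatomy that the phantom
does not emulate.

## Known limitations

* The vendor flip-angle table is reconstructed, not known; default-scheme
  PSF widths carry a ~±0.2 px model uncertainty (see above).
* Slice (partition) encoding, partial Fourier, and 2-D/3-D PSFs are not
  modelled; the PSF is 1-D along phase encode.
* DANTE banding, diffusion during gradients, pulsatile velocity waveforms
  and B1 transmit maps are out of scope.
* GRAPPA g-maps and SENSE g-maps are different quantities by construction;
  comparisons against the closed form use the SENSE reconstruction.
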