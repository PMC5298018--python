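# dantespace

Simulation and quantification toolkit for **DANTE-prepared variable
flip-angle turbo spin echo (SPACE) vessel-wall MRI** at 7T.

Intracranial vessel-wall imaging must suppress both flowing blood and the
slowly moving CSF surrounding an artery while keeping the sub-millimetre
wall itself sharp and bright. Two sequence components control this:

* the **SPACE readout** — a long train of refocusing pulses with variable
  flip angles below 180°, whose per-echo transverse amplitude (the
  modulation transfer function, MTF) shapes the point-spread function (PSF)
  along phase encode and hence the effective wall resolution;
* the **DANTE preparation** — hundreds of rapid low-flip nonselective RF
  pulses interleaved with strong gradients; spins moving with velocity *v*
  accrue an extra phase per pulse interval

  Δφ(n) ≈ γ **G**·**r**₀ τ_G + γ (n−½) **G**·**v** τ_G²,

  which destroys their longitudinal steady state (black-blood / CSF
  crushing) while static wall tissue approaches a steady state.

The package implements, for synthetic data end to end:

| module              | contents |
|---------------------|----------|
| `flipangle_design`  | prescribed signal evolutions, extended-phase-graph (EPG) echo-train simulation, per-echo flip-angle solver with global scale search |
| `psf_analysis`      | MTF → PSF transform (linear ascending k-space order), FWHM measurement, multi-scheme reports |
| `dante_bloch`       | isochromat Bloch simulation of the DANTE train (velocity-dispersed ensembles, Mz trajectories, spin-density-weighted contrast ΔM_z = ρ_wall·M_z,wall − ρ_fluid·\|M_z,fluid\|) |
| `image_metrics`     | 5-point Gaussian line-profile fits, GRAPPA reconstruction, pseudo-multiple-replica SNR / g-factor maps, SNR_t = S_t/(G·σ_noise), CNR and signal-ratio reports |
| `phantom_synth`     | annular vessel phantoms with sub-voxel partial volume, smooth multi-coil sensitivities with correlated noise, undersampled k-space + RF-free noise companions |

## Worked example

Design the wall-optimized train (T1/T2 = 1500/40 ms at 7T, echo spacing
4.6 ms, ETL 345 ms), simulate its MTF on wall tissue and measure the PSF:

```python
from dantespace import flipangle_design as fa, psf_analysis as ps

timing = fa.SequenceTiming.protocol_7t()          # esp 4.6 ms, ETL 345 ms
target = fa.prescribed_evolution(timing)          # decay / plateau / decay
optimized = fa.design_flip_angles(target, fa.VESSEL_WALL_7T, timing)
default = fa.design_flip_angles(target, fa.VENDOR_DEFAULT, timing)

report = ps.scheme_psf_report(
    {"default": default, "optimized": optimized}, fa.VESSEL_WALL_7T, timing
)
print(report)
```

prints

```
            fwhm_px  improvement_vs_first
scheme
default    1.875058              0.000000
optimized  1.382426              0.262730
```

i.e. re-designing the flip angles for the actual wall relaxation times
sharpens the wall PSF from 1.88 px to 1.38 px — a 26% resolution
improvement, with lower overall flip angles (less SAR). The DANTE side:

```python
from dantespace import dante_bloch as db

sweep = db.dante_sweep(n_max=700)      # flips 7..12 deg, wall/CSF/blood
csf = sweep[10.0]["trajectories"]["csf"]
print(db.first_crossing(csf, 0.05))    # -> 176
```

at the protocol gradients (28/20/40 mT/m, τ_D = 1.6 ms, τ_G = 1.4 ms) a
10° train crushes flowing CSF below 5% of equilibrium within ~176 pulses,
while a 7° train needs ~489 — the reason the protocol uses 300 pulses at
10°.

A command-line interface mirrors the library
(`dantespace design|psf|dante|phantom|profile|gfactor|report`); see
`dantespace --help`.

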