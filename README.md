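# nucmix

**Signal mixing between the subthalamic nucleus and substantia nigra under
spatial smoothing.**

The subthalamic nucleus (STN, ~120 mm³) and the directly adjacent substantia
nigra (SN) are small basal-ganglia nuclei that functional MRI studies try to
resolve with voxels of ~30 mm³ and Gaussian smoothing kernels of 4–12 mm
FWHM. At that scale, the BOLD signal attributed to one nucleus is in fact a
mixture of signal from that nucleus, its neighbour, and surrounding tissue.
`nucmix` quantifies this for researchers who analyze (or review) subcortical
fMRI:

* a **smoothing-mixture simulation**: given binary STN/SN masks on a fine
  grid and a kernel FWHM, it decomposes the smoothed signal at each nucleus's
  center voxel by spatial origin;
* a **synthetic anatomy generator** that produces seeded cohorts of paired
  STN/SN masks calibrated to literature statistics (STN volume 119.88 mm³,
  STN–SN center-of-mass separation 6.4 mm left / 6.7 mm right), so the whole
  pipeline runs without downloading any atlas;
* a **coordinate meta-analysis** over a packaged table of 52 BOLD fMRI
  studies (one row per reported STN/SN activation focus), comparing reported
  MNI coordinates to reference centers of mass and summarizing the kernels
  and voxel sizes the field uses;
* **atlas I/O** for real probabilistic masks in NIfTI format (thresholding,
  conjunct two-rater masks, probability-weighted centers of mass).

## The model

Every voxel of a nucleus mask carries unit signal. Smoothing with a Gaussian
kernel of width σ = FWHM / (2√(2 ln 2)) mixes signals spatially; at an
evaluation point *p* (the mask's center voxel), the mass contributed by mask
*M* is

```
mass_M = Σ_{v ∈ M} exp( −Σ_d (v_d − p_d)² / (2 σ_d²) )
```

summed over the mask's voxel centers on a 0.5 mm grid. Dividing by the total
kernel mass over the lattice turns the masses into fractions that sum to 1
with the remainder attributed to tissue outside both nuclei. A separate
closed form gives the in-sphere mass of an isotropic 3-D Gaussian,
`P = erf(z/√2) − √(2/π)·z·exp(−z²/2)` with `z = r/σ`, used as an independent
oracle for the lattice computation.

## Worked example

```python
from nucmix import default_config, generate_cohort, simulate_cohort, summarize_curves

cohort = generate_cohort(default_config(seed=0))      # 30 subjects, both hemispheres
curves = simulate_cohort(cohort, [0.0, 4.0, 8.0])     # tidy per-subject table
summary = summarize_curves(curves)                    # mean/SD across 60 simulations
```

Composition of the smoothed signal at the **STN center voxel** (percent,
cohort mean with SD across the 60 subject-hemispheres), as printed by the
code above:

```
 fwhm_mm    source  percent  sd
     0.0        SN      0.0 0.0
     0.0       STN    100.0 0.0
     0.0 elsewhere     0.0  0.0
     4.0        SN      8.7 2.2
     4.0       STN     58.3 5.1
     4.0 elsewhere     32.9 4.4
     8.0        SN     11.3 1.5
     8.0       STN     14.4 2.1
     8.0 elsewhere     74.3 2.1
```

Reading: without smoothing the center voxel contains only its own nucleus's
signal. At a typical 8 mm kernel, only ~14% of the signal measured at the
best possible STN voxel still originates from the STN — about as much as
arrives from the neighbouring SN — and ~3/4 comes from outside both nuclei.

The literature table ships with the package:

```python
from nucmix import meta
records = meta.load_foci()                 # 52 studies, one row per focus
meta.kernel_summary(records)
# {'n_studies_total': 52, 'n_studies_reporting': 48, 'mean_fwhm_mm': 6.24,
#  'median_fwhm_mm': 6.0, 'modal_fwhm_mm': 8.0, 'n_studies_mode': 16}
```

## Command line

```bash
nucmix simulate --fwhm 0,2,4,6,8,10 --seed 1 --out curves.csv
nucmix meta --out table2.csv --summaries summaries.json
nucmix leakage --voxel-dims 3.4,4,4 --fwhm 2
nucmix atlas-com --mask STN_L.nii.gz --mask STN_R.nii.gz --out coms.yaml
nucmix run --out-dir results/ --plots        # full pipeline + manifest
```

Configuration is a YAML file mirroring the shipped
`src/nucmix/data/anatomy_defaults.yaml`; CLI flags override config keys, and
every run writes a `manifest.json` (config snapshot, seed, version, input
checksums) that makes outputs bit-reproducible.

Real probabilistic masks (e.g. the deposited 7 T basal-ganglia atlas) are
consumed through `nucmix atlas-com` / `--coms`; they are never required —
the synthetic atlas stands in for desk-scale use.

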