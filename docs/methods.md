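# Methods

## The mixture model

The simulation treats each nucleus as a binary occupancy field on a fine
voxel grid (0.5 mm isotropic by default) in MNI/RAS millimetre space, with
unit signal in every in-mask voxel. Smoothing is an isotropic (optionally
per-axis) Gaussian with σ = FWHM / (2√(2 ln 2)). For an evaluation point
*p*, the raw mass contributed by a mask is the sum of the kernel over the
mask's voxel centers; fractions are obtained by dividing by the total kernel
mass over the full voxel lattice, and the remainder is attributed to tissue
outside both nuclei. Consequences of this normalization: fractions lie in
[0, 1], sum to exactly 1, and a point deep inside a very large mask has
own-fraction 1.

The evaluation point is the **center voxel**: the grid voxel nearest the
mask's binary center of mass (nearest in-mask voxel, lowest index on ties,
if the center of mass falls outside a concave mask). This emulates a
best-case region-of-interest study in which the ROI sits on the single most
representative voxel of the nucleus.

Numerical choices:

* Kernel weights are the Gaussian **evaluated at voxel centers** (a
  sum-of-exponentials), not integrated over voxel extents; a
  voxel-integrated variant is available via `KernelSpec(integrated=True)`.
* Kernel support is truncated at 4σ per axis (configurable). Results at 4σ
  and 6σ differ by < 1e−4, which the suite asserts.
* FWHM 0 is the delta kernel: smoothing is the identity and the center
  voxel's signal originates entirely from its own nucleus. This is exact,
  not a limit.
* `smooth_field` performs the same computation as separable convolution over
  the whole grid; the two code paths agree to 1e−6 and are cross-checked in
  the tests.
* The discrete voxel-leakage bound samples the kernel at acquisition-grid
  voxel centers (e.g. 3.4×4×4 mm), normalizes the weights to sum 1, and
  reports one minus the central weight — the fraction of a voxel's smoothed
  signal that originated in *other* voxels. It is separable and exact.

## Synthetic anatomy

The generator stands in for a manually segmented ultra-high-resolution 7 T
dataset (30 subjects, both hemispheres). It is **calibrated to the
statistics the literature pins down** rather than to true nucleus shape:

| parameter | default | anchor |
|---|---|---|
| STN volume | 119.88 ± 20 mm³ | weighted literature average |
| STN–SN COM separation | 6.4 mm (L), 6.7 mm (R) | deposited 7 T atlas |
| SN volume | 450 ± 60 mm³ | several times the STN; no printed value exists |
| grid | 0.5 mm isotropic | segmentation resolution of the 7 T data |

Nuclei are rotated ellipsoids. The STN is a flat lens (semi-axis ratio
2 : 1.5 : 1) with its short axis pointing at the SN; the SN is an elongated
oblique ellipsoid (2.5 : 1 : 1.7) whose long axis is pitched 35° toward the
STN so that its near tip almost touches the STN's ventral border while its
center of mass keeps the configured separation. This obliqueness is what
reconciles two printed observations that a face-on ellipsoid cannot satisfy
simultaneously: a ~10% SN contribution at the STN center already at FWHM
4 mm (which requires SN tissue within ~2–4 mm of the STN center) and a COM
separation of 6.4 mm. The SN's geometry is fully exposed in the config — it
is a calibration, not an anatomical claim.

Per-subject variability: a shared translation per hemisphere (σ = 1 mm per
axis; registration scatter moves neighbouring nuclei together), a small
independent SN offset (σ = 0.3 mm) so the pairwise separation stays
calibrated, orientation jitter (σ = 6°), and normally drawn volumes
(clipped at ±3 SD). Randomness uses one integer seed with fixed per-subject
substreams, so enlarging the cohort never reshuffles earlier subjects.

Two-rater **conjunct masking** is emulated by a probabilistic one-voxel
erosion (p = 0.5 per subject): conjunct masks are smaller and smoother than
single-rater masks, and the exact rater disagreement process is
unrecoverable. Volume targets always refer to the *final* mask: eroded
subjects are built from an inflated ellipsoid (+0.42 mm per semi-axis) and a
short multiplicative fixed-point loop absorbs the residual discretization
error, keeping every realized volume within 5% of its per-subject target.

Disjointness: jitter can make the ellipsoids interpenetrate. Small overlaps
(≤ 5% of SN voxels) are resolved by assigning the contested voxels to the
STN — the way raters resolve a shared boundary — which leaves the separation
statistics unbiased; an earlier push-apart-only rule inflated the mean
separation by ~0.6 mm and starved the near-contact region. Gross overlaps
still push the SN outward along the separation axis in 0.25 mm steps (at
most 10) before erroring with the subject's id.

The probabilistic atlas is the per-voxel fraction of subjects whose mask
contains the voxel — identical to brute-force occupancy counting, which the
tests assert exactly.

### What the generator does and does not emulate

It reproduces cohort-level volume, separation and overlap statistics, and
the resulting mixture percentages. It does **not** model true STN/SN shape
(no lens asymmetry beyond ellipsoids, no SN pars compacta/reticulata split),
registration error, susceptibility distortion, or vascular/physiological
noise. Passing tests therefore show that the *mixture arithmetic* behaves as
published under calibrated geometry — not that any particular empirical
dataset would yield identical numbers.

## Simulation study conditions

The default run is 30 subjects × 2 hemispheres = 60 simulations on the
0.5 mm grid, evaluating both nuclei's center voxels at the requested kernel
sizes; the shipped defaults take seconds on one CPU. The cohort means at
FWHM 4 mm are ≈ 33% from outside both nuclei / 9% from SN / 58% from the STN
itself, and at FWHM 8 mm ≈ 74% / 11% / 14% — reproducing the published
pattern that at commonly used kernel sizes the neighbour's contribution
rivals the nucleus's own.

## Coordinate meta-analysis

The packaged table transcribes the 52-study literature overview: one row per
reported activation focus (113 coordinate rows; 9 further rows record
studies whose foci were not specified), with structure label (STN, SN,
SN/VTA, SN/STN), MNI coordinates, kernel FWHM, voxel volume, field strength
and flags. Coordinates originally reported in Talairach space were already
converted in the source table; the pooled Lancaster (2007) tal2icbm affine
ships in `meta.TAL2MNI` for converting further Talairach-space foci.

Decisions the source does not spell out, fixed here:

* **Hemisphere rule**: x < 0 → left, x ≥ 0 → right (the single midline
  SN/VTA focus at (0, −14, −12) lands in the right-hemisphere group, which
  is the assignment consistent with the published group sizes).
* **Per-study aggregation** for kernel and voxel summaries: average within
  study, excluding unspecified values; the modal kernel is counted over
  studies reporting *any* kernel of that size.
* **SDs** are sample SDs (n − 1); a single-focus group reports no SD.
* **Reference mapping**: STN foci are compared to the STN center of mass;
  SN, SN/VTA and SN/STN foci to the SN center of mass. Probability-weighted
  COMs are the default; a threshold-then-binarize mode exists because the
  published choice is unknown.

Reproduced summaries: median kernel 6 mm, mean 6.24 mm, 8 mm modal kernel
used by 16 of 52 studies; mean voxel volume 33.97 mm³, range 3.38–103.82
mm³. Two published numbers do not reconcile with the published study table
itself and are documented rather than matched: the count of studies
reporting voxel resolution (the table yields 48, the text says 47), and the
right-hemisphere deviation-group sizes (the table yields SN 16 / SN/VTA 21 /
STN 26 foci vs printed 18 / 17 / 17; the left hemisphere matches exactly).
Absolute deviation distances (e.g. mean left-STN distance 5.2 mm) depend on
the real deposited atlas masks; supplying their COMs via `--coms`
reproduces that computation, but no atlas files are bundled.

## Known limitations

* Ellipsoid anatomy cannot reproduce per-axis deviation statistics of real
  masks; only volume/separation-level statistics are calibrated.
* The erosion stand-in for conjunct rating is a coarse model of rater
  disagreement.
* The mixture assumes equal unit signal strength in both nuclei; relative
  differences in signal amplitude rescale the SN/STN fractions
  proportionally (the published conclusion is robust to this, and so is the
  simulation's).
* The Pearson coordinate-vs-kernel correlations treat foci as independent,
  as in the source analysis, although foci within a study are not.
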