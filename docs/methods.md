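# Methods

This note documents the models, conventions and numerical choices behind
ciliapol, and what the synthetic-data validation does and does not show.

## Coordinate and angle conventions

Images use the raster convention: origin top-left, x to the right, y
downwards, units of pixels; `pixel_size` (µm/px) calibrates lengths and
areas.  All reported angles follow the mathematical convention —
counter-clockwise from +x — obtained by flipping the y axis:
`angle = atan2(−dy, dx) mod 360°`.  Files always carry degrees;
trigonometry is done in radians internally.

Two periodicities are supported.  Directed angles (basal-body vectors,
central-pair directions) live on the 360° circle; undirected axes use
the 180° convention and are angle-doubled before any circular averaging
and halved after (the standard treatment of axial data).  Minimal
wrapped differences lie in (−period/2, period/2], with the boundary
mapped to +period/2.

## Translational polarity

The "cell centre" is the area-weighted polygon centroid (shoelace
formula).  The measurement itself does not prescribe a centre
definition; the area-weighted centroid was chosen because it is
parameter-free and reproducible.  Polygons must be simple; an O(n²)
edge-crossing check rejects self-intersecting outlines, and polygons
with numerically zero area (< 1e-12 px²) are rejected as degenerate.

Per-cell vectors run from the cell centre to the basal-body patch
centroid (accepted as a precomputed point, however the patch was
segmented).  Vectors shorter than `epsilon` = 0.1 µm (configurable) are
flagged degenerate and excluded from direction statistics — at typical
calibrations this is below one pixel, so a basal-body patch sitting on
the cell centre is not assigned a spurious direction.

Deviations are absolute wrapped differences from a reference direction,
in [0°, 180°].  The default reference is the per-image circular mean of
the non-degenerate vectors; a fixed external angle can be supplied
instead (used by the validation suite, where the generating mean is
known).  The headline statistic is the fraction of deviations ≤ 45°;
the bound is configurable.  For perfectly uniform directions this
fraction tends to 45/180 = 0.25, which the test suite verifies against
the numerically integrated von Mises probability P(|Δ| ≤ 45°) across
concentrations.  Histograms default to 24 bins of 15° over the signed
deviation range [−180°, 180°).  A summary computed from fewer than 30
usable cells (configurable) carries a warning, reflecting the usual
reporting convention for this measurement.

## Rotational polarity

Each image's cilia are summarised by their circular mean angle, and each
cilium contributes its absolute wrapped deviation from that mean.  The
circular (not arithmetic) mean was chosen because the angles live on a
circle and the arithmetic mean is not rotation-equivariant; this choice
matters only for dispersed images.  Deviations are pooled across images;
the grand mean ± s.e.m. is computed across pooled cilia (per-image mean
deviations are also reported for per-image-first aggregation).
Directional 360° periodicity is the default — central-pair measurements
carry a directionality — with the axial 180° convention selectable.
Histograms default to 18 bins of 10° over [0°, 180°].  Warnings are
attached below 100 pooled cilia or 10 images (both configurable).

A finite-sample property worth knowing: because deviations are taken
against the *sample* mean, their expectation is slightly below the
population value E|θ − μ|; for von Mises data the shrinkage is roughly
√(1 − 1/n) per image, i.e. ~0.5% at 100 cilia per image but ~4% at 12.
The validation suite uses 50–2000 cilia per image so this bias is
negligible relative to its tolerances; analyses of small images should
prefer many images over tight per-image means.

## Circular-statistics kernel

The circular mean and resultant length R come from the unit-vector sum;
means are undefined (NaN) when R < 1e-9, as for balanced or uniform
samples.  von Mises maximum likelihood takes μ as the circular mean and
solves I₁(κ)/I₀(κ) = R by bracketed root finding with exponentially
scaled Bessel functions; κ is capped at 1e6 (and flagged) when R is
numerically 1, and set to 0 for near-uniform samples.

The Watson two-sample U² statistic is computed on the combined ordered
sample: with d_k the difference of the two empirical CDFs after the k-th
point, U² = (n₁n₂/N²)·Σ(d_k − d̄)².  Tied observations share the mean d
of their tie group (mid-ranks); the tie fraction is reported.  The null
distribution is obtained by random relabelling permutations (default
9999) with an explicit seed, and p = (1 + #{U²_perm ≥ U²_obs})/(1 + B),
which can never be exactly zero.  A permutation null was preferred over
asymptotic critical-value tables because it is exact under
exchangeability at any sample size and handles ties naturally; the
asymptotic survival function 2·Σ(−1)^(m−1)·exp(−2m²π²U²) is available as
a secondary output.  Subtracting d̄ makes the statistic exactly
invariant under common rotation of both samples (the sequence of d
values is only cyclically shifted and offset), and it is symmetric under
sample exchange; both invariances are tested, as are the test's size and
p-value uniformity under the null.  Samples need at least 4 angles each
and a common periodicity; axial samples are angle-doubled first.

## Beat kinetics

Kymographs sample each frame along a line ROI with linear interpolation
(nearest-pixel selectable), averaged over a 3-pixel band perpendicular
to the line to reduce noise; the beat trace is the spatial mean of the
kymograph.  Peak counting uses prominence ≥ 20% of the trace range and a
minimum separation of 0.3/f_max seconds (f_max defaults to Nyquist);
frequency is n_peaks/duration.  The independent spectral estimate
mean-detrends the trace (no windowing by default), takes the dominant
non-zero rFFT bin and refines it by parabolic interpolation of the
log-magnitudes of the three surrounding bins, so resolution is not
limited to fps/T.  A flat trace yields 0 Hz (peaks) and NaN (spectral)
with a `low_snr` flag; the two estimates disagreeing by more than
0.5 Hz sets a `disagreement` flag.  Both estimators are invariant to
affine intensity rescaling and to resampling at a higher frame rate.
Recording summaries aggregate hierarchically — ROI → image → animal —
with the s.e.m. across image means, matching how such recordings are
reported (3–5 ROIs per area, ~5 images per animal).

Whether a "beat" is a full cycle or a half-stroke depends on the imaging
geometry; the peak definition is configurable and the peak count is
returned alongside the frequency so the choice is auditable.

## Signature similarity

Attribute vectors default to log2 fold change against a homeostatic
baseline; the scale is carried as metadata so mixed conventions are
detectable.  Gene matching is by case-insensitive symbol, and genes
missing in any population are dropped (intersection) rather than
zero-filled, because zero-filling biases |cos θ| toward 0; the dropped
count is logged.  The distance and correlation accumulations run
sequentially over the gene axis so results are bit-reproducible and
exactly match a naive-loop reference, which the tests assert.
Populations with all-zero aligned vectors have no direction and are
excluded with a warning.  Matrix ordering uses average-linkage
agglomerative clustering on the Euclidean distance matrix (other
linkages selectable); no standardisation of attribute vectors is applied
by default, with a config switch left to the caller since published
signature tables differ in convention.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the estimators are
sensitive to, not the optics of microscopy:

* **Apical maps** are perturbed rectangular grids of convex
  quadrilaterals — cell *shapes* are unrealistic, but the analysis only
  consumes centroids and areas, and the full grid's areas sum exactly to
  the bounding rectangle (a conservation law the tests check).  Interior
  vertices are jittered uniformly; the jitter half-width is
  √(3/2)·CV·side (capped at 0.25·side to keep quads simple), which
  realises an approximate target area CV.  Basal bodies are displaced by
  `displacement_frac`·√(area/π) — the radius definition is
  shape-independent — along von Mises angles recorded per cell.
* **Orientation fields** draw per-image von Mises angles; there is no
  spatial correlation between neighbouring cilia.
* **Beat recordings** are a flat background plus a 3-pixel band whose
  intensity follows offset + A·sin(2πft), with i.i.d. Gaussian noise;
  waveform asymmetry, drift and resonance-scanner line jitter are not
  modelled.  Frequencies at or above Nyquist are rejected at generation.
* **Profile sets** place a common `effect` on disjoint signature-gene
  blocks plus i.i.d. Gaussian noise; real signatures share partially
  overlapping gene programs rather than disjoint blocks.

Consequently, passing tests demonstrate estimator correctness and
calibration under the declared noise models — not robustness to
segmentation errors, photobleaching, non-sinusoidal waveforms or
cross-study batch effects.

All generators take an explicit seed, derive per-cell/per-image
sub-streams deterministically from it, and are bit-for-bit reproducible;
the drawn ground truth (angles, frequency, ROI, block pairs) is stored
alongside the data.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 2000 null replicates
(n = 50 + 50, 199 permutations each) for the Watson U² size and
uniformity checks; 20 fields of 20 × 50 cilia for rotational recovery at
the concentration whose expected absolute deviation is 10° (κ ≈ 21.3,
found by inverting the von Mises integral); 20 maps of 200 cells per
concentration for the translational closed form; 5 frequencies × 20
recordings (4 s at 60 fps, amplitude-to-noise 3) for beat recovery; and
100 seeds of the 6-population/3-block design (500 genes, effect/noise
= 5) for clustering fidelity.  These sizes put Monte-Carlo noise
comfortably inside each check's tolerance while keeping the whole suite
fast.

## Known limitations

* No segmentation: analyses start from outlines, centroids, angle lists
  and ROIs produced elsewhere.
* The per-image-mean reference makes translational and rotational
  deviation statistics slightly optimistic for very small images (see
  above); no small-sample correction is applied.
* The Watson U² permutation p-value has resolution 1/(B + 1).
* Cluster order depends on the linkage choice for populations at nearly
  equal distances; ties are resolved by scipy's deterministic merge
  order.
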