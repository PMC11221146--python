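# ciliapol

Quantitative analysis of planar cell polarity (PCP), ciliary beat
frequency and transcriptomic signature similarity for multiciliated
ependymal epithelia.

Multiciliated ependymal cells line the brain ventricles and aqueduct and
propel cerebrospinal fluid with coordinated ciliary beating.  Their
maturation is read out through a small set of quantitative measurements
that this package implements as a tested, reusable library with a thin
CLI — for developmental biologists and microscopists comparing genotypes
(e.g. wild-type vs knockout) or developmental stages:

* **Translational polarity** — the per-cell displacement of the ciliary
  basal-body patch from the apical-surface centre.  For each cell with
  outline polygon and basal-body centroid, a vector is drawn from the
  area-weighted polygon centroid to the basal-body centroid; its angle
  (counter-clockwise from +x after flipping the image y axis) is compared
  with the per-image circular mean, and the share of cells within 45° of
  the mean summarises tissue-level coordination.  Apical areas
  (shoelace area × pixel-size²) are reported alongside.
* **Rotational polarity** — how uniformly individual cilia point.  Each
  cilium's central microtubule-pair angle θᵢ is compared with its
  image's circular mean θ̄; deviations |θᵢ − θ̄| (wrapped into
  [0°, 180°]) are pooled into a grand mean ± s.e.m. and a histogram.
* **Ciliary beat frequency** — from a time-lapse stack and a line ROI a
  kymograph (space × time) is extracted; the beat trace's frequency is
  estimated by prominent-peak counting (f = n_peaks/duration) and
  independently by the dominant Fourier component, with a quality flag
  when the two disagree by more than 0.5 Hz.
* **Signature similarity** — populations (e.g. microglial subtypes such
  as CD11c⁺, PAM, DAM) are attribute vectors v = (v₁, …, vₙ) of
  differential-expression levels over n shared genes, compared by
  Euclidean distance
  d_ij = √Σₖ(vₖⁱ − vₖʲ)² and absolute-cosine correlation
  C_ij = |cos θ| = |vⁱ·vʲ| / (‖vⁱ‖‖vʲ‖) ∈ [0, 1]
  (0 = orthogonal/independent, 1 = linearly dependent/equivalent), with
  average-linkage clustering ordering the matrices.

The circular-statistics kernel provides the **Watson two-sample U²
homogeneity test** with a random-relabelling permutation null (mid-rank
tie handling; p = (1 + #{U²ₚₑᵣₘ ≥ U²ₒᵦₛ})/(1 + B)), plus von Mises
fitting and the von Mises integrals used for closed-form checks.

A first-class **synthetic-data generator** produces every input the
pipeline consumes — perturbed-grid apical maps with von Mises basal-body
displacements, von Mises orientation fields, sinusoidal beat recordings
at 60 frames/s with Gaussian noise, and block-structured expression
profiles — with the drawn ground truth recorded, so every estimator is
validated by closing the simulate→estimate loop.

## Worked example

```bash
$ ciliapol simulate apical --n-cells 60 --kappa 4 --seed 7 --out wt
wrote wt/cell_map.csv (60 cells)
$ ciliapol translational --map wt/cell_map.csv --out wt
n=60 cells, 81.7% within 45 deg of the mean; mean apical area 60.08 +/- 1.28 um^2
```

60 synthetic cells were generated with basal-body displacement angles
drawn from von Mises(μ=0°, κ=4).  The analysis recovers a polarised
tissue: 81.7% of per-cell vectors lie within 45° of the image mean
(the closed-form von Mises expectation at κ=4 is 85.8%, within the
Monte-Carlo noise of 60 cells), and the mean apical area matches the
generator's 60 µm² target.

```bash
$ ciliapol simulate beat --freq 9 --noise-sd 20 --duration 2 --seed 7 --out rec
wrote rec/recording.tif (120 frames @ 60.0 fps)
$ ciliapol beat --stack rec/recording.tif --out rec
roi0: 9.00 Hz (peaks) / 8.96 Hz (spectral)
```

Both estimators recover the true 9 Hz beat from a noisy recording and
agree within tolerance, so no quality flag is raised.

```bash
$ ciliapol simulate profiles --seed 7 --out prof
wrote prof/profiles.csv (5 populations)
$ ciliapol similarity --profiles prof/profiles.csv --out prof
5 populations on 500 genes; cluster order: DAM1 DAM2 PAM query CD11c
```

The designed block structure (query/CD11c/PAM share a signature block;
DAM1/DAM2 share another) is recovered: block-mates are adjacent in the
clustering order.

`ciliapol run --seed N --out DIR` executes the full simulate-and-analyse
pipeline (two conditions, Watson U² comparison between them) and writes
tables, figures and a `report.json`; `ciliapol watson --a A.csv --b B.csv
--perms 9999 --seed N` compares two angle tables directly.

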