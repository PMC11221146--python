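"""Rotational planar-cell-polarity quantification.

Rotational polarity measures how uniformly individual cilia point: in
axoneme cross-sections the axis of the central microtubule pair defines
each cilium's direction.  Per image, every cilium's deviation is taken
against the circular mean angle of that image's cilia; deviations from
many images are pooled into a grand mean +/- s.e.m. and a histogram.

Angles default to the directional (360-degree) periodicity because the
central pair carries a directionality; the axial 180-degree convention
is selectable for undirected measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circular import OrientationSample, circular_mean_resultant, wrap_difference
from .errors import InvalidParameterError

__all__ = [
    "RotationalSummary",
    "per_cilium_deviation",
    "summarize_rotational",
]

#: default histogram: 18 bins of 10 degrees over [0, 180]
DEFAULT_N_BINS = 18

#: minimum pooled cilia expected for a well-powered summary
DEFAULT_MIN_CILIA = 100
DEFAULT_MIN_IMAGES = 10


@dataclass
class RotationalSummary:
    per_image_mean_dev_deg: list[float]
    grand_mean_dev_deg: float
    sem_dev_deg: float
    histogram_edges_deg: np.ndarray
    histogram_counts: np.ndarray
    n_cilia: int
    n_images: int
    warnings: list[str] = field(default_factory=list)


def per_cilium_deviation(sample: OrientationSample) -> np.ndarray:
    """Absolute deviation of each cilium from its image's circular mean.

    Deviations are wrapped into ``[0, period/2]`` under the sample's
    periodicity.  Requires at least two angles — a single cilium has no
    within-image reference.
    """
    if sample.n < 2:
        raise InvalidParameterError(
            f"image {sample.label!r}: deviation analysis needs >= 2 angles"
        )
    mean, _ = circular_mean_resultant(sample)
    if math.isnan(mean):
        mean = 0.0  # perfectly balanced image: any reference gives the same spread
    return np.abs(np.atleast_1d(wrap_difference(sample.angles_deg, mean, sample.periodicity)))


def summarize_rotational(
    samples: list[OrientationSample],
    n_bins: int = DEFAULT_N_BINS,
    min_cilia: int = DEFAULT_MIN_CILIA,
    min_images: int = DEFAULT_MIN_IMAGES,
) -> RotationalSummary:
    """Pool per-cilium deviations across images.

    The grand mean and s.e.m. are computed across all pooled cilia (the
    reporting convention for this measurement); per-image mean deviations
    are also returned for per-image-first aggregation by the caller.
    """
    if not samples:
        raise InvalidParameterError("no orientation samples given")
    periods = {s.periodicity for s in samples}
    if len(periods) > 1:
        raise InvalidParameterError("all samples must share a periodicity")
    half_period = samples[0].period_deg / 2.0

    all_dev: list[np.ndarray] = []
    per_image_means: list[float] = []
    for s in samples:
        dev = per_cilium_deviation(s)
        all_dev.append(dev)
        per_image_means.append(float(np.mean(dev)))
    pooled = np.concatenate(all_dev)

    grand_mean = float(np.mean(pooled))
    sem = float(np.std(pooled, ddof=1) / math.sqrt(pooled.size)) if pooled.size > 1 else 0.0
    edges = np.linspace(0.0, half_period, n_bins + 1)
    counts, _ = np.histogram(pooled, bins=edges)

    warnings: list[str] = []
    if pooled.size < min_cilia:
        warnings.append(
            f"only {pooled.size} cilia pooled; fewer than the configured minimum of {min_cilia}"
        )
    if len(samples) < min_images:
        warnings.append(
            f"only {len(samples)} images; fewer than the configured minimum of {min_images}"
        )

    return RotationalSummary(
        per_image_mean_dev_deg=per_image_means,
        grand_mean_dev_deg=grand_mean,
        sem_dev_deg=sem,
        histogram_edges_deg=edges,
        histogram_counts=counts,
        n_cilia=int(pooled.size),
        n_images=len(samples),
        warnings=warnings,
    )


def plot_deviation_histogram(summary: RotationalSummary, path) -> None:
    """Save a bar histogram of pooled per-cilium deviations."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = summary.histogram_edges_deg
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(edges[:-1], summary.histogram_counts, width=np.diff(edges),
           align="edge", color="#b03535", edgecolor="white")
    ax.set_xlabel("deviation from image mean (deg)")
    ax.set_ylabel("cilia")
    ax.set_title(
        f"grand mean {summary.grand_mean_dev_deg:.2f} deg "
        f"+/- {summary.sem_dev_deg:.2f} (n={summary.n_cilia})"
    )
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
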