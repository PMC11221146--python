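"""Circular-statistics kernel.

Angles cross the public API in **degrees**; all trigonometry is done in
radians internally.  Two periodicities are supported:

``directional_360``
    directed angles on the full circle (e.g. basal-body displacement
    vectors, central-pair arrow directions); period 360 degrees.
``axial_180``
    undirected axes (orientation without a head); period 180 degrees.
    Axial samples are angle-doubled before averaging and halved after,
    the standard device for axial data.

The module provides the circular mean and resultant length, minimal
wrapped differences, maximum-likelihood von Mises fitting, the Watson
two-sample U-squared homogeneity test with a permutation null, and the
small von Mises integrals (expected absolute deviation, probability of a
deviation within a bound) used by the polarity modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, special

from .errors import InvalidParameterError

__all__ = [
    "AngularSample",
    "WatsonResult",
    "VonMisesFit",
    "circular_mean_resultant",
    "wrap_difference",
    "watson_u2",
    "vonmises_fit",
    "vonmises_abs_deviation_expectation",
    "kappa_for_mean_abs_deviation",
    "vonmises_prob_within",
]

PERIODS_DEG = {"directional_360": 360.0, "axial_180": 180.0}

#: resultant lengths below this leave the mean direction undefined
RESULTANT_TOL = 1e-9

#: kappa values above this cap are reported as "effectively point mass"
KAPPA_CAP = 1e6


def _check_periodicity(periodicity: str) -> float:
    try:
        return PERIODS_DEG[periodicity]
    except KeyError:
        raise InvalidParameterError(
            f"unknown periodicity {periodicity!r}; expected one of {sorted(PERIODS_DEG)}"
        ) from None


@dataclass
class AngularSample:
    """A list of angles with explicit periodicity.

    Angles are wrapped into ``[0, period)`` on construction.  ``label``
    doubles as the image identifier for per-image orientation samples.
    """

    angles_deg: np.ndarray
    periodicity: str = "directional_360"
    label: str = ""

    def __post_init__(self) -> None:
        period = _check_periodicity(self.periodicity)
        angles = np.asarray(self.angles_deg, dtype=float)
        if angles.ndim != 1 or angles.size < 1:
            raise InvalidParameterError("angles must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(angles)):
            raise InvalidParameterError("angles must be finite")
        self.angles_deg = np.mod(angles, period)

    @property
    def period_deg(self) -> float:
        return PERIODS_DEG[self.periodicity]

    @property
    def n(self) -> int:
        return int(self.angles_deg.size)

    def rotated(self, offset_deg: float) -> "AngularSample":
        """Return a copy with ``offset_deg`` added to every angle."""
        return AngularSample(self.angles_deg + offset_deg, self.periodicity, self.label)


# Orientation samples (one TEM image's central-pair angles) are plain
# angular samples whose label carries the image id.
OrientationSample = AngularSample


def circular_mean_resultant(sample: AngularSample) -> tuple[float, float]:
    """Circular mean direction and mean resultant length.

    Axial samples are angle-doubled before averaging and the mean is
    halved afterwards.  Returns ``(mean_deg, R)`` with ``mean_deg`` in
    ``[0, period)``; when ``R`` is below :data:`RESULTANT_TOL` (e.g. for
    perfectly balanced or uniform data) the mean direction is undefined
    and NaN is returned for it.
    """
    period = sample.period_deg
    scale = 360.0 / period  # 1 for directional, 2 for axial (angle doubling)
    theta = np.deg2rad(sample.angles_deg * scale)
    c = float(np.mean(np.cos(theta)))
    s = float(np.mean(np.sin(theta)))
    r = math.hypot(c, s)
    if r < RESULTANT_TOL:
        return float("nan"), r
    mean = math.degrees(math.atan2(s, c)) / scale
    mean = float(np.mod(mean, period))
    if mean >= period:  # float wrap edge: mod can round up to the period itself
        mean = 0.0
    return mean, r


def wrap_difference(a_deg, b_deg, periodicity: str = "directional_360"):
    """Minimal signed angular difference ``a - b`` in ``(-period/2, period/2]``.

    Vectorised over array inputs.
    """
    period = _check_periodicity(periodicity)
    d = np.mod(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float), period)
    d = np.where(d > period / 2.0, d - period, d)
    if np.ndim(d) == 0:
        return float(d)
    return d


# ---------------------------------------------------------------------------
# Watson two-sample U^2 test
# ---------------------------------------------------------------------------


@dataclass
class WatsonResult:
    """Result of the Watson two-sample U^2 homogeneity test."""

    u2: float
    p_permutation: float
    n1: int
    n2: int
    n_permutations: int
    seed: int
    tie_fraction: float = 0.0
    p_asymptotic: float | None = None

    def __post_init__(self) -> None:
        assert self.u2 >= 0.0
        assert 0.0 < self.p_permutation <= 1.0


def _u2_from_membership(z: np.ndarray, n1: int, n2: int,
                        group_starts: np.ndarray | None,
                        group_counts: np.ndarray | None) -> np.ndarray:
    """U^2 for one or many 0/1 membership rows over the combined sorted sample.

    ``z[..., k]`` is 1 when the k-th smallest combined observation belongs to
    sample 1.  ``d_k`` is the running difference of the two empirical CDFs;
    with ties, ``d`` is averaged within each tie group (mid-rank handling).
    """
    n = n1 + n2
    d = np.cumsum(z, axis=-1) / n1 - np.cumsum(1.0 - z, axis=-1) / n2
    if group_starts is not None:
        sums = np.add.reduceat(d, group_starts, axis=-1)
        d = np.repeat(sums / group_counts, group_counts, axis=-1)
    dbar = d.mean(axis=-1, keepdims=True)
    return (n1 * n2) / (n * n) * np.sum((d - dbar) ** 2, axis=-1)


def _u2_asymptotic_sf(u2: float, terms: int = 200) -> float:
    """Asymptotic survival function of U^2: 2 * sum (-1)^(m-1) exp(-2 m^2 pi^2 u2)."""
    m = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (m - 1) * np.exp(-2.0 * m**2 * np.pi**2 * u2))
    return float(min(max(p, 0.0), 1.0))


def watson_u2(
    sample1: AngularSample,
    sample2: AngularSample,
    n_permutations: int = 9999,
    seed: int = 0,
    asymptotic: bool = False,
) -> WatsonResult:
    """Watson two-sample U^2 test with a random-relabelling permutation null.

    The statistic is computed on the combined ordered sample:
    ``U^2 = (n1*n2/N^2) * sum_k (d_k - dbar)^2`` where ``d_k`` is the
    difference of the two empirical CDFs after the k-th combined point,
    with tied points sharing the mean ``d`` of their tie group
    (mid-ranks).  The p-value is ``(1 + #{U2_perm >= U2_obs}) /
    (1 + n_permutations)`` so it can never be exactly zero.

    Both samples must share a periodicity and have at least 4 angles.
    """
    if sample1.periodicity != sample2.periodicity:
        raise InvalidParameterError("samples must share a periodicity")
    n1, n2 = sample1.n, sample2.n
    if n1 < 4 or n2 < 4:
        raise InvalidParameterError("Watson U2 requires at least 4 angles per sample")
    if n_permutations < 1:
        raise InvalidParameterError("n_permutations must be >= 1")

    values = np.concatenate([sample1.angles_deg, sample2.angles_deg])
    labels = np.concatenate([np.ones(n1), np.zeros(n2)])
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    z_obs = labels[order]

    # contiguous tie groups in the sorted combined sample
    new_group = np.empty(n1 + n2, dtype=bool)
    new_group[0] = True
    new_group[1:] = np.diff(sorted_vals) > 0
    group_starts: np.ndarray | None = np.flatnonzero(new_group)
    group_counts: np.ndarray | None = np.diff(
        np.append(group_starts, n1 + n2)
    )
    tie_fraction = float(1.0 - group_starts.size / (n1 + n2))
    if group_starts.size == n1 + n2:  # no ties: skip the reduceat pass
        group_starts = group_counts = None

    u2_obs = float(_u2_from_membership(z_obs, n1, n2, group_starts, group_counts))

    rng = np.random.default_rng(seed)
    z_perm = rng.permuted(np.tile(z_obs, (n_permutations, 1)), axis=1)
    u2_perm = _u2_from_membership(z_perm, n1, n2, group_starts, group_counts)
    p = (1.0 + int(np.count_nonzero(u2_perm >= u2_obs))) / (1.0 + n_permutations)

    return WatsonResult(
        u2=u2_obs,
        p_permutation=p,
        n1=n1,
        n2=n2,
        n_permutations=n_permutations,
        seed=seed,
        tie_fraction=tie_fraction,
        p_asymptotic=_u2_asymptotic_sf(u2_obs) if asymptotic else None,
    )


# ---------------------------------------------------------------------------
# von Mises fitting and integrals
# ---------------------------------------------------------------------------


@dataclass
class VonMisesFit:
    mu_deg: float
    kappa: float
    r: float
    capped: bool = False


def _bessel_ratio(kappa: float) -> float:
    """A(kappa) = I1(kappa)/I0(kappa), computed with scaled Bessels for stability."""
    return float(special.i1e(kappa) / special.i0e(kappa))


def vonmises_fit(sample: AngularSample, kappa_cap: float = KAPPA_CAP) -> VonMisesFit:
    """Maximum-likelihood von Mises fit.

    ``mu`` is the circular mean; ``kappa`` solves ``I1(k)/I0(k) = R`` by
    bracketed root finding.  Samples so concentrated that the implied
    kappa exceeds ``kappa_cap`` are capped and flagged; near-uniform
    samples yield ``kappa = 0``.  Requires n >= 10 for a meaningful fit.
    """
    if sample.n < 10:
        raise InvalidParameterError("von Mises fit requires at least 10 angles")
    mu, r = circular_mean_resultant(sample)
    if r < RESULTANT_TOL:
        return VonMisesFit(mu_deg=float("nan"), kappa=0.0, r=r)
    if r >= _bessel_ratio(kappa_cap):
        return VonMisesFit(mu_deg=mu, kappa=kappa_cap, r=r, capped=True)
    kappa = optimize.brentq(lambda k: _bessel_ratio(k) - r, 1e-12, kappa_cap)
    return VonMisesFit(mu_deg=mu, kappa=float(kappa), r=r)


def _vm_pdf(theta: np.ndarray, kappa: float) -> np.ndarray:
    """von Mises density at mean 0, written with exponentially scaled I0."""
    return np.exp(kappa * (np.cos(theta) - 1.0)) / (2.0 * np.pi * special.i0e(kappa))


def vonmises_abs_deviation_expectation(kappa: float) -> float:
    """E|theta| in degrees for theta ~ von Mises(0, kappa) on (-180, 180]."""
    if kappa < 0:
        raise InvalidParameterError("kappa must be >= 0")
    if kappa == 0.0:
        return 90.0
    val, _ = integrate.quad(lambda t: t * _vm_pdf(t, kappa), 0.0, np.pi, limit=200)
    return math.degrees(2.0 * val)


def kappa_for_mean_abs_deviation(target_deg: float) -> float:
    """Invert :func:`vonmises_abs_deviation_expectation` numerically.

    Finds the concentration at which the expected absolute deviation from
    the mean direction equals ``target_deg`` (must lie in (0, 90)).
    """
    if not 0.0 < target_deg < 90.0:
        raise InvalidParameterError("target mean absolute deviation must be in (0, 90) degrees")
    return float(
        optimize.brentq(
            lambda k: vonmises_abs_deviation_expectation(k) - target_deg, 1e-6, 1e6
        )
    )


def vonmises_prob_within(kappa: float, bound_deg: float) -> float:
    """P(|theta| <= bound) for theta ~ von Mises(0, kappa), by numeric integration."""
    if kappa < 0:
        raise InvalidParameterError("kappa must be >= 0")
    bound = math.radians(min(max(bound_deg, 0.0), 180.0))
    if kappa == 0.0:
        return bound / np.pi
    val, _ = integrate.quad(lambda t: _vm_pdf(t, kappa), 0.0, bound, limit=200)
    return float(min(2.0 * val, 1.0))
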