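"""Circular statistics for escape-direction analysis.

Implements, from the published formulas, the primitives the behavioural
pipeline needs: vector summaries of angular samples, the Rayleigh test of
uniformity, Rao's homogeneity test (dispersion component), bootstrap
confidence arcs for circular means, the multimodal-to-unimodal angle
transform used to compare bimodal paired-stimulus escape distributions
with unimodal single-stimulus ones, and the sector / orientation binning
protocols.

All angles are degrees in [0, 360).  Axial data (directions defined only
up to 180 deg) are analysed by doubling the angles modulo 360 and halving
the mean back, the standard convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps


class InvalidInputError(ValueError):
    """Sample does not satisfy the preconditions of a statistical test."""


# ---------------------------------------------------------------------------
# basic summaries


def _to_angles(angles) -> np.ndarray:
    a = np.atleast_1d(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise InvalidInputError("empty angular sample")
    return np.mod(a, 360.0)


@dataclass(frozen=True)
class CircularSummary:
    """Vector summary of an angular sample.

    ``mean_direction`` is in degrees (on the original scale for axial
    samples, i.e. halved back after doubling); ``rho`` is the mean
    resultant length in [0, 1] (computed on the doubled scale for axial
    samples).  ``mean_defined`` is False for balanced samples whose
    resultant is numerically zero, where the mean direction is arbitrary.
    """

    mean_direction: float
    rho: float
    n: int
    axial: bool = False
    mean_defined: bool = True


def circ_summary(angles, axial: bool = False) -> CircularSummary:
    """Circular mean direction and mean resultant length of a sample."""
    a = _to_angles(angles)
    work = np.mod(2.0 * a, 360.0) if axial else a
    rad = np.radians(work)
    c, s = np.cos(rad).mean(), np.sin(rad).mean()
    rho = float(np.hypot(c, s))
    defined = rho > 1e-12
    mean = float(np.degrees(np.arctan2(s, c))) % 360.0 if defined else np.nan
    if axial and defined:
        mean /= 2.0
    return CircularSummary(
        mean_direction=mean,
        rho=min(rho, 1.0),
        n=a.size,
        axial=axial,
        mean_defined=defined,
    )


def angular_difference(a: float, b: float) -> float:
    """Signed shortest-arc difference ``a - b`` in (-180, 180]."""
    d = (float(a) - float(b)) % 360.0
    return d - 360.0 if d > 180.0 else d


def transform_multimodal(angles, m: int):
    """Map an m-modal angular sample onto a common mode: ``(m*a) mod 360``.

    With the stimulus frames used here (paired stimuli at 0/270 or 0/180
    deg), multiplying by 4 (Paired 90) or 2 (Paired 180) maps both
    selective escape modes onto 0 deg and the divided-attention mode onto
    180 deg, so bimodal distributions become unimodal and comparable with
    analogously transformed single-stimulus data.
    """
    if m not in (2, 4):
        warnings.warn(
            f"multimodal transform with m={m}; the standard protocol uses "
            "m=4 (90-deg separation) or m=2 (axial / 180-deg separation)",
            stacklevel=2,
        )
    a = _to_angles(angles)
    out = np.mod(float(m) * a, 360.0)
    return out if np.ndim(angles) else float(out[0])


# ---------------------------------------------------------------------------
# tests


def rayleigh_test(angles, axial: bool = False) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns ``(Z, p)`` with ``Z = n * rho**2`` and the standard series
    approximation for the p-value,

    ``p = exp(-Z) * [1 + (2Z - Z^2)/(4n)
          - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]``,

    clipped to [0, 1].  Accurate for n >= 4; requires n >= 2.
    """
    a = _to_angles(angles)
    n = a.size
    if n < 2:
        raise InvalidInputError("Rayleigh test needs at least 2 angles")
    rho = circ_summary(a, axial=axial).rho
    z = n * rho**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4)
        / (288.0 * n**2)
    )
    return float(z), float(np.clip(p, 0.0, 1.0))


def _group_moments(angles: np.ndarray):
    """Per-group mean cos/sin, their (co)variances, and resultant length."""
    rad = np.radians(angles)
    c, s = np.cos(rad), np.sin(rad)
    n = angles.size
    cbar, sbar = c.mean(), s.mean()
    var_c = c.var(ddof=1)
    var_s = s.var(ddof=1)
    cov_cs = ((c - cbar) * (s - sbar)).sum() / (n - 1)
    rbar = float(np.hypot(cbar, sbar))
    return cbar, sbar, var_c, var_s, cov_cs, rbar, n


def rao_dispersion_test(samples) -> tuple[float, int, float]:
    """Rao's (1967) homogeneity test, dispersion component.

    Tests equality of circular dispersions across k groups by comparing
    the per-group mean resultant lengths ``Rbar_i``.  The large-sample
    variance of ``Rbar_i`` follows from the delta method,

    ``var(Rbar) = (Cbar^2 s_cc + 2 Cbar Sbar s_cs + Sbar^2 s_ss)
                  / (n Rbar^2)``,

    and the statistic is the weighted heterogeneity chi-square

    ``H = sum Rbar_i^2 / v_i - (sum Rbar_i / v_i)^2 / sum 1/v_i``

    with k - 1 degrees of freedom.

    Parameters
    ----------
    samples : sequence of array_like
        k >= 2 angular samples (deg), each with n >= 5 observations.

    Returns
    -------
    (chi2, df, p)
    """
    groups = [_to_angles(s) for s in samples]
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    if any(g.size < 5 for g in groups):
        raise InvalidInputError("each group needs at least 5 angles")
    t, v = [], []
    for g in groups:
        cbar, sbar, var_c, var_s, cov_cs, rbar, n = _group_moments(g)
        if rbar < 1e-12:
            raise InvalidInputError(
                "a group has zero resultant length; dispersion undefined"
            )
        var_r = (
            cbar**2 * var_c + 2.0 * cbar * sbar * cov_cs + sbar**2 * var_s
        ) / (n * rbar**2)
        t.append(rbar)
        v.append(max(var_r, 1e-300))
    t = np.asarray(t)
    w = 1.0 / np.asarray(v)
    chi2 = float(np.sum(t**2 * w) - np.sum(t * w) ** 2 / np.sum(w))
    chi2 = max(chi2, 0.0)
    df = len(groups) - 1
    p = float(sps.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p


def bootstrap_direction_ci(
    angles,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | None = None,
    axial: bool = False,
) -> tuple[float, float]:
    """Percentile bootstrap confidence arc for the circular mean direction.

    Bootstrap mean directions are re-centred on the full-sample mean via
    the shortest signed arc before taking percentiles, so intervals never
    wrap incorrectly across 0/360.  Returns ``(lo, hi)`` in degrees on the
    original scale; the arc runs counter-clockwise from lo to hi.

    For samples whose mean direction is undefined (resultant ~ 0) a
    warning is issued and the full circle ``(0, 360)`` returned.
    """
    a = _to_angles(angles)
    if a.size < 8:
        raise InvalidInputError("bootstrap CI needs at least 8 angles")
    if n_boot < 2:
        warnings.warn(
            "n_boot < 2 gives a degenerate bootstrap interval", stacklevel=2
        )
    summary = circ_summary(a, axial=axial)
    if not summary.mean_defined:
        warnings.warn(
            "mean direction undefined (resultant ~ 0); "
            "returning the full circle",
            stacklevel=2,
        )
        return (0.0, 360.0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(max(n_boot, 1), a.size))
    work = np.mod(2.0 * a, 360.0) if axial else a
    rad = np.radians(work[idx])
    means = np.degrees(
        np.arctan2(np.sin(rad).mean(axis=1), np.cos(rad).mean(axis=1))
    ) % 360.0
    if axial:
        # re-centre on the doubled scale, halve back at the end
        centre = summary.mean_direction * 2.0 % 360.0
    else:
        centre = summary.mean_direction
    delta = (means - centre + 180.0) % 360.0 - 180.0
    alpha = 1.0 - level
    lo_d, hi_d = np.quantile(delta, [alpha / 2.0, 1.0 - alpha / 2.0])
    lo, hi = (centre + lo_d) % 360.0, (centre + hi_d) % 360.0
    if axial:
        lo, hi = lo / 2.0, hi / 2.0
    return (float(lo), float(hi))


def ci_contains(ci: tuple[float, float], angle: float) -> bool:
    """Whether a counter-clockwise angular interval contains ``angle``."""
    lo, hi = ci
    span = (hi - lo) % 360.0
    if span == 0.0 and hi != lo:
        span = 360.0
    return (float(angle) - lo) % 360.0 <= span


def arcs_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Whether two counter-clockwise angular intervals intersect."""
    return (
        ci_contains(a, b[0])
        or ci_contains(a, b[1])
        or ci_contains(b, a[0])
        or ci_contains(b, a[1])
    )


# ---------------------------------------------------------------------------
# sector and orientation binning


@dataclass(frozen=True)
class SectorScheme:
    """Labelled half-open angular sectors ``[lo, hi)`` on the circle.

    ``sectors`` maps labels ('green', 'red', 'white') to lists of
    (lo, hi) interval bounds in degrees; angles in no listed sector are
    'unlabeled'.  Intervals must not overlap.
    """

    sectors: dict = field(
        default_factory=lambda: paired90_sector_scheme().sectors
    )

    def __post_init__(self) -> None:
        spans = []
        for intervals in self.sectors.values():
            for lo, hi in intervals:
                spans.append((lo % 360.0, hi % 360.0))
        for (lo1, hi1), (lo2, hi2) in combinations(spans, 2):
            mid = (lo1 + ((hi1 - lo1) % 360.0) / 2.0) % 360.0
            if _in_halfopen(mid, lo2, hi2) or _in_halfopen(lo1, lo2, hi2):
                raise InvalidInputError("sector intervals overlap")


def _in_halfopen(angle: float, lo: float, hi: float) -> bool:
    return (angle - lo) % 360.0 < (hi - lo) % 360.0


def paired90_sector_scheme(
    azimuths: tuple[float, float] = (0.0, 270.0), width: float = 45.0
) -> SectorScheme:
    """The green/white/red sector protocol for 90-deg-separated stimuli.

    With stimuli at 0 and 270 deg the selective-attention escape modes sit
    at 180 and 90 deg and the divided-attention mode at 135 deg.  The
    central ``width`` of each selective mode is white (excluded from
    analysis); the inner flank between them, centred on the divided mode,
    is green; the two outer flanks are red.  Green vs combined-red then
    compares an inner-tail with an outer-tail count, which is balanced
    (~50% green) for purely selective behaviour and green-heavy under a
    divided contribution.
    """
    away = sorted(((a + 180.0) % 360.0 for a in azimuths))
    lo_mode, hi_mode = away  # e.g. 90 and 180
    h = width / 2.0
    return SectorScheme(
        sectors={
            "white": [
                (lo_mode - h, lo_mode + h),
                (hi_mode - h, hi_mode + h),
            ],
            "green": [(lo_mode + h, hi_mode - h)],
            "red": [
                (hi_mode + h, hi_mode + 3 * h),
                (lo_mode - 3 * h, lo_mode - h),
            ],
        }
    )


def sector_classify(angle, scheme: SectorScheme | None = None):
    """Label of the sector containing ``angle``; 'unlabeled' if none."""
    if scheme is None:
        scheme = paired90_sector_scheme()
    a = np.atleast_1d(_to_angles(angle))
    out = np.full(a.shape, "unlabeled", dtype=object)
    for label, intervals in scheme.sectors.items():
        for lo, hi in intervals:
            mask = (a - lo) % 360.0 < (hi - lo) % 360.0
            out[mask] = label
    return out if np.ndim(angle) else str(out[0])


def sector_proportion_test(
    labels_single,
    labels_paired,
    n_perm: int | None = 9999,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Permutation test on P(green | green or red) between two groups.

    White and unlabeled escapes are excluded, mirroring the protocol in
    which the central 45 deg of each predicted peak is not analysed.  The
    test statistic is the difference in green proportions; group labels
    are permuted (``n_perm`` random permutations, or exhaustively over all
    assignments when ``n_perm`` is None).  Two-sided p-value.

    Returns ``(prop_green_single, prop_green_paired, p)``.
    """
    g1 = _green_indicator(labels_single, "single")
    g2 = _green_indicator(labels_paired, "paired")
    n1, n2 = g1.size, g2.size
    p1, p2 = g1.mean(), g2.mean()
    observed = abs(p2 - p1)
    pooled = np.concatenate([g1, g2])
    total_green = int(pooled.sum())
    if n_perm is None:
        # exhaustive: the statistic depends only on how many of the
        # pooled green escapes land in group 1 -> hypergeometric weights
        count_extreme = 0
        total = comb(n1 + n2, n1)
        for k in range(max(0, total_green - n2), min(n1, total_green) + 1):
            stat = abs(
                (total_green - k) / n2 - k / n1
            )
            if stat >= observed - 1e-12:
                count_extreme += comb(total_green, k) * comb(
                    n1 + n2 - total_green, n1 - k
                )
        pval = count_extreme / total
    else:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(pooled, (int(n_perm), 1)), axis=1)
        stat = np.abs(
            perms[:, n1:].mean(axis=1) - perms[:, :n1].mean(axis=1)
        )
        pval = (1 + int((stat >= observed - 1e-12).sum())) / (1 + int(n_perm))
    return float(p1), float(p2), float(min(pval, 1.0))


def _green_indicator(labels, name: str) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    keep = np.isin(arr, ("green", "red"))
    if not keep.any():
        raise InvalidInputError(
            f"{name} group has no green or red escapes to compare"
        )
    return (arr[keep] == "green").astype(float)


_ORIENTATION_BINS = (
    "lateral_0",
    "anteroposterior_90",
    "lateral_180",
    "anteroposterior_270",
)


def bin_orientation(body_orientation_rel_stimulus):
    """Assign a body orientation (deg) to one of four 90-deg bins.

    Orientation is the azimuth of the crab's lateral (long) body axis
    relative to the reference stimulus.  Bins are centred on 0, 90, 180
    and 270 deg with half-open bounds [centre-45, centre+45), so the bins
    centred on 0/180 capture trials in which the stimulus approached
    along the lateral axis and the 90/270 bins trials in which it
    approached along the anterior-posterior axis.
    """
    a = np.atleast_1d(_to_angles(body_orientation_rel_stimulus))
    idx = (np.floor((a + 45.0) / 90.0).astype(int)) % 4
    out = np.asarray(_ORIENTATION_BINS, dtype=object)[idx]
    return out if np.ndim(body_orientation_rel_stimulus) else str(out[0])
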