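"""Nuclei-area morphometry for ploidy inference.

Genome doubling roughly doubles nuclear volume; since projected area scales as
volume^(2/3), a tetraploid nucleus is ~2^(2/3) = 1.59x larger in area than its
diploid counterpart.  A mixed diploid/tetraploid population therefore shows a
multimodal area distribution, and the antimode between the diploid and
tetraploid modes provides a ploidy threshold.  Anisonucleosis (spread of
nuclear sizes) is compared between samples with the Feltz-Miller asymptotic
test on coefficients of variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import cluster, signal, stats

from .errors import DataError, ParameterError

__all__ = [
    "NucleiSample",
    "ModeStructure",
    "AreaStats",
    "area_stats",
    "volume_area_factor",
    "fraction_large",
    "threshold_from_modes",
    "cluster_clones",
    "feltz_miller_test",
]


@dataclass
class NucleiSample:
    """Per-nucleus projected areas (um^2) for one cell line or clone."""

    sample_id: str
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 1 or self.areas.size < 1:
            raise DataError(f"{self.sample_id}: need a non-empty 1-d area vector")
        if not np.all(self.areas > 0):
            raise DataError(f"{self.sample_id}: areas must be positive")

    @property
    def n(self) -> int:
        return self.areas.size


@dataclass
class ModeStructure:
    """Detected modes and interleaving antimodes of an area distribution."""

    mode_areas: list[float]
    antimodes: list[float]
    bandwidth: float
    suggested_threshold: float
    threshold_source: str  # "antimode" or "volume_scaling_fallback"


class AreaStats(NamedTuple):
    mean: float
    sd: float
    cv: float


def area_stats(sample: NucleiSample) -> AreaStats:
    """Sample mean, SD (n-1 denominator) and coefficient of variation."""
    if sample.n < 2:
        raise DataError("need at least 2 nuclei for dispersion statistics")
    mean = float(np.mean(sample.areas))
    sd = float(np.std(sample.areas, ddof=1))
    return AreaStats(mean=mean, sd=sd, cv=sd / mean)


def volume_area_factor(volume_ratio: float) -> float:
    """Area ratio corresponding to a volume ratio: V^(2/3) for a nucleus that
    scales isotropically (doubling the volume gives 2^(2/3) ~ 1.59x area)."""
    if volume_ratio <= 0:
        raise ParameterError("volume ratio must be positive")
    return float(volume_ratio ** (2.0 / 3.0))


def fraction_large(sample: NucleiSample, threshold: float) -> float:
    """Proportion of nuclei with area strictly greater than `threshold`."""
    return float(np.mean(sample.areas > threshold))


def threshold_from_modes(
    sample: NucleiSample, n_grid: int = 1024, bw_adjust: float = 1.0
) -> ModeStructure:
    """Kernel-density mode/antimode detection and a suggested ploidy threshold.

    The density is estimated on log-area (areas are right-skewed) with
    Silverman's bandwidth, optionally scaled by ``bw_adjust``, and mapped
    back.  Peaks below 1% relative prominence are treated as noise.  The
    suggested threshold is the first antimode above the principal
    (highest-density) mode.  When no antimode is resolved — including the
    common case of a small doubled-genome subpopulation that only produces a
    shoulder, not a separate peak — the threshold falls back to
    principal_mode * 2^(2/3), the area expected of a doubled-volume nucleus.
    """
    if sample.n < 50:
        raise DataError("need at least 50 nuclei for mode detection")
    if bw_adjust <= 0:
        raise ParameterError("bw_adjust must be positive")
    if np.ptp(sample.areas) == 0:
        raise DataError("degenerate (constant) area distribution")
    log_a = np.log(sample.areas)
    kde = stats.gaussian_kde(log_a, bw_method="silverman")
    kde.set_bandwidth(kde.factor * bw_adjust)
    grid = np.linspace(log_a.min() - 0.25, log_a.max() + 0.25, n_grid)
    dens = kde(grid)

    # prominence filter suppresses spurious bumps in low-density tails
    max_idx, _ = signal.find_peaks(dens, prominence=0.01 * dens.max())
    if len(max_idx) == 0:  # monotone density on the open grid; use global max
        max_idx = np.array([int(np.argmax(dens))])
    # antimodes interleave the retained modes
    min_idx = np.array(
        [a + int(np.argmin(dens[a : b + 1])) for a, b in zip(max_idx[:-1], max_idx[1:])],
        dtype=int,
    )
    modes = [float(np.exp(grid[i])) for i in max_idx]
    antis = [float(np.exp(grid[i])) for i in min_idx]

    principal = modes[int(np.argmax(dens[max_idx]))]
    # the diploid/tetraploid boundary must lie below the area of a
    # doubled-volume nucleus; an antimode beyond it means the doubled mode
    # was merged into a higher cluster, so the volume-scaling rule applies
    cap = principal * volume_area_factor(2.0)
    above = [a for a in antis if principal < a < cap]
    if above:
        threshold = above[0]
        source = "antimode"
    else:
        threshold = cap
        source = "volume_scaling_fallback"
    bw = float(kde.factor * np.std(log_a, ddof=1))
    return ModeStructure(
        mode_areas=modes,
        antimodes=antis,
        bandwidth=bw,
        suggested_threshold=float(threshold),
        threshold_source=source,
    )


def cluster_clones(mean_areas: Mapping[str, float]) -> tuple[dict[str, str], bool]:
    """Split clones into {small, large} by average nuclei area.

    Agglomerative clustering (single feature, Euclidean distance, average
    linkage) cut into two groups; the group with the larger centroid is
    labeled "large".  Returns ``(labels, flagged)`` where ``flagged`` marks a
    degenerate split (all means equal -> one effective cluster).
    """
    if len(mean_areas) < 3:
        raise DataError("need at least 3 clones to cluster")
    names = sorted(mean_areas)  # deterministic tie-break by clone label order
    x = np.array([[mean_areas[k]] for k in names], dtype=float)
    if np.all(x == x[0]):
        return {k: "small" for k in names}, True
    link = cluster.hierarchy.linkage(x, method="average", metric="euclidean")
    assign = cluster.hierarchy.fcluster(link, t=2, criterion="maxclust")
    centroids = {g: x[assign == g].mean() for g in np.unique(assign)}
    large_group = max(centroids, key=lambda g: centroids[g])
    labels = {
        k: ("large" if g == large_group else "small") for k, g in zip(names, assign)
    }
    flagged = len(centroids) < 2
    return labels, flagged


def feltz_miller_test(samples: Sequence[NucleiSample]) -> tuple[float, int, float]:
    """Asymptotic chi-square test for equality of coefficients of variation.

    With m_i = n_i - 1, c_i the sample CVs and pooled c = sum(m_i c_i)/sum(m_i),
    the statistic D = sum m_i (c_i - c)^2 / [c^2 (0.5 + c^2)] is approximately
    chi-square with k-1 degrees of freedom under equal CVs.

    Returns ``(D, df, p)``.
    """
    if len(samples) < 2:
        raise DataError("need at least 2 samples")
    cvs, ms = [], []
    for s in samples:
        if s.n < 10:
            raise DataError(f"{s.sample_id}: need n >= 10 per sample")
        cv = area_stats(s).cv
        if cv == 0:
            raise DataError(f"{s.sample_id}: zero CV")
        cvs.append(cv)
        ms.append(s.n - 1)
    cvs = np.asarray(cvs)
    ms = np.asarray(ms, dtype=float)
    cbar = float(np.sum(ms * cvs) / np.sum(ms))
    d = float(np.sum(ms * (cvs - cbar) ** 2) / (cbar**2 * (0.5 + cbar**2)))
    df = len(samples) - 1
    p = float(stats.chi2.sf(d, df))
    return d, df, p
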