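"""Methylation-specific qPCR: Cq calling, relative demethylation levels (RDL),
somatic demethylation (delta-RDL) and tumor classification.

The assay runs two reactions per sample: one amplifying only unmethylated
target molecules and one serving as the per-sample denominator (for LINE-1 a
methylated-specific reaction, for SST1 a methylation-independent reaction).
The Cq difference between the two reactions measures the unmethylated
proportion; normalizing against the same difference in a fixed reference
genomic DNA gives the relative demethylation level

    RDL = E^[(Cq_denominator - Cq_unmethylated)_sample
             - (Cq_denominator - Cq_unmethylated)_reference]

with amplification efficiency E (default 2).  Higher RDL means more
demethylation.  The somatic demethylation value of a tumor/normal pair is
delta-RDL = log2 RDL_tumor - log2 RDL_normal; tumors are classed as
strong (>3), moderate (1..3] excluded top, i.e. 1 < delta <= 3) or none
(<=1) demethylation.  Strongly demethylated tumors are alternatively flagged
as upward outliers from the tumor-on-normal regression's 95% prediction band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import DataError, ParameterError

__all__ = [
    "AmplificationCurve",
    "CqResult",
    "RdlRecord",
    "SamplePair",
    "call_cq",
    "rdl",
    "delta_rdl",
    "classify",
    "RdlRegressionModel",
    "RdlRegressionResults",
    "regression_outliers",
]

REACTIONS = ("unmethylated_specific", "methylated_specific", "methylation_independent")


@dataclass
class AmplificationCurve:
    """Raw fluorescence per cycle for one qPCR reaction."""

    cycles: np.ndarray
    fluorescence: np.ndarray
    reaction: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycles.shape != self.fluorescence.shape or self.cycles.ndim != 1:
            raise DataError("cycles and fluorescence must be matching 1-d arrays")
        if len(self.cycles) < 20:
            raise DataError("need at least 20 cycles")
        if not np.isfinite(self.fluorescence).all():
            raise DataError("non-finite fluorescence")
        if self.reaction not in REACTIONS:
            raise ParameterError(f"unknown reaction {self.reaction!r}")


@dataclass(frozen=True)
class CqResult:
    """Quantification cycle from the second-derivative-maximum method."""

    cq: float  # NaN when no amplification detected
    confident: bool
    reason: str = ""

    @property
    def detected(self) -> bool:
        return math.isfinite(self.cq)


def call_cq(
    curve: AmplificationCurve,
    window: int = 5,
    polyorder: int = 3,
    min_snr: float = 10.0,
    confident_snr: float = 20.0,
) -> CqResult:
    """Cq at the maximum of the second derivative of the smoothed curve.

    The fluorescence is smoothed with a local polynomial (Savitzky-Golay,
    window 5, order 3), second-differenced, and the discrete maximum is
    refined by parabolic interpolation to sub-cycle resolution.

    A curve whose total rise is below ``min_snr`` times the smoothing-residual
    noise is reported as undetected ("no Cq"); between ``min_snr`` and
    ``confident_snr`` the Cq is returned but flagged low-confidence.  A curve
    already near plateau at the first cycle raises an error, since its
    exponential phase was not observed.
    """
    f = curve.fluorescence
    smooth = savgol_filter(f, window_length=window, polyorder=polyorder)
    resid_sd = float(np.std(f - smooth, ddof=1))
    amplitude = float(smooth.max() - smooth.min())
    if amplitude <= 0 or (resid_sd > 0 and amplitude < min_snr * resid_sd):
        return CqResult(cq=float("nan"), confident=False, reason="no_amplification")
    if smooth[0] >= 0.8 * smooth[-1] and smooth[-1] > 0:
        # already near plateau at the first cycle: exponential phase missed
        raise DataError("curve saturated from the first cycle; no exponential phase")

    d2 = smooth[2:] - 2.0 * smooth[1:-1] + smooth[:-2]  # at cycles[1:-1]
    j = int(np.argmax(d2))
    cq = curve.cycles[j + 1]
    if 0 < j < len(d2) - 1:
        denom = d2[j - 1] - 2.0 * d2[j] + d2[j + 1]
        if denom != 0:
            delta = 0.5 * (d2[j - 1] - d2[j + 1]) / denom
            step = curve.cycles[1] - curve.cycles[0]
            cq = cq + float(np.clip(delta, -1, 1)) * step
    confident = resid_sd == 0 or amplitude >= confident_snr * resid_sd
    return CqResult(cq=float(cq), confident=confident, reason="" if confident else "low_snr")


@dataclass
class RdlRecord:
    """Reference-normalized relative demethylation level for one sample."""

    sample_id: str
    tissue: str  # tumor | normal | cell_line
    assay: str  # SST1 | LINE1
    cq_u: float
    cq_ref_reaction: float
    rdl: float
    log2_rdl: float
    denominator_reaction: str = "methylation_independent"

    @property
    def missing(self) -> bool:
        return not math.isfinite(self.rdl)


def _mean_cq(cq) -> float:
    """Duplicates are averaged on the Cq scale (standard qPCR practice)."""
    if np.isscalar(cq):
        return float(cq)
    arr = np.asarray(list(cq) if isinstance(cq, Iterable) else cq, dtype=float)
    return float(np.mean(arr))


def rdl(
    cq_u_sample,
    cq_m_sample,
    cq_u_ref,
    cq_m_ref,
    efficiency: float = 2.0,
    sample_id: str = "",
    tissue: str = "tumor",
    assay: str = "SST1",
    denominator_reaction: str = "methylation_independent",
) -> RdlRecord:
    """Relative demethylation level from four Cq values (or duplicate lists).

    rdl = E^[(cq_m_sample - cq_u_sample) - (cq_m_ref - cq_u_ref)], where
    the "m" reaction is the assay's denominator (methylated-specific for
    LINE-1, methylation-independent for SST1).  Missing (NaN) Cq values
    propagate to a missing record rather than raising.
    """
    if efficiency <= 1:
        raise ParameterError("efficiency must exceed 1")
    cqs = [_mean_cq(c) for c in (cq_u_sample, cq_m_sample, cq_u_ref, cq_m_ref)]
    cu_s, cm_s, cu_r, cm_r = cqs
    if any(not math.isfinite(c) for c in cqs):
        value = float("nan")
    else:
        value = efficiency ** ((cm_s - cu_s) - (cm_r - cu_r))
    return RdlRecord(
        sample_id=sample_id,
        tissue=tissue,
        assay=assay,
        cq_u=cu_s,
        cq_ref_reaction=cm_s,
        rdl=value,
        log2_rdl=math.log2(value) if value > 0 else float("nan"),
        denominator_reaction=denominator_reaction,
    )


def delta_rdl(tumor: RdlRecord, normal: RdlRecord) -> float:
    """Somatic demethylation: log2 RDL(tumor) - log2 RDL(normal)."""
    if tumor.assay != normal.assay:
        raise DataError(f"assay mismatch: {tumor.assay} vs {normal.assay}")
    return tumor.log2_rdl - normal.log2_rdl


def classify(delta: float) -> str:
    """Demethylation class from delta-RDL: >3 strong, (1, 3] moderate,
    <=1 none.  Equality at the boundaries is assigned downward (1 -> none,
    3 -> moderate)."""
    if not math.isfinite(delta):
        raise DataError("delta-RDL must be finite")
    if delta > 3:
        return "strong"
    if delta > 1:
        return "moderate"
    return "none"


@dataclass
class SamplePair:
    """One patient's tumor/normal pair of somatic demethylation values."""

    patient_id: str
    delta_rdl_sst1: float
    delta_rdl_line1: float
    class_sst1: str = field(default="")
    outlier_flag: bool = False

    def __post_init__(self) -> None:
        if not self.class_sst1 and math.isfinite(self.delta_rdl_sst1):
            self.class_sst1 = classify(self.delta_rdl_sst1)


@dataclass
class RdlRegressionResults:
    """OLS fit of tumor log2 RDL on normal log2 RDL with outlier flags."""

    slope: float
    intercept: float
    r: float
    outlier_flags: np.ndarray
    upper_band: np.ndarray
    lower_band: np.ndarray
    alpha: float
    band: str
    ols_results: object = field(repr=False)  # statsmodels RegressionResults
    normal: np.ndarray = field(repr=False, default=None)
    tumor: np.ndarray = field(repr=False, default=None)

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_flags.sum())

    def summary(self) -> str:
        return (
            "Tumor-on-normal log2 RDL regression\n"
            "===================================\n"
            f"n = {len(self.outlier_flags)}\n"
            f"slope = {self.slope:.3f}, intercept = {self.intercept:.3f}, "
            f"r = {self.r:.3f}\n"
            f"{self.band} band at {100*(1-self.alpha):.0f}%: "
            f"{self.n_outliers} upward outlier(s) flagged"
        )

    def plot(self, ax=None):
        """Scatter with fitted line and the outlier band; outliers in red."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = np.argsort(self.normal)
        ax.plot(self.normal[order], self.intercept + self.slope * self.normal[order], "b-")
        ax.plot(self.normal[order], self.upper_band[order], "k--", lw=0.8)
        ax.plot(self.normal[order], self.lower_band[order], "k--", lw=0.8)
        ok = ~self.outlier_flags
        ax.scatter(self.normal[ok], self.tumor[ok], s=12, c="tab:blue")
        ax.scatter(self.normal[~ok], self.tumor[~ok], s=18, c="tab:red")
        ax.set_xlabel("normal log2 RDL")
        ax.set_ylabel("tumor log2 RDL")
        return ax


class RdlRegressionModel:
    """Flag strongly demethylated tumors as upward outliers from the
    tumor-on-normal log2 RDL regression.

    Parameters
    ----------
    normal, tumor : 1-d arrays of log2 RDL values, paired by patient.
    """

    def __init__(self, normal, tumor) -> None:
        self.normal = np.asarray(normal, dtype=float)
        self.tumor = np.asarray(tumor, dtype=float)
        if self.normal.shape != self.tumor.shape or self.normal.ndim != 1:
            raise DataError("normal and tumor must be matching 1-d arrays")
        if len(self.normal) < 10:
            raise DataError("need at least 10 pairs")
        if np.std(self.normal) == 0:
            raise DataError("degenerate normal-tissue variance")

    def fit(self, alpha: float = 0.05, band: str = "prediction") -> RdlRegressionResults:
        """OLS fit; a tumor is an outlier when its value exceeds the upper
        limit of the 95% band at its normal-tissue value.  ``band`` selects
        the prediction interval for a new observation (default; encloses
        nearly all non-outlying points) or the mean-response confidence band.
        """
        import statsmodels.api as sm

        if band not in ("prediction", "mean"):
            raise ParameterError("band must be 'prediction' or 'mean'")
        X = sm.add_constant(self.normal)
        res = sm.OLS(self.tumor, X).fit()
        pred = res.get_prediction(X).summary_frame(alpha=alpha)
        if band == "prediction":
            upper = pred["obs_ci_upper"].values
            lower = pred["obs_ci_lower"].values
        else:
            upper = pred["mean_ci_upper"].values
            lower = pred["mean_ci_lower"].values
        flags = self.tumor > upper
        r = float(np.corrcoef(self.normal, self.tumor)[0, 1])
        return RdlRegressionResults(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            r=r,
            outlier_flags=flags,
            upper_band=upper,
            lower_band=lower,
            alpha=alpha,
            band=band,
            ols_results=res,
            normal=self.normal,
            tumor=self.tumor,
        )


def regression_outliers(
    normal, tumor, alpha: float = 0.05, band: str = "prediction"
) -> RdlRegressionResults:
    """Functional wrapper around :class:`RdlRegressionModel`."""
    return RdlRegressionModel(normal, tumor).fit(alpha=alpha, band=band)
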