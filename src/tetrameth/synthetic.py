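"""Synthetic-data generators with known ground truth.

Every downstream stage of the package is testable without external data:
these generators emulate the five input kinds the analysis consumes —
bisulfite clone state matrices, qPCR amplification curves, per-nucleus area
tables, stochastic karyotype trajectories and a tumor/normal cohort table —
with the statistical structure the methods assume, and return the simulated
truth alongside.  Seeds are explicit arguments, never global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import msqpcr
from .bisulfite import MethylationMatrix
from .cohort import CohortTable
from .errors import ParameterError
from .msqpcr import AmplificationCurve
from .nuclei import NucleiSample
from .ploidy import KaryotypeCount, PloidyModel

__all__ = [
    "BisulfiteSimSpec",
    "QpcrSimSpec",
    "NucleiSimSpec",
    "CohortSimSpec",
    "QpcrCurveSet",
    "gen_bisulfite_clones",
    "gen_qpcr_curves",
    "gen_nuclei_areas",
    "gen_cohort",
    "gen_clonal_trajectory",
]


def _check_fraction(name: str, value: float, lo: float = 0.0, hi: float = 1.0) -> None:
    if not (lo <= value <= hi):
        raise ParameterError(f"{name} must be in [{lo}, {hi}], got {value}")


@dataclass(frozen=True)
class BisulfiteSimSpec:
    """Clone-level bisulfite simulation: per-molecule methylation drawn from a
    beta-binomial (clone mean + intra-clone overdispersion), polymorphic CpGs
    masked non-informative, and a per-molecule conversion-failure rate."""

    n_clones: int
    molecules_per_clone: int
    clone_mean_meth: Sequence[float]
    n_cpg: int = 28
    intra_clone_dispersion: float = 0.2
    polymorphic_site_prob: float = 0.0
    conversion_failure_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_clones < 1 or self.molecules_per_clone < 1 or self.n_cpg < 1:
            raise ParameterError("counts must be >= 1")
        if len(self.clone_mean_meth) != self.n_clones:
            raise ParameterError("clone_mean_meth length must equal n_clones")
        for m in self.clone_mean_meth:
            _check_fraction("clone_mean_meth", m)
        if not (0.0 <= self.intra_clone_dispersion < 1.0):
            raise ParameterError("intra_clone_dispersion must be in [0, 1)")
        _check_fraction("polymorphic_site_prob", self.polymorphic_site_prob)
        _check_fraction("conversion_failure_rate", self.conversion_failure_rate)


def gen_bisulfite_clones(
    spec: BisulfiteSimSpec, seed: int | None = 0
) -> tuple[list[MethylationMatrix], np.ndarray]:
    """Simulate per-clone methylation matrices.

    Each molecule draws its methylation probability from a Beta distribution
    with the clone's mean mu and dispersion rho (a = mu(1-rho)/rho,
    b = (1-mu)(1-rho)/rho; rho -> 0 degenerates to Binomial(mu)); sites are
    then independent Bernoulli draws, masked non-informative with the
    polymorphic-site probability.  Returns the matrices and the true clone
    means (ground truth).
    """
    rng = np.random.default_rng(seed)
    matrices = []
    for c, mu in enumerate(spec.clone_mean_meth):
        n_mol, n_cpg = spec.molecules_per_clone, spec.n_cpg
        if spec.intra_clone_dispersion == 0 or mu in (0.0, 1.0):
            p_mol = np.full(n_mol, mu)
        else:
            rho = spec.intra_clone_dispersion
            a = mu * (1 - rho) / rho
            b = (1 - mu) * (1 - rho) / rho
            p_mol = rng.beta(a, b, size=n_mol)
        states = (rng.random((n_mol, n_cpg)) < p_mol[:, None]).astype(float)
        if spec.polymorphic_site_prob > 0:
            mask = rng.random((n_mol, n_cpg)) < spec.polymorphic_site_prob
            states[mask] = np.nan
        conv_ok = rng.random(n_mol) >= spec.conversion_failure_rate
        matrices.append(
            MethylationMatrix(
                clone_id=f"C{c + 1}",
                states=states,
                conversion_ok=conv_ok,
            )
        )
    return matrices, np.asarray(spec.clone_mean_meth, dtype=float)


@dataclass(frozen=True)
class QpcrSimSpec:
    """Four-curve qPCR simulation for one sample against the reference DNA.

    The unmethylated-specific reaction's template is the unmethylated
    fraction; the denominator reaction's template is the full target (1).
    True RDL = true_unmeth_fraction / reference_unmeth_fraction.
    """

    true_unmeth_fraction: float
    reference_unmeth_fraction: float
    efficiency: float = 2.0
    n_cycles: int = 45
    plateau: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0
    midpoint_cycle: float = 22.0  # logistic midpoint for template abundance 1

    def __post_init__(self) -> None:
        for name in ("true_unmeth_fraction", "reference_unmeth_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ParameterError(f"{name} must be in (0, 1], got {v}")
        if not (1.0 < self.efficiency <= 2.0):
            raise ParameterError("efficiency must be in (1, 2]")
        if self.n_cycles < 20:
            raise ParameterError("n_cycles must be >= 20")
        if self.plateau <= 0 or self.noise_sd < 0:
            raise ParameterError("plateau must be positive, noise_sd non-negative")

    @property
    def true_rdl(self) -> float:
        return self.true_unmeth_fraction / self.reference_unmeth_fraction


@dataclass
class QpcrCurveSet:
    """The four amplification curves defining one RDL measurement."""

    sample_unmeth: AmplificationCurve
    sample_denominator: AmplificationCurve
    reference_unmeth: AmplificationCurve
    reference_denominator: AmplificationCurve
    true_rdl: float


def _logistic_curve(
    rng: np.random.Generator,
    template: float,
    spec: QpcrSimSpec,
    reaction: str,
    sample_id: str,
) -> AmplificationCurve:
    cycles = np.arange(1, spec.n_cycles + 1, dtype=float)
    k = math.log(spec.efficiency)
    mid = spec.midpoint_cycle - math.log(template) / k
    fl = spec.plateau / (1.0 + np.exp(-k * (cycles - mid)))
    if spec.noise_sd > 0:
        fl = fl + rng.normal(0.0, spec.noise_sd, size=fl.shape)
    return AmplificationCurve(cycles=cycles, fluorescence=fl, reaction=reaction, sample_id=sample_id)


def gen_qpcr_curves(spec: QpcrSimSpec) -> QpcrCurveSet:
    """Simulate the four logistic amplification curves of one measurement.

    The exponential-phase offset encodes template abundance: halving the
    template delays the curve by one cycle at efficiency 2, so the
    Cq arithmetic of the RDL pipeline recovers ``spec.true_rdl`` exactly in
    the noiseless limit.
    """
    rng = np.random.default_rng(spec.seed)
    return QpcrCurveSet(
        sample_unmeth=_logistic_curve(
            rng, spec.true_unmeth_fraction, spec, "unmethylated_specific", "sample"
        ),
        sample_denominator=_logistic_curve(
            rng, 1.0, spec, "methylation_independent", "sample"
        ),
        reference_unmeth=_logistic_curve(
            rng, spec.reference_unmeth_fraction, spec, "unmethylated_specific", "reference"
        ),
        reference_denominator=_logistic_curve(
            rng, 1.0, spec, "methylation_independent", "reference"
        ),
        true_rdl=spec.true_rdl,
    )


@dataclass(frozen=True)
class NucleiSimSpec:
    """Lognormal mixture of nuclei areas: strictly positive, right-skewed,
    with components centered (median) at the given modal areas."""

    mode_areas: Sequence[float]
    mode_weights: Sequence[float]
    lognormal_sigma: float = 0.18
    n_nuclei: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        areas = list(self.mode_areas)
        if not areas or any(a <= 0 for a in areas):
            raise ParameterError("mode areas must be positive")
        if any(b <= a for a, b in zip(areas, areas[1:])):
            raise ParameterError("mode areas must be strictly increasing")
        w = np.asarray(self.mode_weights, dtype=float)
        if len(w) != len(areas) or (w < 0).any() or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ParameterError("mode_weights must be a simplex matching mode_areas")
        if self.lognormal_sigma <= 0:
            raise ParameterError("lognormal_sigma must be positive")
        if self.n_nuclei < 1:
            raise ParameterError("n_nuclei must be >= 1 (empty sample)")


def gen_nuclei_areas(spec: NucleiSimSpec, sample_id: str = "sim") -> tuple[NucleiSample, np.ndarray]:
    """Draw nuclei areas from the lognormal mixture; component labels are the
    ground truth ploidy assignment."""
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(len(spec.mode_areas), size=spec.n_nuclei, p=list(spec.mode_weights))
    mus = np.log(np.asarray(spec.mode_areas, dtype=float))
    areas = np.exp(rng.normal(mus[labels], spec.lognormal_sigma))
    return NucleiSample(sample_id=sample_id, areas=areas), labels


@dataclass(frozen=True)
class CohortSimSpec:
    """Tumor/normal cohort with a known demethylation-class composition, a
    target SST1-LINE1 somatic-demethylation correlation and an elevated TP53
    mutation odds in strongly demethylated cases."""

    n_patients: int
    frac_strong: float = 0.05
    frac_moderate: float = 0.12
    sst1_line1_corr: float = 0.5
    tp53_odds: float = 10.0
    rdl_noise_sd: float = 0.25
    tp53_base_prob: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        _check_fraction("frac_strong", self.frac_strong)
        _check_fraction("frac_moderate", self.frac_moderate)
        if self.frac_strong + self.frac_moderate > 1:
            raise ParameterError("frac_strong + frac_moderate must be <= 1")
        if not (-1.0 <= self.sst1_line1_corr <= 1.0):
            raise ParameterError("correlation must be in [-1, 1]")
        if self.tp53_odds <= 0:
            raise ParameterError("tp53_odds must be positive")
        if self.rdl_noise_sd < 0:
            raise ParameterError("rdl_noise_sd must be non-negative")
        _check_fraction("tp53_base_prob", self.tp53_base_prob)


def gen_cohort(spec: CohortSimSpec) -> tuple[CohortTable, pd.DataFrame]:
    """Simulate a tumor/normal cohort table.

    Normal-tissue SST1 log2 RDL is standard normal; tumors add the class's
    true somatic shift (none: 0; moderate: U(1.2, 2.8); strong: U(3.5, 6))
    plus measurement noise, so normal and tumor values correlate strongly
    except in demethylated cases.  LINE-1 somatic demethylation is built with
    the target correlation to the SST1 value; TP53 mutation odds are
    multiplied by ``tp53_odds`` in strong cases.  Returns the cohort table
    (classes as recovered by the delta-RDL classifier) and a ground-truth
    frame with the simulated class and shifts.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    true_class = rng.choice(
        ["strong", "moderate", "none"],
        size=n,
        p=[spec.frac_strong, spec.frac_moderate, 1 - spec.frac_strong - spec.frac_moderate],
    )
    shift = np.zeros(n)
    shift[true_class == "moderate"] = rng.uniform(1.2, 2.8, (true_class == "moderate").sum())
    shift[true_class == "strong"] = rng.uniform(3.5, 6.0, (true_class == "strong").sum())

    normal_sst1 = rng.normal(0.0, 1.0, n)
    tumor_sst1 = normal_sst1 + shift + rng.normal(0.0, spec.rdl_noise_sd, n)
    delta_sst1 = tumor_sst1 - normal_sst1

    s = (delta_sst1 - delta_sst1.mean()) / delta_sst1.std()
    rho = spec.sst1_line1_corr
    delta_line1 = rho * s + math.sqrt(max(0.0, 1 - rho**2)) * rng.normal(0.0, 1.0, n)

    base_odds = spec.tp53_base_prob / (1 - spec.tp53_base_prob)
    odds = np.where(true_class == "strong", base_odds * spec.tp53_odds, base_odds)
    p_mut = odds / (1 + odds)
    tp53 = np.where(rng.random(n) < p_mut, "MUT", "WT")

    data = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "normal_log2_rdl_sst1": normal_sst1,
            "tumor_log2_rdl_sst1": tumor_sst1,
            "delta_rdl_sst1": delta_sst1,
            "delta_rdl_line1": delta_line1,
            "class_sst1": [msqpcr.classify(d) for d in delta_sst1],
            "gender": rng.choice(["F", "M"], n),
            "age_group": rng.choice(["<66", ">66"], n),
            "ethnicity": rng.choice(["Caucasian", "AfrAm"], n, p=[0.82, 0.18]),
            "location": rng.choice(["proximal", "distal"], n),
            "stage_group": rng.choice(["IS-A-B", "C-D-M"], n),
            "msi_status": rng.choice(["MSS", "MSI"], n, p=[0.85, 0.15]),
            "tp53": tp53,
            "kras": rng.choice(["WT", "MUT"], n, p=[0.63, 0.37]),
            "braf": rng.choice(["WT", "MUT"], n, p=[0.9, 0.1]),
        }
    )
    truth = pd.DataFrame(
        {"patient_id": data["patient_id"], "true_class": true_class, "true_shift": shift}
    )
    return CohortTable(data), truth


def gen_clonal_trajectory(
    model: PloidyModel,
    n0_diploid: int,
    n0_tetraploid: int,
    generations: int,
    seed: int | None = 0,
) -> list[KaryotypeCount]:
    """Stochastic twin of the deterministic diploid/tetraploid recursion.

    Per generation: the number of failed diploid mitoses is
    Binomial(D, p) — each failure removes the two diploid daughters and adds
    one tetraploid; each tetraploid completes its division with probability
    2**rho - 1, matching the deterministic 2**rho growth factor in
    expectation.  Returns integer karyotype counts per generation,
    reproducible under a fixed seed.
    """
    if n0_diploid < 0 or n0_tetraploid < 0 or generations < 0:
        raise ParameterError("counts and generations must be non-negative")
    rng = np.random.default_rng(seed)
    d, t = int(n0_diploid), int(n0_tetraploid)
    out = [KaryotypeCount(timepoint="gen0", n_metaphases=d + t, n_tetraploid=t)]
    for g in range(1, generations + 1):
        failures = int(rng.binomial(d, model.p)) if d > 0 else 0
        tetra_divisions = (
            int(rng.binomial(t, model.tetraploid_factor - 1.0)) if t > 0 else 0
        )
        d = 2 * (d - failures)
        t = t + tetra_divisions + failures
        out.append(KaryotypeCount(timepoint=f"gen{g}", n_metaphases=d + t, n_tetraploid=t))
    return out
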