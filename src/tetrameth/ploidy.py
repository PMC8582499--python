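"""Diploid/tetraploid population dynamics of spontaneous tetraploidization.

A near-diploid cell can fail cytokinesis during mitosis and collapse its two
daughter genomes into a single near-tetraploid cell.  The model tracks the two
subpopulations over diploid generations:

* each diploid mitosis fails with probability ``p``, consuming the mitosis and
  yielding exactly one tetraploid cell, so diploids multiply by ``2(1-p)`` per
  generation;
* tetraploids are stable (no reversion) but proliferate slower, completing
  ``rho`` divisions per diploid generation, i.e. they multiply by ``2**rho``.

When diploids outgrow tetraploids (``2(1-p) > 2**rho``) the tetraploid
*fraction* converges to an interior fixed point; otherwise tetraploids take
over.  ``TetraploidGrowthModel`` inverts the recursion against two observed
karyotype counts to estimate ``p`` with a parametric-bootstrap confidence
interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError, ParameterError, TetraploidTakeover

__all__ = [
    "PloidyModel",
    "PopulationState",
    "KaryotypeCount",
    "step",
    "iterate",
    "steady_state_fraction",
    "TetraploidGrowthModel",
    "TetraploidGrowthResults",
    "estimate_rate",
    "karyotype_change_test",
    "days_to_generations",
]


@dataclass(frozen=True)
class PloidyModel:
    """Two-type growth parameters.

    Parameters
    ----------
    p : float
        Probability that a diploid mitosis fails cytokinesis and produces one
        tetraploid cell, per mitosis, in [0, 1].
    rho : float
        Relative tetraploid proliferation rate: tetraploid divisions per
        diploid generation, in (0, 1].  Tetraploids multiply by ``2**rho``
        per diploid generation.
    """

    p: float
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ParameterError(f"p must be in [0, 1], got {self.p}")
        if not (0.0 < self.rho <= 1.0):
            raise ParameterError(f"rho must be in (0, 1], got {self.rho}")

    @property
    def diploid_factor(self) -> float:
        return 2.0 * (1.0 - self.p)

    @property
    def tetraploid_factor(self) -> float:
        return 2.0 ** self.rho


@dataclass
class PopulationState:
    """Diploid/tetraploid abundances at a generation (continuous scale)."""

    generation: int
    n_diploid: float
    n_tetraploid: float

    def __post_init__(self) -> None:
        if self.n_diploid < 0 or self.n_tetraploid < 0:
            raise ParameterError("abundances must be non-negative")

    @property
    def tetraploid_fraction(self) -> float:
        total = self.n_diploid + self.n_tetraploid
        if total == 0:
            raise DataError("empty population has no tetraploid fraction")
        return self.n_tetraploid / total


@dataclass(frozen=True)
class KaryotypeCount:
    """Metaphase spread counts at one timepoint."""

    timepoint: str
    n_metaphases: int
    n_tetraploid: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_tetraploid <= self.n_metaphases):
            raise ParameterError(
                "need 0 <= n_tetraploid <= n_metaphases, got "
                f"{self.n_tetraploid}/{self.n_metaphases}"
            )
        if self.n_metaphases == 0:
            raise ParameterError("n_metaphases must be positive")

    @property
    def fraction(self) -> float:
        return self.n_tetraploid / self.n_metaphases


def step(state: PopulationState, model: PloidyModel) -> PopulationState:
    """Advance the deterministic recursion by one diploid generation.

    D' = 2(1-p) D  (failed mitoses yield no diploid daughters)
    T' = 2**rho T + p D  (one new tetraploid per failed diploid mitosis)
    """
    d = model.diploid_factor * state.n_diploid
    t = model.tetraploid_factor * state.n_tetraploid + model.p * state.n_diploid
    return PopulationState(state.generation + 1, d, t)


def iterate(
    state: PopulationState, model: PloidyModel, generations: int, normalize: bool = True
) -> list[PopulationState]:
    """Run `step` for `generations` generations, returning every state.

    With ``normalize`` the abundances are rescaled to sum to 1 each generation
    (the fraction dynamics are invariant to rescaling), which avoids overflow
    over long horizons.
    """
    states = [state]
    cur = state
    for _ in range(generations):
        cur = step(cur, model)
        if normalize:
            total = cur.n_diploid + cur.n_tetraploid
            cur = PopulationState(cur.generation, cur.n_diploid / total, cur.n_tetraploid / total)
        states.append(cur)
    return states


def _forward_fraction(f0: float, p: float, rho: float, generations: int) -> float:
    """Tetraploid fraction after iterating the recursion from fraction f0."""
    d, t = 1.0 - f0, f0
    df = 2.0 * (1.0 - p)
    tf = 2.0 ** rho
    for _ in range(generations):
        d, t = df * d, tf * t + p * d
        s = d + t
        d, t = d / s, t / s
    return t


def steady_state_fraction(model: PloidyModel) -> float:
    """Equilibrium tetraploid fraction of the deterministic recursion.

    The tetraploid/diploid ratio x obeys x' = (2**rho x + p) / (2(1-p)),
    with fixed point x* = p / (2(1-p) - 2**rho) when diploids outgrow
    tetraploids; the fraction is x*/(1+x*).

    Raises
    ------
    TetraploidTakeover
        When 2(1-p) <= 2**rho, in which case the tetraploid fraction tends
        to 1 and no interior equilibrium exists.
    """
    gap = model.diploid_factor - model.tetraploid_factor
    if gap <= 0:
        raise TetraploidTakeover(
            f"2(1-p)={model.diploid_factor:.4f} <= 2^rho={model.tetraploid_factor:.4f}: "
            "tetraploids take over; no interior steady state"
        )
    if model.p == 0:
        return 0.0
    x = model.p / gap
    return x / (1.0 + x)


@dataclass
class TetraploidGrowthResults:
    """Estimation results for the per-mitosis tetraploidization rate."""

    p_hat: float
    ci_low: float
    ci_high: float
    rho: float
    generations: int
    observed: tuple[KaryotypeCount, KaryotypeCount]
    n_boot: int
    bootstrap_estimates: np.ndarray = field(repr=False)

    @property
    def steady_state(self) -> float:
        """Equilibrium tetraploid fraction implied by the point estimate."""
        return steady_state_fraction(PloidyModel(self.p_hat, self.rho))

    @property
    def mitoses_per_event(self) -> float:
        """1/p_hat: one tetraploidization per this many diploid mitoses."""
        return math.inf if self.p_hat == 0 else 1.0 / self.p_hat

    def summary(self) -> str:
        o0, o1 = self.observed
        lines = [
            "Tetraploidization rate estimate (two-type growth model)",
            "=" * 56,
            f"observed: {o0.n_tetraploid}/{o0.n_metaphases} ({100*o0.fraction:.1f}%) -> "
            f"{o1.n_tetraploid}/{o1.n_metaphases} ({100*o1.fraction:.1f}%) "
            f"over {self.generations} generations",
            f"relative tetraploid proliferation rho = {self.rho}",
            f"p_hat = {self.p_hat:.4f}  ({100*self.p_hat:.2f}% of mitoses, "
            f"~1 in {self.mitoses_per_event:.0f})",
            f"95% bootstrap CI: [{self.ci_low:.4f}, {self.ci_high:.4f}]  "
            f"(n_boot={self.n_boot})",
            f"implied equilibrium tetraploid fraction: {100*self.steady_state:.1f}%",
        ]
        return "\n".join(lines)


class TetraploidGrowthModel:
    """Estimate the per-mitosis tetraploidization probability from two
    karyotype counts separated by a known number of diploid generations.

    Parameters
    ----------
    observed : pair of KaryotypeCount
        Counts at the first and second timepoint.
    generations : int
        Diploid generations elapsed between the two counts.
    rho : float
        Relative tetraploid proliferation rate (fixed, not estimated).
    """

    P_BOUNDS = (0.0, 0.5)
    TOL = 1e-8

    def __init__(
        self,
        observed: Sequence[KaryotypeCount],
        generations: int,
        rho: float = 0.8,
    ) -> None:
        if len(observed) != 2:
            raise DataError("exactly two karyotype counts are required")
        if generations < 1:
            raise ParameterError("generations_between must be >= 1")
        PloidyModel(0.0, rho)  # validates rho
        self.observed = (observed[0], observed[1])
        self.generations = int(generations)
        self.rho = float(rho)

    def _solve(self, f0: float, f1: float) -> float:
        """Bisection for p with forward fraction matching f1; clipped to bounds."""
        lo, hi = self.P_BOUNDS

        def resid(p: float) -> float:
            return _forward_fraction(f0, p, self.rho, self.generations) - f1

        r_lo, r_hi = resid(lo), resid(hi)
        if r_lo >= 0:  # target at or below what p=0 already yields
            return lo
        if r_hi <= 0:
            return hi
        while hi - lo > self.TOL:
            mid = 0.5 * (lo + hi)
            if resid(mid) < 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def fit(self, n_boot: int = 1000, seed: int | None = 0) -> TetraploidGrowthResults:
        """Point estimate by bisection; CI by parametric bootstrap of the
        binomial karyotype sampling at both timepoints."""
        o0, o1 = self.observed
        f0, f1 = o0.fraction, o1.fraction
        if f1 <= f0:
            raise DataError(
                "second timepoint fraction must exceed the first "
                f"({f1:.3f} <= {f0:.3f})"
            )
        p_hat = self._solve(f0, f1)
        if p_hat >= self.P_BOUNDS[1]:
            raise DataError("no solution for p in [0, 0.5]")

        rng = np.random.default_rng(seed)
        # resample counts from the fitted trajectory's true fractions
        fit_f1 = _forward_fraction(f0, p_hat, self.rho, self.generations)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            k0 = rng.binomial(o0.n_metaphases, f0)
            k1 = rng.binomial(o1.n_metaphases, fit_f1)
            bf0 = k0 / o0.n_metaphases
            bf1 = k1 / o1.n_metaphases
            boots[b] = self._solve(bf0, bf1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return TetraploidGrowthResults(
            p_hat=p_hat,
            ci_low=float(lo),
            ci_high=float(hi),
            rho=self.rho,
            generations=self.generations,
            observed=self.observed,
            n_boot=n_boot,
            bootstrap_estimates=boots,
        )


def estimate_rate(
    observed: Sequence[KaryotypeCount],
    generations_between: int,
    rho: float = 0.8,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> TetraploidGrowthResults:
    """Functional wrapper around :class:`TetraploidGrowthModel`."""
    return TetraploidGrowthModel(observed, generations_between, rho).fit(
        n_boot=n_boot, seed=seed
    )


def karyotype_change_test(first: KaryotypeCount, second: KaryotypeCount) -> float:
    """Two-sided Fisher exact test for a change in tetraploid fraction."""
    from .cohort import fisher_exact

    return fisher_exact(
        [
            [first.n_tetraploid, first.n_metaphases - first.n_tetraploid],
            [second.n_tetraploid, second.n_metaphases - second.n_tetraploid],
        ]
    )


def days_to_generations(days: float, doubling_time_hours: float) -> int:
    """Whole diploid generations elapsed in `days` of culture."""
    if days < 0:
        raise ParameterError("days must be non-negative")
    if doubling_time_hours <= 0:
        raise ParameterError("doubling time must be positive")
    return int(math.floor(24.0 * days / doubling_time_hours))
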