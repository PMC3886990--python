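"""Imperfect-sorting analysis: contaminated initial conditions and
simulated-annealing fits of the hierarchy-only model.

Flow sorting is never perfect: a nominally pure population carries about
``theta`` percent of the opposite phenotype.  The question is whether that
contamination alone — with no NSCC->CSC transition (K_T = 0) — can explain
the observed return of sorted cultures to the equilibrium CSC proportion.
The test: fit the free parameters (K_C, K_N, e) by simulated annealing to
the sorted-CSC proportion time course with K_T fixed at 0, then evaluate
every accepted combination on the sorted-NSCC time course.  If none fits the
NSCC data within threshold, contamination cannot rescue the hierarchy-only
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import PopulationState, propagate
from .params import DivisionProbabilities, KineticParameters, ParameterError


@dataclass(frozen=True)
class SortingScenario:
    """A nominally pure sorted population with ``error_theta`` percent
    contamination of the opposite phenotype."""

    nominal_type: str  # "CSC" | "NSCC"
    total_cells: float = 1000.0
    error_theta: float = 2.0

    def __post_init__(self) -> None:
        if self.nominal_type not in ("CSC", "NSCC"):
            raise ParameterError("nominal_type must be 'CSC' or 'NSCC'")
        if not (0.0 <= self.error_theta <= 100.0):
            raise ParameterError("error_theta must lie in [0, 100]")
        if self.total_cells <= 0:
            raise ParameterError("total_cells must be positive")


def apply_sorting_error(scenario: SortingScenario,
                        lifespan_generations: int = 50) -> PopulationState:
    """Initial state with theta percent of the opposite phenotype.

    All NSCCs (nominal or contaminating) start in generation 1.
    """
    frac = scenario.error_theta / 100.0
    n_minor = scenario.total_cells * frac
    n_major = scenario.total_cells - n_minor
    counts = np.zeros(lifespan_generations)
    if scenario.nominal_type == "CSC":
        csc, counts[0] = n_major, n_minor
    else:
        csc, counts[0] = n_minor, n_major
    return PopulationState(0.0, csc, counts)


@dataclass
class AnnealSchedule:
    """Geometric-cooling Metropolis schedule for the (K_C, K_N, e) search."""

    n_proposals: int = 10000
    cooling_factor: float = 0.95
    cool_every: int = 50
    initial_temperature: float | None = None  # default: objective at the start point
    proposal_scale_frac: float = 0.05  # Gaussian step, fraction of bound width
    threshold_sigma: float = 0.03  # assumed proportion measurement noise
    threshold: float | None = None  # override: absolute objective threshold
    bounds: tuple = ((1e-6, 3.0), (1e-6, 3.0), (-1.0, 1.0))  # K_C, K_N, e

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling_factor < 1.0):
            raise ParameterError("cooling_factor must lie in (0, 1)")
        if self.n_proposals < 1 or self.cool_every < 1:
            raise ParameterError("n_proposals and cool_every must be >= 1")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ParameterError("each bound must satisfy lo < hi")
        if len(self.bounds) == 3:
            (lo_c, _), (lo_n, _), (lo_e, hi_e) = self.bounds
            if lo_c <= 0 or lo_n <= 0 or lo_e < -1 or hi_e > 1:
                raise ParameterError("bounds must keep rates positive and e in [-1, 1]")

    def threshold_for(self, n_points: int) -> float:
        """Acceptance threshold: the expected pure-noise objective
        ``n_points * sigma^2`` unless overridden."""
        return self.threshold if self.threshold is not None else (
            n_points * self.threshold_sigma ** 2)


@dataclass
class FitResult:
    k_csc_mitosis: float
    k_nscc_division: float
    e_effective: float
    objective: float
    accepted: bool
    anneal_seed: int

    def as_params(self, k_transition: float = 0.0, lifespan_generations: int = 50,
                  senescent_death_rate: float = 1.0) -> KineticParameters:
        return KineticParameters(
            division_probs=DivisionProbabilities.from_e(self.e_effective),
            k_transition=k_transition,
            k_nscc_division=self.k_nscc_division,
            k_csc_mitosis=self.k_csc_mitosis,
            lifespan_generations=lifespan_generations,
            senescent_death_rate=senescent_death_rate,
        )


def objective(candidate: Sequence[float], times: np.ndarray, data: np.ndarray,
              initial: PopulationState, k_transition: float = 0.0,
              lifespan_generations: int = 50,
              senescent_death_rate: float = 1.0) -> float:
    """Sum of squared proportion residuals of a (K_C, K_N, e) candidate."""
    k_c, k_n, e = candidate
    params = KineticParameters(
        division_probs=DivisionProbabilities.from_e(e),
        k_transition=k_transition, k_nscc_division=k_n, k_csc_mitosis=k_c,
        lifespan_generations=lifespan_generations,
        senescent_death_rate=senescent_death_rate,
    )
    times = np.asarray(times, dtype=float)
    data = np.asarray(data, dtype=float)
    if times.size != data.size or times.size == 0:
        raise ParameterError("times and data must be equal-length and non-empty")
    ts = times if times[0] <= initial.time + 1e-12 else np.concatenate(
        ([initial.time], times))
    states = propagate(params, initial.to_vector(), ts)[-times.size:]
    props = states[:, 0] / states.sum(axis=1)
    return float(np.sum((props - data) ** 2))


def _anneal(fn: Callable[[np.ndarray], float], bounds: np.ndarray,
            schedule: AnnealSchedule, rng: np.random.Generator
            ) -> tuple[float, np.ndarray]:
    """Generic Metropolis annealer; returns (best objective, best point)."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    scales = schedule.proposal_scale_frac * (hi - lo)
    x = lo + rng.random(bounds.shape[0]) * (hi - lo)
    f = fn(x)
    best_f, best_x = f, x.copy()
    temp = schedule.initial_temperature if schedule.initial_temperature is not None \
        else max(f, 1e-12)
    for i in range(schedule.n_proposals):
        y = x + rng.normal(0.0, scales)
        if np.any(y < lo) or np.any(y > hi):
            continue  # out-of-bounds proposals are rejected outright
        g = fn(y)
        if g < f or rng.random() < math.exp(-(g - f) / max(temp, 1e-300)):
            x, f = y, g
            if f < best_f:
                best_f, best_x = f, x.copy()
        if (i + 1) % schedule.cool_every == 0:
            temp *= schedule.cooling_factor
    return best_f, best_x


def simulated_annealing_fit(times: Sequence[float], data: Sequence[float],
                            scenario: SortingScenario,
                            schedule: AnnealSchedule | None = None,
                            n_fits: int = 50, seed: int = 0,
                            k_transition: float = 0.0,
                            lifespan_generations: int = 50,
                            senescent_death_rate: float = 1.0) -> list[FitResult]:
    """Run ``n_fits`` independent annealing chains on a proportion time course.

    Each chain starts from a random point inside the bounds, accepts worse
    moves with probability exp(-delta/T), and cools geometrically.  A chain's
    best point is flagged ``accepted`` when its objective falls below the
    schedule threshold.
    """
    if n_fits < 1:
        raise ParameterError("n_fits must be >= 1")
    schedule = schedule or AnnealSchedule()
    times = np.asarray(times, dtype=float)
    data = np.asarray(data, dtype=float)
    initial = apply_sorting_error(scenario, lifespan_generations)
    thr = schedule.threshold_for(times.size)
    bounds = np.asarray(schedule.bounds, dtype=float)

    def fn(x: np.ndarray) -> float:
        return objective(x, times, data, initial, k_transition,
                         lifespan_generations, senescent_death_rate)

    results = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_fits)):
        rng = np.random.default_rng(child)
        best_f, best_x = _anneal(fn, bounds, schedule, rng)
        results.append(FitResult(
            k_csc_mitosis=float(best_x[0]), k_nscc_division=float(best_x[1]),
            e_effective=float(best_x[2]), objective=best_f,
            accepted=best_f < thr, anneal_seed=i,
        ))
    return results


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "k_csc_mitosis": f.k_csc_mitosis, "k_nscc_division": f.k_nscc_division,
        "e_effective": f.e_effective, "objective": f.objective,
        "accepted": f.accepted, "anneal_seed": f.anneal_seed,
    } for f in fits])


def cross_evaluate(fits: Sequence[FitResult], times: Sequence[float],
                   nscc_data: Sequence[float], scenario: SortingScenario,
                   threshold: float, factor: float = 1.0,
                   k_transition: float = 0.0, lifespan_generations: int = 50,
                   senescent_death_rate: float = 1.0
                   ) -> tuple[pd.DataFrame, str]:
    """Evaluate accepted CSC-data fits on the sorted-NSCC time course.

    Returns the per-fit objectives and the verdict:
    ``hierarchy-insufficient`` when even the best accepted combination misses
    the NSCC data by more than ``factor`` times the threshold, else
    ``hierarchy-adequate``.
    """
    accepted = [f for f in fits if f.accepted]
    if not accepted:
        raise ParameterError("no accepted fits to cross-evaluate")
    initial = apply_sorting_error(scenario, lifespan_generations)
    rows = []
    for f in accepted:
        obj = objective((f.k_csc_mitosis, f.k_nscc_division, f.e_effective),
                        np.asarray(times, float), np.asarray(nscc_data, float),
                        initial, k_transition, lifespan_generations,
                        senescent_death_rate)
        rows.append({"anneal_seed": f.anneal_seed, "csc_objective": f.objective,
                     "nscc_objective": obj})
    table = pd.DataFrame(rows)
    verdict = ("hierarchy-insufficient"
               if table["nscc_objective"].min() > factor * threshold
               else "hierarchy-adequate")
    return table, verdict
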