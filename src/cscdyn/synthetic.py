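"""Synthetic experimental data with known ground truth.

Emulates the three kinds of measurements the analysis pipeline consumes:

* scored division events (trinomial draws over self-renewal / asymmetric /
  differentiation) from which the division probabilities are re-estimated;
* one-day sorted-population counts (pure CSC or pure NSCC cultures grown for
  one day) from which the rates K_C, K_N and K_T are re-estimated;
* noisy CSC-proportion time courses from sorted or mixed initial conditions,
  optionally irradiated, standing in for flow-cytometry monitoring data.

All generators take a seed (or generator) and are deterministic under it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import PopulationState, csc_proportion, propagate
from .params import DivisionProbabilities, KineticParameters, ParameterError
from .radiation import RadiationParameters, integrate_irradiated


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class DivisionEventCounts:
    """Scored CSC division events and plug-in probability estimates."""

    n_observed: int
    n_self_renewal: int
    n_asymmetric: int
    n_differentiation: int

    def __post_init__(self) -> None:
        counts = (self.n_self_renewal, self.n_asymmetric, self.n_differentiation)
        if any(c < 0 for c in counts) or sum(counts) != self.n_observed:
            raise ParameterError("division event counts must be >= 0 and sum to n_observed")

    def estimates(self) -> pd.DataFrame:
        """Plug-in frequencies with binomial standard errors."""
        n = self.n_observed
        rows = []
        for name, c in (("P_S", self.n_self_renewal), ("P_A", self.n_asymmetric),
                        ("P_D", self.n_differentiation)):
            p = c / n
            rows.append((name, p, math.sqrt(p * (1 - p) / n)))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "standard_error"])

    def estimated_probs(self) -> DivisionProbabilities:
        n = self.n_observed
        return DivisionProbabilities(self.n_self_renewal / n, self.n_asymmetric / n,
                                     self.n_differentiation / n)


def sample_division_events(probs: DivisionProbabilities, n: int,
                           seed=None) -> DivisionEventCounts:
    """Trinomial draw of ``n`` scored CSC divisions."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = _rng(seed)
    c = rng.multinomial(n, [probs.p_self_renewal, probs.p_asymmetric,
                            probs.p_differentiation])
    return DivisionEventCounts(n, int(c[0]), int(c[1]), int(c[2]))


@dataclass
class OneDayCounts:
    """Day-0 and day-1 totals of a sorted culture, plus (for NSCC sorts) the
    fraction of the lineage that transitioned to the CSC state within the day."""

    sorted_type: str  # "CSC" | "NSCC"
    count_day0: float
    count_day1_total: float
    transitioned_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.sorted_type not in ("CSC", "NSCC"):
            raise ParameterError("sorted_type must be 'CSC' or 'NSCC'")
        if self.count_day0 <= 0 or self.count_day1_total <= 0:
            raise ParameterError("counts must be positive")
        if self.transitioned_fraction is not None and not (
                0.0 <= self.transitioned_fraction <= 1.0):
            raise ParameterError("transitioned_fraction must lie in [0, 1]")


def simulate_one_day_counts(params: KineticParameters, sorted_type: str,
                            n0: int = 1000, seed=None,
                            observation_noise: bool = False) -> OneDayCounts:
    """Grow a pure sorted population for one day under the full model.

    The transitioned fraction reported for NSCC sorts is the fraction of
    lineage mass removed by the NSCC->CSC conversion over the day.  Because
    conversion acts as a uniform per-capita sink on the NSCC cascade, this
    fraction is exactly ``1 - exp(-K_T * 1 day)`` regardless of division and
    senescence.  With ``observation_noise`` the day-1 total is Poisson and
    the transitioned fraction a binomial frequency over ``n0`` tracked cells.
    """
    if n0 < 1:
        raise ParameterError("n0 must be >= 1")
    rng = _rng(seed)
    m = params.lifespan_generations
    if sorted_type == "CSC":
        x0 = PopulationState.pure_csc(n0, m)
    elif sorted_type == "NSCC":
        x0 = PopulationState.pure_nscc(n0, m)
    else:
        raise ParameterError("sorted_type must be 'CSC' or 'NSCC'")
    total1 = float(propagate(params, x0.to_vector(), np.array([0.0, 1.0]))[-1].sum())
    frac = None
    if sorted_type == "NSCC":
        frac = -math.expm1(-params.k_transition)
    if observation_noise:
        total1 = float(rng.poisson(total1))
        total1 = max(total1, 1.0)
        if frac is not None:
            frac = rng.binomial(n0, frac) / n0
    return OneDayCounts(sorted_type, float(n0), total1, frac)


@dataclass
class RateEstimates:
    k_transition: float
    k_nscc_division: float
    k_csc_mitosis: float


def estimate_rates_one_day(csc_obs: OneDayCounts, nscc_obs: OneDayCounts,
                           naive_transition: bool = False) -> RateEstimates:
    """One-day rate estimators for K_C, K_N and K_T.

    K_C = ln(total_1 / C_0) from the CSC sort and K_N = ln(total_1 / N_0)
    from the NSCC sort — exact when divisions of the newly produced opposite
    phenotype within the day are neglected.  The transition rate inverts the
    exponential waiting time, K_T = -ln(1 - f); pass ``naive_transition`` to
    use the small-rate reading K_T = f instead.
    """
    if csc_obs.sorted_type != "CSC" or nscc_obs.sorted_type != "NSCC":
        raise ParameterError("expected one CSC-sort and one NSCC-sort observation")
    if nscc_obs.transitioned_fraction is None:
        raise ParameterError("NSCC observation lacks a transitioned fraction")
    f = nscc_obs.transitioned_fraction
    if f >= 1.0:
        raise ParameterError("transitioned_fraction must be < 1 for rate inversion")
    return RateEstimates(
        k_transition=f if naive_transition else -math.log(1.0 - f),
        k_nscc_division=math.log(nscc_obs.count_day1_total / nscc_obs.count_day0),
        k_csc_mitosis=math.log(csc_obs.count_day1_total / csc_obs.count_day0),
    )


@dataclass
class SyntheticTimeCourse:
    """Noisy CSC-proportion time course with its generating truth attached."""

    times: np.ndarray
    observed_proportions: np.ndarray
    true_proportions: np.ndarray
    initial: PopulationState
    params: KineticParameters
    noise_sigma: float
    seed: object = None
    radiation: RadiationParameters | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_days": self.times,
            "csc_proportion": self.observed_proportions,
            "true_proportion": self.true_proportions,
        })


def generate_time_course(params: KineticParameters, initial: PopulationState,
                         sample_times: Sequence[float], noise_sigma: float = 0.02,
                         seed=None, radiation: RadiationParameters | None = None,
                         noise_model: str = "gaussian",
                         n_scored: int = 300) -> SyntheticTimeCourse:
    """Sample the model's CSC proportion at the given times with noise.

    ``noise_model='gaussian'`` adds independent N(0, sigma^2) errors clipped
    to [0, 1]; ``'binomial'`` instead scores ``n_scored`` cells per time point
    (a closer emulation of flow-cytometry counting).  A
    :class:`RadiationParameters` object applies a pulse at the initial time.
    """
    times = np.asarray(sample_times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise ParameterError("sample_times must be strictly increasing")
    rng = _rng(seed)
    if radiation is None:
        states = propagate(params, initial.to_vector(),
                           np.concatenate(([initial.time], times))
                           if times[0] > initial.time else times)
        states = states[-times.size:]
        true_props = states[:, 0] / states.sum(axis=1)
    else:
        traj = integrate_irradiated(params, radiation, initial,
                                    t_end=float(times[-1]), dt_out=0.05)
        true_props = np.interp(times, traj.times, traj.proportions)
    if noise_model == "gaussian":
        observed = np.clip(true_props + rng.normal(0.0, noise_sigma, times.size), 0.0, 1.0)
    elif noise_model == "binomial":
        observed = rng.binomial(n_scored, true_props) / n_scored
    else:
        raise ParameterError(f"unknown noise_model {noise_model!r}")
    return SyntheticTimeCourse(times, observed, true_props, initial, params,
                               noise_sigma, seed, radiation)
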