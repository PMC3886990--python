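"""Equilibrium CSC proportion: reduced phase portrait, full-model limit,
and parameter sensitivity.

The proportion ``R = C / (C + sum N_i)`` of a growing linear population obeys,
after dropping senescence (M -> infinity, d ignored), the scalar equation

    dR/dt = K_C e R + K_T (1 - R) - R [K_C R + K_N (1 - R)]

whose sign structure gives the 1-D phase portrait: with K_T > 0 the origin is
repelling (dR/dt = K_T at R = 0) so an interior stable equilibrium always
exists; with K_T = 0 a nonzero equilibrium requires K_C e > K_N, i.e. the net
CSC proliferation rate exceeding the NSCC one — the hierarchy-only regime.

The full-model equilibrium proportion is the composition of the dominant
eigenvector of the rate matrix (the population grows exponentially along it),
or equivalently the long-time limit of the integrated proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from dataclasses import replace
from scipy.optimize import brentq

from .model import PopulationState, propagate, rate_matrix
from .params import DivisionProbabilities, KineticParameters, ParameterError

_MERGE_TOL = 1e-6


class EquilibriumError(RuntimeError):
    """Equilibrium computation failed (non-convergence or loss of stability)."""


@dataclass(frozen=True)
class Equilibrium:
    proportion: float
    stability: str  # "stable" | "unstable" | "half-stable"


@dataclass
class EquilibriumReport:
    equilibria: list[Equilibrium]
    method: str

    @property
    def stable(self) -> list[float]:
        return [eq.proportion for eq in self.equilibria if eq.stability == "stable"]


def reduced_proportion_rate(r, params: KineticParameters):
    """dR/dt of the senescence-free two-compartment proportion reduction.

    Accepts a scalar or array of proportions in [0, 1].
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > 1):
        raise ParameterError("R must lie in [0, 1]")
    k_t, k_n, k_c = params.k_transition, params.k_nscc_division, params.k_csc_mitosis
    e = params.e
    growth = k_c * r_arr + k_n * (1.0 - r_arr)  # per-capita total growth
    rate = k_c * e * r_arr + k_t * (1.0 - r_arr) - r_arr * growth
    return rate if np.ndim(r) else float(rate)


def _classify(f_left: float, f_right: float) -> str:
    if f_left > 0 and f_right < 0:
        return "stable"
    if f_left < 0 and f_right > 0:
        return "unstable"
    return "half-stable"


def _reduced_analytic(params: KineticParameters, n_grid: int = 20001) -> EquilibriumReport:
    grid = np.linspace(0.0, 1.0, n_grid)
    f = reduced_proportion_rate(grid, params)
    roots: list[float] = []
    # interior sign changes
    for i in np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]:
        roots.append(brentq(lambda r: reduced_proportion_rate(r, params),
                            grid[i], grid[i + 1], xtol=1e-14))
    # exact zeros on the grid (boundary fixed points such as R = 0 when K_T = 0)
    for i in np.nonzero(f == 0.0)[0]:
        roots.append(float(grid[i]))
    roots.sort()
    merged: list[float] = []
    for r in roots:
        if not merged or r - merged[-1] > _MERGE_TOL:
            merged.append(r)
    eps = 1e-7
    equilibria = []
    for r in merged:
        f_left = reduced_proportion_rate(max(r - eps, 0.0), params) if r > 0 else 1.0
        f_right = reduced_proportion_rate(min(r + eps, 1.0), params) if r < 1 else -1.0
        # boundary roots: classify from the interior side only
        if r == 0.0:
            f_left = -reduced_proportion_rate(min(r + eps, 1.0), params)
        if r == 1.0:
            f_right = -reduced_proportion_rate(max(r - eps, 0.0), params)
        equilibria.append(Equilibrium(r, _classify(f_left, f_right)))
    return EquilibriumReport(equilibria, "reduced-analytic")


def equilibrium_proportion(params: KineticParameters) -> float:
    """Full-model equilibrium proportion from the dominant eigenvector.

    The rate matrix is Metzler (non-negative off-diagonals), so its dominant
    eigenvalue is real with a sign-constant eigenvector; the long-time
    population composition is that eigenvector normalized to total one.
    """
    w, v = np.linalg.eig(rate_matrix(params))
    i = int(np.argmax(w.real))
    vec = np.abs(v[:, i].real)
    s = vec.sum()
    if s <= 0:
        raise EquilibriumError("dominant eigenvector is degenerate")
    return float(vec[0] / s)


def _full_longtime(params: KineticParameters, initial: PopulationState | None,
                   t_max: float = 2000.0, dr_tol: float = 1e-10) -> EquilibriumReport:
    m = params.lifespan_generations
    if initial is None:
        initial = PopulationState.mixture(1.0, 0.5, m)
    x = initial.to_vector()
    step = 1.0  # days per convergence check
    r_prev = x[0] / x.sum() if x.sum() > 0 else 0.0
    t = 0.0
    from scipy.linalg import expm

    p = expm(rate_matrix(params) * step)
    while t < t_max:
        x = p @ x
        x /= x.sum()  # renormalize: proportions are scale-invariant
        t += step
        r = x[0]
        if abs(r - r_prev) < dr_tol * step:
            return EquilibriumReport([Equilibrium(float(r), "stable")],
                                     "full-ode-longtime")
        r_prev = r
    raise EquilibriumError(
        f"proportion did not converge to |dR| < {dr_tol}/day within t={t_max} days"
    )


def find_equilibrium_proportion(params: KineticParameters,
                                method: str = "reduced-analytic",
                                initial: PopulationState | None = None,
                                t_max: float = 2000.0) -> EquilibriumReport:
    """Locate equilibrium proportions and their stability.

    ``method`` is one of ``reduced-analytic`` (sign-change roots of the
    reduced dR/dt with stability from the local slope), ``full-ode-longtime``
    (integrate the full generation-structured model until |dR| per day falls
    below 1e-10), or ``full-eigen`` (dominant-eigenvector composition).
    """
    if method == "reduced-analytic":
        return _reduced_analytic(params)
    if method == "full-ode-longtime":
        return _full_longtime(params, initial, t_max=t_max)
    if method == "full-eigen":
        return EquilibriumReport([Equilibrium(equilibrium_proportion(params), "stable")],
                                 "full-eigen")
    raise ValueError(f"unknown method {method!r}")


def _perturbed(params: KineticParameters, name: str, factor: float) -> KineticParameters:
    if name == "e":
        return replace(params, division_probs=DivisionProbabilities.from_e(params.e * factor))
    field_name = {"K_T": "k_transition", "K_N": "k_nscc_division",
                  "K_C": "k_csc_mitosis"}[name]
    return replace(params, **{field_name: getattr(params, field_name) * factor})


def sensitivity_analysis(params: KineticParameters = KineticParameters(),
                         perturbation: float = 0.01) -> pd.DataFrame:
    """Percent change of the equilibrium proportion under small parameter moves.

    Each of K_T, K_N, K_C and e is scaled by ``1 +/- perturbation`` (the
    composite e is moved holding K_C fixed); the integer lifespan M is moved
    by +/- 1.  Rows report ``100 * (R*_perturbed - R*_baseline) / R*_baseline``
    on the full M-generation model.
    """
    r0 = equilibrium_proportion(params)
    if r0 <= 0:
        raise EquilibriumError("baseline has no positive stable equilibrium proportion")
    rows = []
    for name in ("K_T", "K_N", "K_C", "e"):
        for sign, label in ((+1, f"+{perturbation:.0%}"), (-1, f"-{perturbation:.0%}")):
            r = equilibrium_proportion(_perturbed(params, name, 1.0 + sign * perturbation))
            rows.append((name, label, 100.0 * (r - r0) / r0))
    for dm, label in ((+1, "M+1"), (-1, "M-1")):
        m = params.lifespan_generations + dm
        if m >= 1:
            r = equilibrium_proportion(replace(params, lifespan_generations=m))
            rows.append(("M", label, 100.0 * (r - r0) / r0))
    return pd.DataFrame(rows, columns=["parameter", "direction", "percent_change"])
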