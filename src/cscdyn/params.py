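"""Parameter containers for the CSC/NSCC interconversion model.

The model describes two phenotypes in a tumor cell population: cancer stem
cells (CSCs), which self-renew, differentiate, or divide asymmetrically, and
non-stem cancer cells (NSCCs), which proliferate for a limited number of
generations, senesce, and can stochastically convert back to the CSC state.

All rates are per day; time is measured in days throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class ParameterError(ValueError):
    """A parameter set violates one of its invariants."""


_PROB_TOL = 1e-9


@dataclass(frozen=True)
class DivisionProbabilities:
    """Probabilities of the three CSC division types.

    ``p_self_renewal``  — a CSC divides into two CSCs,
    ``p_asymmetric``    — a CSC divides into one CSC and one NSCC,
    ``p_differentiation`` — a CSC divides into two NSCCs.

    The three probabilities must sum to one.  The population dynamics depend
    on them only through the composite ``e = p_self_renewal -
    p_differentiation`` (the expected net CSC gain per CSC division, minus
    one).
    """

    p_self_renewal: float = 0.777
    p_asymmetric: float = 0.164
    p_differentiation: float = 0.059

    def __post_init__(self) -> None:
        probs = (self.p_self_renewal, self.p_asymmetric, self.p_differentiation)
        for name, p in zip(("p_self_renewal", "p_asymmetric", "p_differentiation"), probs):
            if not (0.0 <= p <= 1.0) or not math.isfinite(p):
                raise ParameterError(f"{name}={p!r} must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > _PROB_TOL:
            raise ParameterError(
                f"division probabilities must sum to 1 (got {sum(probs)!r})"
            )

    @property
    def e(self) -> float:
        return self.p_self_renewal - self.p_differentiation

    @classmethod
    def from_e(cls, e: float) -> "DivisionProbabilities":
        """A representative triple with the given composite ``e``.

        Used when only ``e`` matters (fitting, sensitivity perturbation);
        sets the asymmetric probability to zero so the pair
        ((1+e)/2, 0, (1-e)/2) realizes any e in [-1, 1].
        """
        if not -1.0 <= e <= 1.0:
            raise ParameterError(f"e={e!r} must lie in [-1, 1]")
        return cls(
            p_self_renewal=(1.0 + e) / 2.0,
            p_asymmetric=0.0,
            p_differentiation=(1.0 - e) / 2.0,
        )


def effective_e(probs: DivisionProbabilities) -> float:
    """Composite division parameter ``e = P_S - P_D``.

    This is the only combination of the three division probabilities that
    enters the deterministic dynamics: per CSC mitosis the expected change in
    CSC count is ``e`` and in generation-1 NSCC count is ``1 - e``.
    """
    return probs.e


@dataclass(frozen=True)
class KineticParameters:
    """Full kinetic parameterization of the interconversion model.

    Defaults are the in-situ measured values for the SW620 colon cancer line:
    division probabilities (0.777, 0.164, 0.059), NSCC-to-CSC transition rate
    ``k_transition`` = 0.269/day, NSCC proliferation rate ``k_nscc_division``
    = 0.659/day, CSC mitosis rate ``k_csc_mitosis`` = 0.849/day, NSCC
    generational lifespan ``lifespan_generations`` = 50 with senescent death
    rate ``senescent_death_rate`` = 1/day.
    """

    division_probs: DivisionProbabilities = field(default_factory=DivisionProbabilities)
    k_transition: float = 0.269
    k_nscc_division: float = 0.659
    k_csc_mitosis: float = 0.849
    lifespan_generations: int = 50
    senescent_death_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_transition", "k_nscc_division", "k_csc_mitosis",
                     "senescent_death_rate"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name}={v!r} must be a finite rate >= 0")
        m = self.lifespan_generations
        if not isinstance(m, int) or m < 1:
            raise ParameterError(f"lifespan_generations={m!r} must be an integer >= 1")

    @property
    def e(self) -> float:
        return self.division_probs.e


@dataclass(frozen=True)
class RadiationParameters:
    """Radiation-response parameters (DSB kinetics and survival).

    A dose ``dose`` (Gy) instantaneously induces ``dsb_per_gy * dose`` DNA
    double-strand breaks per cell, which are repaired exponentially at rate
    ``repair_rate_csc`` / ``repair_rate_nscc`` (per day).  Lethal mis-repair
    of DSB pairs kills cells at hazard ``m * U(t)^2 / 2``.  Survival
    fractions are the measured per-2-Gy clonogenic survivals used to
    calibrate the mis-repair coefficients.

    Defaults: k=25/Gy, D=2 Gy, r_C=15/day, r_N=10/day, S_C=0.95, S_N=0.43,
    m_C=0.0012, m_N=0.0092 (per day per DSB pair).
    """

    dsb_per_gy: float = 25.0
    dose: float = 2.0
    repair_rate_csc: float = 15.0
    repair_rate_nscc: float = 10.0
    misrepair_csc: float = 0.0012
    misrepair_nscc: float = 0.0092
    survival_csc: float = 0.95
    survival_nscc: float = 0.43

    def __post_init__(self) -> None:
        for name in ("dsb_per_gy", "dose", "repair_rate_csc", "repair_rate_nscc",
                     "misrepair_csc", "misrepair_nscc"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ParameterError(f"{name}={v!r} must be finite and >= 0")
        for name in ("survival_csc", "survival_nscc"):
            s = getattr(self, name)
            if not (0.0 < s <= 1.0):
                raise ParameterError(f"{name}={s!r} must lie in (0, 1]")


DEFAULT_KINETICS = KineticParameters()
DEFAULT_RADIATION = RadiationParameters()
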