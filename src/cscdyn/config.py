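"""Structured run configuration.

YAML config with four optional sections — ``kinetics``, ``radiation``,
``automaton`` and ``anneal`` — plus top-level ``output_dir``, ``seed`` and
``log_level``.  Every key defaults to the measured baseline values, so an
empty file reproduces the default scenario; unknown keys are rejected and
all validation failures are reported together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fitting import AnnealSchedule
from .params import (DivisionProbabilities, KineticParameters, ParameterError,
                     RadiationParameters)


class ConfigError(ValueError):
    """One or more configuration problems; the message lists all of them."""


_KINETIC_KEYS = {"P_S", "P_A", "P_D", "K_T", "K_N", "K_C", "M", "d"}
_RADIATION_KEYS = {"k", "D", "r_C", "r_N", "m_C", "m_N", "S_C", "S_N"}
_AUTOMATON_KEYS = {"rows", "cols", "dt", "seed"}
_ANNEAL_KEYS = {"n_proposals", "cooling_factor", "cool_every",
                "initial_temperature", "proposal_scale_frac",
                "threshold_sigma", "threshold"}
_TOP_KEYS = {"kinetics", "radiation", "automaton", "anneal",
             "output_dir", "seed", "log_level"}


@dataclass
class AutomatonSettings:
    rows: int = 200
    cols: int = 200
    dt: float = 0.05
    seed: int = 0


@dataclass
class RunConfig:
    kinetics: KineticParameters = field(default_factory=KineticParameters)
    radiation: RadiationParameters = field(default_factory=RadiationParameters)
    automaton: AutomatonSettings = field(default_factory=AutomatonSettings)
    anneal: AnnealSchedule = field(default_factory=AnnealSchedule)
    output_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"


def _check_unknown(section: dict, allowed: set, where: str, errors: list) -> None:
    for key in section:
        if key not in allowed:
            errors.append(f"{where}: unknown key {key!r}")


def _build_kinetics(raw: dict, errors: list) -> KineticParameters:
    _check_unknown(raw, _KINETIC_KEYS, "kinetics", errors)
    base = KineticParameters()
    try:
        probs = DivisionProbabilities(
            p_self_renewal=float(raw.get("P_S", base.division_probs.p_self_renewal)),
            p_asymmetric=float(raw.get("P_A", base.division_probs.p_asymmetric)),
            p_differentiation=float(raw.get("P_D", base.division_probs.p_differentiation)),
        )
        return KineticParameters(
            division_probs=probs,
            k_transition=float(raw.get("K_T", base.k_transition)),
            k_nscc_division=float(raw.get("K_N", base.k_nscc_division)),
            k_csc_mitosis=float(raw.get("K_C", base.k_csc_mitosis)),
            lifespan_generations=int(raw.get("M", base.lifespan_generations)),
            senescent_death_rate=float(raw.get("d", base.senescent_death_rate)),
        )
    except (ParameterError, TypeError, ValueError) as exc:
        errors.append(f"kinetics: {exc}")
        return base


def _build_radiation(raw: dict, errors: list) -> RadiationParameters:
    _check_unknown(raw, _RADIATION_KEYS, "radiation", errors)
    base = RadiationParameters()
    try:
        return RadiationParameters(
            dsb_per_gy=float(raw.get("k", base.dsb_per_gy)),
            dose=float(raw.get("D", base.dose)),
            repair_rate_csc=float(raw.get("r_C", base.repair_rate_csc)),
            repair_rate_nscc=float(raw.get("r_N", base.repair_rate_nscc)),
            misrepair_csc=float(raw.get("m_C", base.misrepair_csc)),
            misrepair_nscc=float(raw.get("m_N", base.misrepair_nscc)),
            survival_csc=float(raw.get("S_C", base.survival_csc)),
            survival_nscc=float(raw.get("S_N", base.survival_nscc)),
        )
    except (ParameterError, TypeError, ValueError) as exc:
        errors.append(f"radiation: {exc}")
        return base


def _build_automaton(raw: dict, errors: list) -> AutomatonSettings:
    _check_unknown(raw, _AUTOMATON_KEYS, "automaton", errors)
    base = AutomatonSettings()
    try:
        settings = AutomatonSettings(
            rows=int(raw.get("rows", base.rows)), cols=int(raw.get("cols", base.cols)),
            dt=float(raw.get("dt", base.dt)), seed=int(raw.get("seed", base.seed)),
        )
        if settings.rows < 1 or settings.cols < 1 or settings.dt <= 0:
            raise ParameterError("rows/cols must be >= 1 and dt > 0")
        return settings
    except (ParameterError, TypeError, ValueError) as exc:
        errors.append(f"automaton: {exc}")
        return base


def _build_anneal(raw: dict, errors: list) -> AnnealSchedule:
    _check_unknown(raw, _ANNEAL_KEYS, "anneal", errors)
    base = AnnealSchedule()
    try:
        kwargs = {k: raw[k] for k in raw if k in _ANNEAL_KEYS}
        return AnnealSchedule(**kwargs)
    except (ParameterError, TypeError, ValueError) as exc:
        errors.append(f"anneal: {exc}")
        return base


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Missing file, parse errors, unknown keys and invariant violations all
    raise :class:`ConfigError`; validation problems are listed together.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"config parse error in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    errors: list[str] = []
    _check_unknown(raw, _TOP_KEYS, "top level", errors)
    for section in ("kinetics", "radiation", "automaton", "anneal"):
        if section in raw and not isinstance(raw[section], dict):
            errors.append(f"{section}: must be a mapping")
            raw[section] = {}
    cfg = RunConfig(
        kinetics=_build_kinetics(raw.get("kinetics", {}), errors),
        radiation=_build_radiation(raw.get("radiation", {}), errors),
        automaton=_build_automaton(raw.get("automaton", {}), errors),
        anneal=_build_anneal(raw.get("anneal", {}), errors),
        output_dir=str(raw.get("output_dir", "out")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg
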