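"""Stochastic lattice cellular automaton counterpart of the ODE model.

Cells occupy a bounded rectangular grid (default 200 x 200 sites of
10 µm x 10 µm, one cell per site).  Per time step, in order: senescent
(generation-M) NSCCs die; NSCCs convert to CSCs; every cycling cell advances
its cell-cycle progress by ``dt * K`` (K_C for CSCs, K_N for NSCCs); cells
whose progress reaches its cycle-completion threshold attempt to divide into
a uniformly chosen vacant von Neumann neighbor, drawing the CSC division type
from (P_S, P_A, P_D) and incrementing both daughters' generations for an
NSCC division.  A cell with no vacant neighbor becomes quiescent — progress
held at threshold, still eligible for transition and death, dividing at the
first later opportunity.

Cycle-completion thresholds are drawn per cell from an Exp(1) distribution
(redrawn after every division), so division waiting times are exponential
with rate K — the same mass-action rates the ODE uses.  A deterministic unit
threshold would instead give doubling-time growth K*ln2 and bias the
equilibrium proportion upward.

Division attempts are processed in a freshly randomized order each step so no
lattice-sweep direction is privileged; all randomness comes from one
``numpy`` generator, making runs bit-for-bit reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import KineticParameters, ParameterError

VACANT, CSC, NSCC = 0, 1, 2

_NEIGHBOR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))  # von Neumann


@dataclass
class AutomatonConfig:
    grid_rows: int = 200
    grid_cols: int = 200
    time_step: float = 0.05
    params: KineticParameters = field(default_factory=KineticParameters)
    seed: int = 0
    site_size_um: float = 10.0  # metadata only

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ParameterError("grid dimensions must be positive")
        if self.time_step <= 0:
            raise ParameterError("time_step must be positive")
        k_max = max(self.params.k_csc_mitosis, self.params.k_nscc_division)
        if self.time_step * k_max > 1.0:
            raise ParameterError(
                "time_step too large: cycle progress per step must not exceed 1"
            )


@dataclass
class AutomatonState:
    cell_type: np.ndarray   # int8, VACANT/CSC/NSCC
    generation: np.ndarray  # int16, NSCC division generation (0 for CSCs)
    progress: np.ndarray    # float, cell-cycle progress since last division
    threshold: np.ndarray   # float, Exp(1) cycle-completion threshold
    time: float
    rng: np.random.Generator

    @property
    def csc_count(self) -> int:
        return int(np.count_nonzero(self.cell_type == CSC))

    @property
    def nscc_count(self) -> int:
        return int(np.count_nonzero(self.cell_type == NSCC))

    @property
    def occupied(self) -> int:
        return int(np.count_nonzero(self.cell_type != VACANT))

    def csc_proportion(self) -> float:
        total = self.occupied
        if total == 0:
            raise ZeroDivisionError("empty lattice has no CSC proportion")
        return self.csc_count / total

    def to_text(self) -> str:
        """Snapshot grid: '.' vacant, 'C' CSC, 'N' NSCC; one row per line."""
        chars = np.array([".", "C", "N"])
        return "\n".join("".join(row) for row in chars[self.cell_type])


def init_lattice(config: AutomatonConfig, *, n_csc: int = 0, n_nscc: int = 0,
                 total_cells: int | None = None,
                 proportion_csc: float | None = None) -> AutomatonState:
    """Seed the lattice at uniformly random vacant sites.

    Either give explicit ``n_csc`` / ``n_nscc`` counts, or ``total_cells``
    with ``proportion_csc``.  Seeded NSCCs start in generation 1; every cell
    starts at progress 0 with a fresh Exp(1) cycle-completion threshold
    (memorylessness makes an explicit random initial phase unnecessary).
    """
    if total_cells is not None:
        if proportion_csc is None or not (0.0 <= proportion_csc <= 1.0):
            raise ParameterError("proportion_csc in [0, 1] required with total_cells")
        n_csc = int(round(total_cells * proportion_csc))
        n_nscc = total_cells - n_csc
    n_sites = config.grid_rows * config.grid_cols
    if n_csc + n_nscc > n_sites:
        raise ParameterError(
            f"cannot seed {n_csc + n_nscc} cells on {n_sites} sites"
        )
    rng = np.random.default_rng(config.seed)
    cell_type = np.full((config.grid_rows, config.grid_cols), VACANT, dtype=np.int8)
    generation = np.zeros_like(cell_type, dtype=np.int16)
    progress = np.zeros(cell_type.shape, dtype=float)
    threshold = np.zeros(cell_type.shape, dtype=float)
    sites = rng.choice(n_sites, size=n_csc + n_nscc, replace=False)
    rows, cols = np.unravel_index(sites, cell_type.shape)
    cell_type[rows[:n_csc], cols[:n_csc]] = CSC
    cell_type[rows[n_csc:], cols[n_csc:]] = NSCC
    generation[rows[n_csc:], cols[n_csc:]] = 1
    threshold[rows, cols] = rng.exponential(1.0, n_csc + n_nscc)
    return AutomatonState(cell_type, generation, progress, threshold, 0.0, rng)


def step(state: AutomatonState, config: AutomatonConfig) -> AutomatonState:
    """Advance the lattice by one time step (mutates and returns ``state``)."""
    p = config.params
    dt = config.time_step
    m = p.lifespan_generations
    ct, gen, prog = state.cell_type, state.generation, state.progress
    thr = state.threshold
    rng = state.rng
    shape = ct.shape

    # 1. senescent death: generation-M NSCCs die at rate d
    senescent = (ct == NSCC) & (gen >= m)
    if senescent.any():
        dies = senescent & (rng.random(shape) < -math.expm1(-p.senescent_death_rate * dt))
        ct[dies] = VACANT
        gen[dies] = 0
        prog[dies] = 0.0
        thr[dies] = 0.0

    # 2. stochastic NSCC -> CSC transition (all generations eligible)
    if p.k_transition > 0:
        converts = (ct == NSCC) & (rng.random(shape) < -math.expm1(-p.k_transition * dt))
        ct[converts] = CSC
        gen[converts] = 0  # no generational memory in the CSC state

    # 3. cell-cycle progression (generation-M NSCCs no longer divide)
    prog[ct == CSC] += dt * p.k_csc_mitosis
    prog[(ct == NSCC) & (gen < m)] += dt * p.k_nscc_division

    # 4. division attempts, randomized order; vacancy only shrinks during this
    #    phase, so cells with no vacant neighbor now stay blocked this step
    can_divide = ((ct == CSC) | ((ct == NSCC) & (gen < m)))
    ready_r, ready_c = np.nonzero(can_divide & (prog >= thr))
    if ready_r.size:
        order = rng.permutation(ready_r.size)
        rows_n, cols_n = shape
        probs = p.division_probs
        p_self = probs.p_self_renewal
        p_self_or_asym = probs.p_self_renewal + probs.p_asymmetric
        for idx in order:
            r, c = int(ready_r[idx]), int(ready_c[idx])
            vacant = [(r + dr, c + dc) for dr, dc in _NEIGHBOR_OFFSETS
                      if 0 <= r + dr < rows_n and 0 <= c + dc < cols_n
                      and ct[r + dr, c + dc] == VACANT]
            if not vacant:
                prog[r, c] = thr[r, c]  # quiescent, retains division readiness
                continue
            tr, tc = vacant[int(rng.integers(len(vacant)))]
            if ct[r, c] == CSC:
                u = rng.random()
                if u < p_self:  # self-renewal: two CSCs
                    ct[tr, tc] = CSC
                    gen[tr, tc] = 0
                elif u < p_self_or_asym:  # asymmetric: CSC stays, NSCC daughter
                    ct[tr, tc] = NSCC
                    gen[tr, tc] = 1
                else:  # differentiation: two generation-1 NSCCs
                    ct[r, c] = NSCC
                    gen[r, c] = 1
                    ct[tr, tc] = NSCC
                    gen[tr, tc] = 1
            else:  # NSCC division: both daughters advance one generation
                g = gen[r, c] + 1
                gen[r, c] = g
                ct[tr, tc] = NSCC
                gen[tr, tc] = g
            prog[r, c] = 0.0
            prog[tr, tc] = 0.0
            thr[r, c] = rng.exponential(1.0)
            thr[tr, tc] = rng.exponential(1.0)
    np.minimum(prog, thr, out=prog)  # quiescent cells wait at their threshold
    state.time += dt
    return state


def run(config: AutomatonConfig, n_steps: int, record_every: int = 1,
        *, snapshot_every: int | None = None,
        **seeding) -> tuple[pd.DataFrame, list[str]]:
    """Simulate ``n_steps`` steps from a freshly seeded lattice.

    ``seeding`` is forwarded to :func:`init_lattice`.  Returns a counts table
    with columns time_days, csc_count, nscc_count, csc_proportion (recorded
    every ``record_every`` steps, including the initial state) and a list of
    text snapshots (empty unless ``snapshot_every`` is set).
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    state = init_lattice(config, **seeding)
    records = []
    snapshots: list[str] = []

    def record() -> None:
        n_c, n_n = state.csc_count, state.nscc_count
        total = n_c + n_n
        records.append((state.time, n_c, n_n, n_c / total if total else np.nan))

    record()
    if snapshot_every:
        snapshots.append(state.to_text())
    for k in range(1, n_steps + 1):
        step(state, config)
        if k % record_every == 0 or k == n_steps:
            record()
        if snapshot_every and k % snapshot_every == 0:
            snapshots.append(state.to_text())
    frame = pd.DataFrame(records, columns=["time_days", "csc_count",
                                           "nscc_count", "csc_proportion"])
    return frame, snapshots
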