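"""Per-step scheduler, full runs, and the replicate runner.

Each step executes the fixed six-event sequence:

1. cytokine release (tumor inflow only; the wound-healing one-shot release
   happens during initialization),
2. every free factor takes one random-walk step,
3. every free factor makes one binding attempt (free factors are processed
   in a freshly shuffled uniform random order each step),
4. every bound factor is checked for cleavage against its patch's heparinase,
5. heparinase flux over all patches,

after which the step counter advances and the per-class bound/free counts
are recorded.  (The sixth listed event — tumor replenishment — is event 1 of
the following step; recording happens at every step boundary.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import BOUND, CLEAVED, FREE
from .config import CLASS_ORDER, SimulationConfig
from .dynamics import (
    SimulationState,
    attempt_binding,
    cleave_bound_factor,
    init_simulation,
    move_growth_factor,
    release_cytokines,
    update_heparinase,
)
from .observables import BoundTimeSeries, average_replicates

__all__ = ["RunResult", "ReplicateSummary", "step", "run", "run_replicates"]

_N_CLASSES = len(CLASS_ORDER)


@dataclass(frozen=True)
class RunResult:
    """One replicate's recorded trajectories and final summary.

    All series include t=0, so their length is ``n_steps + 1``.  In degrade
    mode, at every t and for each class,
    ``bound + free + cleaved_so_far == cumulative_released``; in recycle mode
    ``bound + free == cumulative_released``.
    """

    config: SimulationConfig
    replicate_index: int
    bound_series: BoundTimeSeries
    free_series: BoundTimeSeries
    cleaved_series: np.ndarray  # cumulative cleavage events, (T, 3)
    released_series: np.ndarray  # cumulative released, (T, 3)
    final_state: dict

    def mass_balance_ok(self) -> bool:
        """Check the per-class mass-balance identity at every timepoint."""
        bound = self.bound_series.counts
        free = self.free_series.counts
        if self.config.cleaved_fate == "degrade":
            lhs = bound + free + self.cleaved_series
        else:
            lhs = bound + free
        return bool(np.array_equal(lhs, self.released_series.astype(float)))


@dataclass(frozen=True)
class ReplicateSummary:
    """Pointwise mean bound/free series over replicates."""

    config: SimulationConfig
    n_replicates: int
    mean_bound: BoundTimeSeries
    mean_free: BoundTimeSeries


def step(state: SimulationState, config: SimulationConfig) -> SimulationState:
    """Advance one step through the six-event sequence (in place)."""
    # (1) tumor inflow at the start of the step
    if config.tumor_mode:
        release_cytokines(state, config.inflow_per_step)

    # (2)+(3) free factors move, then attempt binding, in one shuffled order
    free_factors = [gf for gf in state.factors if gf.state == FREE]
    if free_factors:
        order = state.rng.permutation(len(free_factors))
        for i in order:
            move_growth_factor(free_factors[i], state)
        for i in order:
            attempt_binding(free_factors[i], state)

    # (4) cleavage check for every bound factor against its patch
    heparinase = state.heparinase
    thresholds = config.cleave_thresholds
    w, h = state.grid_width, state.grid_height
    any_cleaved = False
    for gf in state.factors:
        if gf.state != BOUND:
            continue
        cell = gf.bound_cell
        col, row = int(cell.x) % w, int(cell.y) % h
        if heparinase[row, col] >= thresholds[gf.class_index]:
            if cleave_bound_factor(gf, state.microenvironment(col, row), config):
                state.cumulative_cleaved[gf.class_index] += 1
                any_cleaved = True
    if any_cleaved and config.cleaved_fate == "degrade":
        state.factors = [gf for gf in state.factors if gf.state != CLEAVED]

    # (5) heparinase flux
    update_heparinase(state)

    state.t += 1
    return state


def run(
    config: SimulationConfig,
    replicate_index: int = 0,
    check_invariants: bool = False,
) -> RunResult:
    """Initialize and run one replicate for ``config.n_steps`` steps.

    Bound and free counts per class are recorded at every step including
    t=0.  With ``check_invariants`` the binding-site conservation law is
    asserted after every step (used by the test suite; raises RuntimeError
    on any breach).
    """
    state = init_simulation(config, replicate_index)
    n_rec = config.n_steps + 1
    bound = np.zeros((n_rec, _N_CLASSES), dtype=np.int64)
    free = np.zeros((n_rec, _N_CLASSES), dtype=np.int64)
    cleaved = np.zeros((n_rec, _N_CLASSES), dtype=np.int64)
    released = np.zeros((n_rec, _N_CLASSES), dtype=np.int64)

    def record(t: int) -> None:
        counts = state.counts_by_state()
        bound[t] = counts["bound"]
        free[t] = counts["free"]
        cleaved[t] = state.cumulative_cleaved
        released[t] = state.cumulative_released

    if check_invariants:
        state.check_conservation()
    record(0)
    for t in range(1, n_rec):
        step(state, config)
        if check_invariants:
            state.check_conservation()
        record(t)

    final_counts = state.counts_by_state()
    final_state = {
        "bound": dict(zip(CLASS_ORDER, final_counts["bound"].tolist())),
        "free": dict(zip(CLASS_ORDER, final_counts["free"].tolist())),
        "cleaved": dict(zip(CLASS_ORDER, state.cumulative_cleaved.tolist())),
        "released": dict(zip(CLASS_ORDER, state.cumulative_released.tolist())),
        "heparinase_mean": float(state.heparinase.mean()),
    }
    return RunResult(
        config=config,
        replicate_index=replicate_index,
        bound_series=BoundTimeSeries(bound),
        free_series=BoundTimeSeries(free),
        cleaved_series=cleaved,
        released_series=released,
        final_state=final_state,
    )


def run_replicates(
    config: SimulationConfig, check_invariants: bool = False
) -> tuple[list[RunResult], ReplicateSummary]:
    """Run ``config.n_replicates`` independent replicates and average them.

    Replicate i uses the random stream derived from (seed, i); the summary
    holds the pointwise arithmetic mean bound/free series per class.
    """
    results = [
        run(config, i, check_invariants=check_invariants)
        for i in range(config.n_replicates)
    ]
    summary = ReplicateSummary(
        config=config,
        n_replicates=config.n_replicates,
        mean_bound=average_replicates(r.bound_series for r in results),
        mean_free=average_replicates(r.free_series for r in results),
    )
    return results, summary
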