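"""Elementary stochastic dynamics: initialization, movement, binding,
cleavage, heparinase flux, and cytokine release.

All randomness flows through ``SimulationState.rng``, a numpy Generator
seeded deterministically from ``(config.seed, replicate_index)``, so a run is
fully reproducible from its configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .agents import BOUND, CLEAVED, FREE, Cell, GrowthFactor, Microenvironment
from .config import CLASS_ORDER, ConfigError, SimulationConfig

__all__ = [
    "SimulationState",
    "init_simulation",
    "move_growth_factor",
    "attempt_binding",
    "cleave_bound_factor",
    "update_heparinase",
    "release_cytokines",
]

_N_CLASSES = len(CLASS_ORDER)


@dataclass
class SimulationState:
    """Full mutable state of one replicate.

    The heparinase field is stored as a ``(grid_height, grid_width)`` float
    array (row-major, indexed ``[row, col]``); ``microenvironment(col, row)``
    exposes the per-patch view.  ``factors`` holds the active (free or bound)
    growth factors; factors degraded after cleavage are dropped from the list
    but remain counted in ``cumulative_cleaved``.
    """

    config: SimulationConfig
    replicate_index: int
    rng: np.random.Generator
    t: int
    heparinase: np.ndarray
    cells: list[Cell]
    factors: list[GrowthFactor]
    cumulative_released: np.ndarray  # per class, ever introduced
    cumulative_cleaved: np.ndarray  # per class, cleavage events so far
    # static spatial index patch -> cells there (cells are non-motile)
    _cells_by_patch: dict[tuple[int, int], list[Cell]] = field(default_factory=dict)

    # -- geometry ---------------------------------------------------------

    @property
    def grid_width(self) -> int:
        return self.config.grid_width

    @property
    def grid_height(self) -> int:
        return self.config.grid_height

    @property
    def n_microenvironments(self) -> int:
        return self.heparinase.size

    def patch_of(self, x: float, y: float) -> tuple[int, int]:
        """(col, row) of the patch containing continuous position (x, y)."""
        return int(x) % self.grid_width, int(y) % self.grid_height

    def microenvironment(self, col: int, row: int) -> Microenvironment:
        return Microenvironment(col, row, float(self.heparinase[row, col]))

    def microenvironments(self) -> Iterator[Microenvironment]:
        for row in range(self.grid_height):
            for col in range(self.grid_width):
                yield self.microenvironment(col, row)

    def cells_at(self, col: int, row: int) -> list[Cell]:
        return self._cells_by_patch.get((col, row), [])

    # -- bookkeeping ------------------------------------------------------

    def counts_by_state(self) -> dict[str, np.ndarray]:
        """Per-class counts of free and bound factors among active agents."""
        free = np.zeros(_N_CLASSES, dtype=np.int64)
        bound = np.zeros(_N_CLASSES, dtype=np.int64)
        for gf in self.factors:
            if gf.state == FREE:
                free[gf.class_index] += 1
            elif gf.state == BOUND:
                bound[gf.class_index] += 1
        return {"free": free, "bound": bound}

    def occupied_sites(self) -> int:
        return sum(c.total_sites - c.free_sites for c in self.cells)

    def check_conservation(self) -> None:
        """Assert binding-site conservation; raises RuntimeError on breach."""
        counts = self.counts_by_state()
        n_bound = int(counts["bound"].sum())
        occupied = self.occupied_sites()
        if occupied != n_bound:
            raise RuntimeError(
                f"site conservation violated at t={self.t}: "
                f"{occupied} occupied sites vs {n_bound} bound factors"
            )
        per_cell: dict[int, int] = {}
        for gf in self.factors:
            if gf.state == BOUND:
                per_cell[id(gf.bound_cell)] = per_cell.get(id(gf.bound_cell), 0) + 1
        for cell in self.cells:
            expect = per_cell.get(id(cell), 0)
            if cell.total_sites - cell.free_sites != expect:
                raise RuntimeError(
                    f"per-cell conservation violated at t={self.t}: cell at "
                    f"({cell.x:.2f},{cell.y:.2f}) has {cell.bound_sites} occupied "
                    f"sites but {expect} bound factors"
                )


def _derive_rng(seed: int, replicate_index: int) -> np.random.Generator:
    # SeedSequence([seed, replicate]) gives independent, reproducible streams
    return np.random.default_rng(np.random.SeedSequence([seed, replicate_index]))


def init_simulation(config: SimulationConfig, replicate_index: int) -> SimulationState:
    """Build the initial state of one replicate.

    Heparinase is drawn independently uniform on [0, heparinase_max] per
    patch; cells land at uniform continuous positions with binding-site
    counts from a rounded, zero-clamped normal(site_mean, site_sd); the
    initial one-shot release places ``initial_release[c]`` free factors of
    each class at uniform positions.
    """
    if replicate_index < 0:
        raise ConfigError(f"replicate_index must be >= 0, got {replicate_index}")
    rng = _derive_rng(config.seed, replicate_index)
    w, h = config.grid_width, config.grid_height

    heparinase = rng.uniform(0.0, config.heparinase_max, size=(h, w))

    xs = rng.uniform(0.0, w, size=config.n_cells)
    ys = rng.uniform(0.0, h, size=config.n_cells)
    sites = rng.normal(config.site_mean, config.site_sd, size=config.n_cells)
    sites = np.clip(np.rint(sites), 0, None).astype(np.int64)
    cells = [
        Cell(float(x), float(y), int(s), int(s)) for x, y, s in zip(xs, ys, sites)
    ]

    state = SimulationState(
        config=config,
        replicate_index=replicate_index,
        rng=rng,
        t=0,
        heparinase=heparinase,
        cells=cells,
        factors=[],
        cumulative_released=np.zeros(_N_CLASSES, dtype=np.int64),
        cumulative_cleaved=np.zeros(_N_CLASSES, dtype=np.int64),
    )
    for cell in cells:
        state._cells_by_patch.setdefault(state.patch_of(cell.x, cell.y), []).append(cell)

    release_cytokines(state, config.initial_release)
    return state


def move_growth_factor(
    gf: GrowthFactor, state: SimulationState, step_length: float = 1.0
) -> GrowthFactor:
    """One unit step of an isotropic random walk on the torus.

    Free factors pick a uniform heading and advance ``step_length`` (one
    patch width by default); positions wrap.  Bound and cleaved factors are
    left untouched (contractual no-op).
    """
    if gf.state != FREE:
        return gf
    theta = state.rng.uniform(0.0, 2.0 * math.pi)
    gf.x = (gf.x + step_length * math.cos(theta)) % state.grid_width
    gf.y = (gf.y + step_length * math.sin(theta)) % state.grid_height
    return gf


def attempt_binding(gf: GrowthFactor, state: SimulationState) -> bool:
    """One binding attempt of a free factor in its current patch.

    Among co-located cells with at least one free binding site, one is chosen
    uniformly at random; with the class's ``attach_prob`` the factor binds to
    it and the cell loses one free site.  Returns True iff the factor bound.
    """
    if gf.state != FREE:
        return False
    col, row = state.patch_of(gf.x, gf.y)
    eligible = [c for c in state.cells_at(col, row) if c.free_sites > 0]
    if not eligible:
        return False
    if len(eligible) == 1:
        cell = eligible[0]
    else:
        cell = eligible[int(state.rng.integers(len(eligible)))]
    if state.rng.random() < state.config.attach_probs[gf.class_index]:
        gf.state = BOUND
        gf.bound_cell = cell
        cell.free_sites -= 1
        return True
    return False


def cleave_bound_factor(
    gf: GrowthFactor, env: Microenvironment, config: SimulationConfig
) -> bool:
    """Threshold cleavage of a bound factor by local heparinase.

    If the patch heparinase is at or above the class's cleavage threshold the
    factor detaches and its cell regains one free site.  The detached
    factor's fate follows ``config.cleaved_fate``: ``degrade`` marks it
    cleaved (it takes no further actions), ``recycle`` returns it to the free
    pool to resume its walk.  Free/cleaved factors are a no-op.
    """
    if gf.state != BOUND:
        return False
    if env.heparinase < config.cleave_thresholds[gf.class_index]:
        return False
    gf.bound_cell.free_sites += 1
    gf.bound_cell = None
    gf.state = FREE if config.cleaved_fate == "recycle" else CLEAVED
    return True


def update_heparinase(state: SimulationState) -> SimulationState:
    """Stochastic heparinase flux, patch-wise independent.

    Each patch, with probability ``flux_prob``, has its heparinase perturbed
    by a uniform increment on [-flux_magnitude, +flux_magnitude]; the result
    is clamped to [0, heparinase_max].  The symmetric clamped walk keeps the
    field in homeostatic balance around heparinase_max / 2.
    """
    cfg = state.config
    shape = state.heparinase.shape
    mask = state.rng.random(shape) < cfg.flux_prob
    delta = state.rng.uniform(-cfg.flux_magnitude, cfg.flux_magnitude, size=shape)
    np.clip(
        state.heparinase + np.where(mask, delta, 0.0),
        0.0,
        cfg.heparinase_max,
        out=state.heparinase,
    )
    return state


def release_cytokines(state: SimulationState, counts_per_class) -> SimulationState:
    """Introduce new free factors at uniform random positions.

    ``counts_per_class`` is an (LA, MA, HA) triple of non-negative integers;
    ``cumulative_released`` is incremented accordingly.
    """
    if len(counts_per_class) != _N_CLASSES:
        raise ConfigError("counts_per_class must be an (LA, MA, HA) triple")
    for label, n in zip(CLASS_ORDER, counts_per_class):
        if n != int(n) or int(n) < 0:
            raise ConfigError(f"release count ({label}) must be a non-negative integer")
    w, h = state.grid_width, state.grid_height
    for ci, n in enumerate(counts_per_class):
        n = int(n)
        if n == 0:
            continue
        xs = state.rng.uniform(0.0, w, size=n)
        ys = state.rng.uniform(0.0, h, size=n)
        state.factors.extend(
            GrowthFactor(ci, float(x), float(y)) for x, y in zip(xs, ys)
        )
        state.cumulative_released[ci] += n
    return state
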