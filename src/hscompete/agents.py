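"""Agent and patch types: stromal cells, growth factors, microenvironments."""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import CLASS_ORDER

__all__ = ["FREE", "BOUND", "CLEAVED", "Microenvironment", "Cell", "GrowthFactor"]

# Growth-factor states.
FREE = "free"
BOUND = "bound"
CLEAVED = "cleaved"


@dataclass(slots=True)
class Microenvironment:
    """One lattice patch, carrying a local heparinase concentration.

    The simulation state stores the heparinase field as a dense array; a
    ``Microenvironment`` is the per-patch view handed to operations that act
    on a single patch.
    """

    col: int
    row: int
    heparinase: float


@dataclass(slots=True)
class Cell:
    """A non-motile stromal cell at a continuous position.

    ``total_sites`` is fixed for the cell's lifetime; ``free_sites`` falls as
    growth factors occupy heparan-sulfate binding sites and rises again when
    bound factors are cleaved by heparinase.
    """

    x: float
    y: float
    total_sites: int
    free_sites: int

    @property
    def bound_sites(self) -> int:
        return self.total_sites - self.free_sites


@dataclass(slots=True)
class GrowthFactor:
    """A motile cytokine agent of one affinity class.

    While free it performs a unit-step random walk on the (toroidal) lattice;
    once bound it stays with its cell until the local heparinase reaches the
    class's cleavage threshold.  Cleaved factors take no further actions.
    """

    class_index: int  # index into CLASS_ORDER
    x: float
    y: float
    state: str = FREE
    bound_cell: Cell | None = None

    @property
    def class_label(self) -> str:
        return CLASS_ORDER[self.class_index]
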