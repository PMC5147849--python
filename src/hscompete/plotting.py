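"""Optional plot export: bound counts per class against time."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .config import CLASS_ORDER
from .observables import BoundTimeSeries

_COLORS = {"LA": "tab:red", "MA": "tab:green", "HA": "tab:blue"}
_LABELS = {
    "LA": "LA (stimulators, e.g. VEGF)",
    "MA": "MA (stabilizers, e.g. PDGF-B)",
    "HA": "HA (inhibitors, e.g. PF-4/TSP-1)",
}


def plot_bound_series(
    summary: BoundTimeSeries, path: Union[str, Path], title: str | None = None
) -> Path:
    """Save a per-class bound-count time-series figure (PNG/PDF by suffix)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label in CLASS_ORDER:
        ax.plot(summary.for_class(label), color=_COLORS[label], label=_LABELS[label])
    ax.set_xlabel("time step")
    ax.set_ylabel("bound growth factors")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
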