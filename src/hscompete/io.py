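"""Configuration files, CSV serialization, and output bundles.

Config files are flat key-value documents (YAML or JSON — YAML is a
superset, so one loader covers both).  Per-class parameters use suffixed
keys (``attach_prob_la``, ``cleave_threshold_ha``, ``initial_release_ma``,
``inflow_la``, ...).  Unknown keys are rejected by name.

Time-series CSVs carry the fixed column set
``step, class, bound_count, free_count, replicate_index`` in deterministic
step-major order with classes LA, MA, HA; the replicate-mean file uses
``replicate_index = "mean"``.  Files are written to a temporary sibling and
atomically renamed, so a failed write never leaves a partial CSV behind.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (
    CLASS_ORDER,
    AffinityClassParams,
    ConfigError,
    SimulationConfig,
    default_class_params,
)
from .engine import ReplicateSummary, RunResult
from .observables import BoundTimeSeries, PatternVerdict

__all__ = [
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_output_bundle",
    "OutputBundle",
]

CSV_COLUMNS = ("step", "class", "bound_count", "free_count", "replicate_index")

_SCALAR_KEYS = (
    "grid_width",
    "grid_height",
    "n_cells",
    "site_mean",
    "site_sd",
    "heparinase_max",
    "flux_prob",
    "flux_magnitude",
    "cleaved_fate",
    "n_steps",
    "n_replicates",
    "seed",
)
_CLASS_KEY_STEMS = ("attach_prob", "cleave_threshold", "initial_release", "inflow")


def _class_key(stem: str, label: str) -> str:
    return f"{stem}_{label.lower()}"


_KNOWN_KEYS = frozenset(_SCALAR_KEYS) | {
    _class_key(stem, label) for stem in _CLASS_KEY_STEMS for label in CLASS_ORDER
}


def config_to_dict(config: SimulationConfig) -> dict:
    """Flatten a config into the key-value form used by config files."""
    doc: dict = {k: getattr(config, k) for k in _SCALAR_KEYS}
    for label, params in zip(CLASS_ORDER, config.class_params):
        doc[_class_key("attach_prob", label)] = params.attach_prob
        doc[_class_key("cleave_threshold", label)] = params.cleave_threshold
    for label, n0, inflow in zip(
        CLASS_ORDER, config.initial_release, config.inflow_per_step
    ):
        doc[_class_key("initial_release", label)] = n0
        doc[_class_key("inflow", label)] = inflow
    return doc


def config_from_dict(doc: dict) -> SimulationConfig:
    """Build a validated config from a flat key-value mapping.

    Missing keys take their defaults; unknown keys raise a ConfigError that
    names them all.
    """
    unknown = sorted(set(doc) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")

    kwargs = {k: doc[k] for k in _SCALAR_KEYS if k in doc}

    heparinase_max = doc.get("heparinase_max", 1.0)
    class_keys_present = any(
        _class_key(stem, label) in doc
        for stem in ("attach_prob", "cleave_threshold")
        for label in CLASS_ORDER
    )
    if class_keys_present:
        base = default_class_params(heparinase_max)
        kwargs["class_params"] = tuple(
            AffinityClassParams(
                label,
                doc.get(_class_key("attach_prob", label), p.attach_prob),
                doc.get(_class_key("cleave_threshold", label), p.cleave_threshold),
            )
            for label, p in zip(CLASS_ORDER, base)
        )

    for stem, cfg_field, default in (
        ("initial_release", "initial_release", (300, 300, 300)),
        ("inflow", "inflow_per_step", (0, 0, 0)),
    ):
        if any(_class_key(stem, label) in doc for label in CLASS_ORDER):
            kwargs[cfg_field] = tuple(
                doc.get(_class_key(stem, label), dflt)
                for label, dflt in zip(CLASS_ORDER, default)
            )

    return SimulationConfig(**kwargs)


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Load and validate a configuration file (YAML or JSON dialect).

    An empty document yields the full defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse configuration file {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(
            f"configuration file {path} must contain a key-value mapping, "
            f"got {type(doc).__name__}"
        )
    return config_from_dict(doc)


def save_config(config: SimulationConfig, path: Union[str, Path]) -> None:
    """Write the flat key-value form of a config as YAML."""
    _atomic_write_text(
        Path(path), yaml.safe_dump(config_to_dict(config), sort_keys=True)
    )


def _atomic_write_text(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _series_frame(
    bound: BoundTimeSeries, free: BoundTimeSeries, replicate_label
) -> pd.DataFrame:
    n = bound.n_timepoints
    rows = {
        "step": np.repeat(np.arange(n), len(CLASS_ORDER)),
        "class": np.tile(np.array(CLASS_ORDER), n),
        "bound_count": bound.counts.reshape(-1),
        "free_count": free.counts.reshape(-1),
        "replicate_index": replicate_label,
    }
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_timeseries_csv(
    result: Union[RunResult, ReplicateSummary], path: Union[str, Path]
) -> Path:
    """Serialize a run or a replicate summary to the fixed CSV layout."""
    if isinstance(result, RunResult):
        frame = _series_frame(
            result.bound_series, result.free_series, result.replicate_index
        )
        # raw replicate counts are integral; keep them so
        frame["bound_count"] = frame["bound_count"].astype(np.int64)
        frame["free_count"] = frame["free_count"].astype(np.int64)
    elif isinstance(result, ReplicateSummary):
        frame = _series_frame(result.mean_bound, result.mean_free, "mean")
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    path = Path(path)
    _atomic_write_text(path, frame.to_csv(index=False, lineterminator="\n"))
    return path


def read_timeseries_csv(
    path: Union[str, Path],
) -> tuple[BoundTimeSeries, BoundTimeSeries]:
    """Read a time-series CSV back into (bound, free) series.

    A file holding several replicates is averaged pointwise per class.
    """
    frame = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing CSV column(s): {', '.join(sorted(missing))}")
    out = []
    for value_col in ("bound_count", "free_count"):
        pivot = frame.pivot_table(
            index="step", columns="class", values=value_col, aggfunc="mean"
        )
        pivot = pivot.reindex(columns=list(CLASS_ORDER)).sort_index()
        if pivot.isna().any().any():
            raise ValueError(f"{path}: incomplete series (missing step/class entries)")
        out.append(BoundTimeSeries(pivot.to_numpy()))
    return out[0], out[1]


@dataclasses.dataclass(frozen=True)
class OutputBundle:
    """Paths of everything one `run` invocation wrote."""

    outdir: Path
    replicate_csvs: tuple[Path, ...]
    summary_csv: Path
    verdict_json: Path
    config_echo: Path
    manifest: Path


def write_output_bundle(
    outdir: Union[str, Path],
    results: list[RunResult],
    summary: ReplicateSummary,
    verdict: PatternVerdict,
    config: SimulationConfig,
    scenario_name: str | None = None,
    timestamp: str | None = None,
) -> OutputBundle:
    """Write the self-describing output directory for one run.

    Contents: one CSV per replicate, the replicate-mean CSV, the pattern
    verdict as JSON, a config echo sufficient to reproduce every CSV, and a
    small manifest (the only file carrying a timestamp).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    replicate_csvs = []
    for res in results:
        p = outdir / f"timeseries_rep{res.replicate_index:03d}.csv"
        write_timeseries_csv(res, p)
        replicate_csvs.append(p)
    summary_csv = write_timeseries_csv(summary, outdir / "timeseries_mean.csv")

    verdict_json = outdir / "verdict.json"
    _atomic_write_text(
        verdict_json, json.dumps(dataclasses.asdict(verdict), indent=2) + "\n"
    )

    config_echo = outdir / "config.yaml"
    save_config(config, config_echo)

    manifest = outdir / "manifest.txt"
    lines = [
        f"hscompete_version: {__version__}",
        f"seed: {config.seed}",
        f"n_replicates: {config.n_replicates}",
        f"n_steps: {config.n_steps}",
        f"scenario: {scenario_name or 'custom'}",
        f"timestamp: {timestamp or ''}",
    ]
    _atomic_write_text(manifest, "\n".join(lines) + "\n")

    return OutputBundle(
        outdir=outdir,
        replicate_csvs=tuple(replicate_csvs),
        summary_csv=summary_csv,
        verdict_json=verdict_json,
        config_echo=config_echo,
        manifest=manifest,
    )
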