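"""Simulation configuration: parameter record, defaults, and validation.

The model distinguishes three growth-factor classes by their affinity for
heparan sulfate: LA (low affinity; angiogenesis stimulators such as VEGF),
MA (medium affinity; vessel stabilizers such as PDGF-B) and HA (high
affinity; inhibitors such as PF-4 and TSP-1).  Affinity is expressed as the
heparinase concentration a class tolerates before being cleaved off its
binding site: the low-affinity class is cleaved at the lowest heparinase
level and the high-affinity class only at the highest, so valid
configurations must satisfy the strict ordering

    cleave_threshold(LA) < cleave_threshold(MA) < cleave_threshold(HA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = [
    "CLASS_ORDER",
    "ConfigError",
    "AffinityClassParams",
    "SimulationConfig",
    "validate_affinity_ordering",
    "default_class_params",
]

#: Growth-factor classes in increasing order of heparan-sulfate affinity.
CLASS_ORDER = ("LA", "MA", "HA")

#: Default cleavage thresholds as fractions of ``heparinase_max``.
_DEFAULT_THRESHOLD_FRACTIONS = (0.25, 0.50, 0.75)

#: Default per-class attachment probability.  Affinity differences are
#: expressed exclusively through the cleavage thresholds; attachment is
#: class-independent by default.
_DEFAULT_ATTACH_PROB = 0.5

CLEAVED_FATES = ("degrade", "recycle")


class ConfigError(ValueError):
    """A configuration parameter is missing, unknown, or invalid."""


@dataclass(frozen=True)
class AffinityClassParams:
    """Parameters of one growth-factor affinity class.

    Parameters
    ----------
    class_label
        One of ``"LA"``, ``"MA"``, ``"HA"``.
    attach_prob
        Probability in [0, 1] that a factor co-located with a cell that has
        a free binding site attaches to it in one step.
    cleave_threshold
        Heparinase concentration (arbitrary units) at or above which a bound
        factor of this class is cleaved off its binding site.
    """

    class_label: str
    attach_prob: float
    cleave_threshold: float

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_ORDER:
            raise ConfigError(
                f"class_label must be one of {CLASS_ORDER}, got {self.class_label!r}"
            )
        if not 0.0 <= self.attach_prob <= 1.0:
            raise ConfigError(
                f"attach_prob ({self.class_label}) must lie in [0, 1], "
                f"got {self.attach_prob}"
            )
        if self.cleave_threshold < 0.0:
            raise ConfigError(
                f"cleave_threshold ({self.class_label}) must be >= 0, "
                f"got {self.cleave_threshold}"
            )


def default_class_params(
    heparinase_max: float = 1.0,
    attach_prob: float = _DEFAULT_ATTACH_PROB,
) -> tuple[AffinityClassParams, ...]:
    """Default class parameters: thresholds at 0.25/0.50/0.75 of the
    heparinase ceiling, a common attachment probability for all classes."""
    return tuple(
        AffinityClassParams(label, attach_prob, frac * heparinase_max)
        for label, frac in zip(CLASS_ORDER, _DEFAULT_THRESHOLD_FRACTIONS)
    )


def _check_nonneg_int_triple(name: str, triple) -> tuple[int, int, int]:
    if len(triple) != len(CLASS_ORDER):
        raise ConfigError(f"{name} must have one entry per class {CLASS_ORDER}")
    out = []
    for label, v in zip(CLASS_ORDER, triple):
        if v != int(v) or int(v) < 0:
            raise ConfigError(f"{name} ({label}) must be a non-negative integer, got {v}")
        out.append(int(v))
    return tuple(out)


@dataclass(frozen=True)
class SimulationConfig:
    """Every model parameter in one validated record.

    The defaults reproduce the baseline wound-healing setup: a 51x51 lattice
    (2601 microenvironments), 200 stromal cells whose binding-site counts are
    drawn from a rounded, zero-clamped normal(5, 2), a one-shot release of
    300 factors per class at t=0, no tumor inflow, and heparinase fields
    initialized uniformly on [0, heparinase_max] with clamped symmetric flux.

    ``inflow_per_step`` all zero means wound-healing mode; any nonzero entry
    means tumor mode (continuous per-step release).
    """

    grid_width: int = 51
    grid_height: int = 51
    n_cells: int = 200
    site_mean: float = 5.0
    site_sd: float = 2.0
    class_params: tuple[AffinityClassParams, ...] | None = None
    initial_release: tuple[int, int, int] = (300, 300, 300)
    inflow_per_step: tuple[int, int, int] = (0, 0, 0)
    heparinase_max: float = 1.0
    flux_prob: float = 0.2
    flux_magnitude: float | None = None
    cleaved_fate: str = "degrade"
    n_steps: int = 500
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_params is None:
            object.__setattr__(
                self, "class_params", default_class_params(self.heparinase_max)
            )
        else:
            object.__setattr__(self, "class_params", tuple(self.class_params))
        if self.flux_magnitude is None:
            object.__setattr__(self, "flux_magnitude", 0.1 * self.heparinase_max)

        for name in ("grid_width", "grid_height"):
            v = getattr(self, name)
            if v != int(v) or int(v) < 1:
                raise ConfigError(f"{name} must be a positive integer, got {v}")
            object.__setattr__(self, name, int(v))
        for name, minimum in (("n_cells", 0), ("n_steps", 0), ("n_replicates", 1)):
            v = getattr(self, name)
            if v != int(v) or int(v) < minimum:
                raise ConfigError(f"{name} must be an integer >= {minimum}, got {v}")
            object.__setattr__(self, name, int(v))
        if self.seed != int(self.seed) or int(self.seed) < 0:
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed}")
        object.__setattr__(self, "seed", int(self.seed))

        for name in ("site_mean", "site_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.heparinase_max <= 0:
            raise ConfigError(f"heparinase_max must be > 0, got {self.heparinase_max}")
        if not 0.0 <= self.flux_prob <= 1.0:
            raise ConfigError(f"flux_prob must lie in [0, 1], got {self.flux_prob}")
        if self.flux_magnitude < 0:
            raise ConfigError(f"flux_magnitude must be >= 0, got {self.flux_magnitude}")
        if self.cleaved_fate not in CLEAVED_FATES:
            raise ConfigError(
                f"cleaved_fate must be one of {CLEAVED_FATES}, got {self.cleaved_fate!r}"
            )

        object.__setattr__(
            self,
            "initial_release",
            _check_nonneg_int_triple("initial_release", self.initial_release),
        )
        object.__setattr__(
            self,
            "inflow_per_step",
            _check_nonneg_int_triple("inflow_per_step", self.inflow_per_step),
        )

        labels = tuple(p.class_label for p in self.class_params)
        if labels != CLASS_ORDER:
            raise ConfigError(
                f"class_params must list one entry per class in order {CLASS_ORDER}, "
                f"got labels {labels}"
            )
        validate_affinity_ordering(self)

    # -- convenience accessors -------------------------------------------

    def params_for(self, class_label: str) -> AffinityClassParams:
        return self.class_params[CLASS_ORDER.index(class_label)]

    @property
    def attach_probs(self) -> tuple[float, ...]:
        return tuple(p.attach_prob for p in self.class_params)

    @property
    def cleave_thresholds(self) -> tuple[float, ...]:
        return tuple(p.cleave_threshold for p in self.class_params)

    @property
    def n_microenvironments(self) -> int:
        return self.grid_width * self.grid_height

    @property
    def tumor_mode(self) -> bool:
        return any(self.inflow_per_step)

    def with_overrides(self, **overrides) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        known = {f.name for f in fields(self)}
        unknown = sorted(set(overrides) - known)
        if unknown:
            raise ConfigError(f"unknown configuration field(s): {', '.join(unknown)}")
        return replace(self, **overrides)


def validate_affinity_ordering(config: SimulationConfig) -> None:
    """Enforce the elution-derived affinity ordering.

    The elution experiments establish that angiogenesis stimulators (LA,
    VEGF) are released from heparan sulfate at the lowest protease level,
    stabilizers (MA, PDGF-B) next, and inhibitors (HA, PF-4/TSP-1) only at
    the highest.  Cleavage thresholds must therefore be strictly increasing
    from LA to MA to HA.

    Raises
    ------
    ConfigError
        Naming the first adjacent pair of classes out of order.
    """
    params = config.class_params
    for lo, hi in zip(params, params[1:]):
        if not lo.cleave_threshold < hi.cleave_threshold:
            raise ConfigError(
                "cleave_threshold ordering violated: requires "
                f"{lo.class_label} < {hi.class_label}, got "
                f"{lo.cleave_threshold} vs {hi.cleave_threshold}"
            )
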