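"""Configuration and parameter types for the intercalary growth model.

The simulator is parameterized by four fate probabilities (p1, p2, p3 for
entering the endocycle at each of the three patterning cell cycles, p_s for
an extra stomatal-lineage division of terminal 2C cells), a cell-cycle-time
distribution, a division-asymmetry noise model, and the geometry/stopping
parameters of the generative layer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from .errors import ConfigError


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class FateProbabilities:
    """Per-cycle endocycle-entry probabilities and the stomatal division probability.

    ``p1``..``p3`` are the probabilities that a 2C cell entering the
    endocycle at the end of its first, second, or third patterning cell
    cycle; ``p_s`` is the probability that a terminal 2C cell undergoes one
    further (stomatal-lineage) division.
    """

    p1: float
    p2: float
    p3: float
    p_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p_s"):
            _check_prob(name, getattr(self, name))

    def as_dict(self) -> dict[str, float]:
        return {"p1": self.p1, "p2": self.p2, "p3": self.p3, "p_s": self.p_s}


@dataclass(frozen=True)
class CycleTimeDistribution:
    """Distribution from which each cell's cycle duration is drawn.

    Families:
      * ``lognormal`` / ``gamma``: moment-matched to ``mean_hours`` and
        ``sd_hours`` (``sd_hours=0`` degenerates to the mean exactly).
      * ``empirical``: a histogram of ``(bin_start_hours, probability)``
        pairs on a fixed-width grid (live-imaging cycle-time histograms use
        6-h bins); sampling picks a bin, then a uniform offset inside it.

    ``quantize_hours`` optionally rounds every sample up to the nearest
    multiple, emulating the finite temporal resolution of imaging data.
    """

    family: str = "lognormal"
    mean_hours: float = 24.0
    sd_hours: float = 9.0
    histogram: tuple[tuple[float, float], ...] | None = None
    bin_width_hours: float = 6.0
    quantize_hours: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gamma", "empirical"):
            raise ConfigError(f"unknown cycle-time family {self.family!r}")
        if self.family == "empirical":
            if not self.histogram:
                raise ConfigError("empirical family requires a histogram")
            object.__setattr__(
                self, "histogram", tuple((float(a), float(b)) for a, b in self.histogram)
            )
            total = sum(p for _, p in self.histogram)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"histogram probabilities sum to {total}, expected 1")
            if any(p < 0 for _, p in self.histogram):
                raise ConfigError("histogram probabilities must be nonnegative")
            if any(start < 0 for start, _ in self.histogram):
                raise ConfigError("histogram bin starts must be nonnegative")
            if self.bin_width_hours <= 0:
                raise ConfigError("bin_width_hours must be positive")
        else:
            if self.mean_hours <= 0:
                raise ConfigError("mean_hours must be positive")
            if self.sd_hours < 0:
                raise ConfigError("sd_hours must be nonnegative")
        if self.quantize_hours is not None and self.quantize_hours <= 0:
            raise ConfigError("quantize_hours must be positive when set")

    @property
    def mean(self) -> float:
        if self.family == "empirical":
            assert self.histogram is not None
            return sum(p * (start + self.bin_width_hours / 2) for start, p in self.histogram)
        return self.mean_hours

    def scaled(self, factor: float) -> "CycleTimeDistribution":
        """Return a copy with mean (and sd, for parametric families) scaled."""
        if self.family == "empirical":
            assert self.histogram is not None
            hist = tuple((start * factor, p) for start, p in self.histogram)
            return dataclasses.replace(
                self, histogram=hist, bin_width_hours=self.bin_width_hours * factor
            )
        return dataclasses.replace(
            self, mean_hours=self.mean_hours * factor, sd_hours=self.sd_hours * factor
        )


@dataclass(frozen=True)
class DivisionNoise:
    """Noise model of the division split fraction.

    The apical/first daughter receives a fraction ``s`` of the parent area,
    drawn from Normal(0.5, ``split_sd``) truncated to
    [``split_min``, ``split_max``].  The relative daughter-area deviation
    2s - 1 then has standard deviation 2*``split_sd`` (so the default
    ``split_sd=0.05`` reproduces a 10% SD in daughter areas).
    """

    split_sd: float = 0.05
    split_min: float = 0.3
    split_max: float = 0.7

    def __post_init__(self) -> None:
        if self.split_sd < 0:
            raise ConfigError("split_sd must be nonnegative")
        if not (0 < self.split_min <= 0.5):
            raise ConfigError("split_min must lie in (0, 0.5]")
        if not (0.5 <= self.split_max < 1):
            raise ConfigError("split_max must lie in [0.5, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one simulated sepal epidermis."""

    fate: FateProbabilities
    cycle_dist: CycleTimeDistribution = CycleTimeDistribution()
    noise: DivisionNoise = DivisionNoise()
    generative_width: int = 8
    target_cells: int = 1600
    doubling_time_hours: float | None = None  # defaults to cycle_dist mean
    dt_hours: float = 0.5
    initial_area: float = 100.0
    initial_aspect: float = 2.0
    seed: int = 0
    stomatal_max_rounds: int = 1
    noise_free: bool = False

    def __post_init__(self) -> None:
        if self.generative_width < 1:
            raise ConfigError("generative_width must be >= 1")
        if self.target_cells < 1:
            raise ConfigError("target_cells must be >= 1")
        if self.dt_hours <= 0:
            raise ConfigError("dt_hours must be positive")
        if self.initial_area <= 0:
            raise ConfigError("initial_area must be positive")
        if self.initial_aspect <= 0:
            raise ConfigError("initial_aspect must be positive")
        if self.stomatal_max_rounds < 0:
            raise ConfigError("stomatal_max_rounds must be >= 0")
        if self.doubling_time_hours is not None and self.doubling_time_hours <= 0:
            raise ConfigError("doubling_time_hours must be positive")
        # Scheduler resolution: the fixed step must comfortably subdivide a
        # typical cycle so at most one completion falls inside a step.
        if self.dt_hours > self.cycle_dist.mean / 4:
            raise ConfigError(
                f"dt_hours={self.dt_hours} exceeds a quarter of the mean "
                f"cycle time ({self.cycle_dist.mean} h)"
            )

    @property
    def doubling_time(self) -> float:
        return (
            self.doubling_time_hours
            if self.doubling_time_hours is not None
            else self.cycle_dist.mean
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["cycle_dist"]["histogram"] is not None:
            d["cycle_dist"]["histogram"] = [list(x) for x in d["cycle_dist"]["histogram"]]
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        data = dict(data)
        kwargs: dict[str, Any] = {}
        nested = {
            "fate": FateProbabilities,
            "cycle_dist": CycleTimeDistribution,
            "noise": DivisionNoise,
        }
        for key, sub_cls in nested.items():
            if key in data:
                sub = data.pop(key)
                if isinstance(sub, sub_cls):
                    kwargs[key] = sub
                else:
                    _reject_unknown(sub, sub_cls, key)
                    if key == "cycle_dist" and sub.get("histogram") is not None:
                        sub = dict(sub)
                        sub["histogram"] = tuple(tuple(x) for x in sub["histogram"])
                    kwargs[key] = sub_cls(**sub)
        _reject_unknown(data, cls, "config")
        kwargs.update(data)
        if "fate" not in kwargs:
            raise ConfigError("config is missing required section 'fate'")
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _reject_unknown(data: Mapping[str, Any], cls: type, where: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def load_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a TOML or JSON file."""
    path = Path(path)
    text = path.read_bytes()
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(text.decode())
    elif path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        raise ConfigError(f"unsupported config format {path.suffix!r} (use .toml or .json)")
    return SimulationConfig.from_dict(data)
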