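"""Closed-form branching ("population") model of terminal ploidy fractions.

Each patterning-lineage founder runs three cell cycles; at cycle k a 2C
cell enters the endocycle with probability p_k (irreversibly) or divides.
Commitment at cycle 1/2/3 yields a terminal 16C/8C/4C cell; never
committing yields 2^3 = 8 terminal 2C cells, each of which may undergo a
further stomatal-lineage division with probability p_s per round.  The
expected number of terminal cells per founder is therefore

    n16 = p1
    n8  = 2 (1-p1) p2
    n4  = 4 (1-p1)(1-p2) p3
    n2  = 8 (1-p1)(1-p2)(1-p3) m(rounds)

where the stomatal multiplier obeys m(0) = 1 and
m(r) = (1-p_s) + 2 p_s m(r-1) — a terminal cell that declines its stomatal
division terminates and never re-decides, so m(1) = 1 + p_s and deeper
rounds grow sub-geometrically.  The expected flow-cytometry fractions are
these counts normalized by their sum.  ``fit_probabilities`` inverts the map, recovering fate
probabilities from observed (possibly partial) ploidy fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .config import FateProbabilities
from .errors import ConfigError

PARAM_NAMES = ("p1", "p2", "p3", "p_s")
PLOIDIES = (2, 4, 8, 16)


@dataclass(frozen=True)
class PloidyFractions:
    """Terminal 2C/4C/8C/16C fractions (flow-cytometry style); sums to 1."""

    f2: float
    f4: float
    f8: float
    f16: float

    def __post_init__(self) -> None:
        vals = (self.f2, self.f4, self.f8, self.f16)
        if any(v < -1e-12 or v > 1 + 1e-12 for v in vals):
            raise ConfigError(f"fractions must be in [0, 1], got {vals}")
        total = sum(vals)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"fractions must sum to 1, got {total}")

    def as_mapping(self) -> dict[int, float]:
        return {2: self.f2, 4: self.f4, 8: self.f8, 16: self.f16}

    @classmethod
    def from_mapping(cls, m: Mapping[int, float]) -> "PloidyFractions":
        return cls(f2=m.get(2, 0.0), f4=m.get(4, 0.0), f8=m.get(8, 0.0), f16=m.get(16, 0.0))


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected terminal cells per founding patterning cell, by ploidy."""

    n2: float
    n4: float
    n8: float
    n16: float

    @property
    def total(self) -> float:
        return self.n2 + self.n4 + self.n8 + self.n16


def expected_counts(fate: FateProbabilities, stomatal_rounds: int = 1) -> ExpectedCounts:
    """Expected terminal cell counts per founder, exact closed form."""
    if stomatal_rounds < 0:
        raise ConfigError("stomatal_rounds must be >= 0")
    q1, q2, q3 = 1 - fate.p1, 1 - fate.p2, 1 - fate.p3
    m = 1.0
    for _ in range(stomatal_rounds):
        m = (1 - fate.p_s) + 2 * fate.p_s * m
    return ExpectedCounts(
        n16=fate.p1,
        n8=2 * q1 * fate.p2,
        n4=4 * q1 * q2 * fate.p3,
        n2=8 * q1 * q2 * q3 * m,
    )


def expected_ploidy_fractions(
    fate: FateProbabilities, stomatal_rounds: int = 1
) -> PloidyFractions:
    """Expected terminal ploidy fractions for given fate probabilities."""
    c = expected_counts(fate, stomatal_rounds)
    total = c.total
    if total <= 0:
        raise ConfigError("all terminal pathways closed (zero expected cells)")
    return PloidyFractions(
        f2=c.n2 / total, f4=c.n4 / total, f8=c.n8 / total, f16=c.n16 / total
    )


# ---------------------------------------------------------------------------
# Inverse fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    fate: FateProbabilities
    free: tuple[str, ...]
    residuals: dict[int, float]
    cost: float
    converged: bool
    method: str
    stomatal_rounds: int

    def as_dict(self) -> dict:
        return {
            "estimates": self.fate.as_dict(),
            "free": list(self.free),
            "residuals": {str(k): v for k, v in self.residuals.items()},
            "cost": self.cost,
            "converged": self.converged,
            "method": self.method,
            "stomatal_rounds": self.stomatal_rounds,
        }


def _normalize_observed(
    observed: "PloidyFractions | Mapping[int, float]",
) -> dict[int, float]:
    if isinstance(observed, PloidyFractions):
        return observed.as_mapping()
    obs = {int(k): float(v) for k, v in observed.items()}
    unknown = set(obs) - set(PLOIDIES)
    if unknown:
        raise ConfigError(f"unknown ploidy class(es): {sorted(unknown)}")
    if any(v < 0 or v > 1 for v in obs.values()):
        raise ConfigError("observed fractions must lie in [0, 1]")
    if len(obs) == 4:
        PloidyFractions.from_mapping(obs)  # validates the sum
    elif sum(obs.values()) > 1 + 1e-9:
        raise ConfigError("observed fractions exceed 1 in total")
    if not obs:
        raise ConfigError("no observed fractions given")
    return obs


def fit_probabilities(
    observed: "PloidyFractions | Mapping[int, float]",
    stomatal_rounds: int = 1,
    fixed: Mapping[str, float] | None = None,
    method: str = "least_squares",
    n_nuclei: int | None = None,
) -> FitResult:
    """Fit free fate probabilities to observed terminal ploidy fractions.

    ``observed`` may be a full :class:`PloidyFractions` or a partial mapping
    ``{ploidy: fraction}`` (e.g. only the 16C and 8C fractions, the two the
    flow-cytometry experiment pins down unambiguously — observed 4C mixes
    endoreduplicated cells with mitotic G2 cells).  Parameters named in
    ``fixed`` are held at the given values; the rest are estimated by
    bounded least squares on the fractions (default) or, with
    ``method="multinomial"`` and ``n_nuclei``, by maximum likelihood on
    multinomial counts.

    The number of free parameters must not exceed the number of independent
    constraints (full fractions carry 3; a partial set of m fractions
    carries m).
    """
    obs = _normalize_observed(observed)
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(PARAM_NAMES)
    if unknown:
        raise ConfigError(f"unknown fixed parameter(s): {sorted(unknown)}")
    for name, value in fixed.items():
        if not (0 <= value <= 1):
            raise ConfigError(f"fixed {name}={value} outside [0, 1]")
    free = tuple(p for p in PARAM_NAMES if p not in fixed)
    n_constraints = len(obs) - (1 if len(obs) == 4 else 0)
    if len(free) > n_constraints:
        raise ConfigError(
            f"{len(free)} free parameter(s) {free} but only "
            f"{n_constraints} independent constraint(s); fix more parameters"
        )
    keys = sorted(obs)

    def _fate(x: np.ndarray) -> FateProbabilities:
        params = dict(fixed)
        params.update({name: float(np.clip(v, 0, 1)) for name, v in zip(free, x)})
        return FateProbabilities(**params)

    def _residuals(x: np.ndarray) -> np.ndarray:
        frac = expected_ploidy_fractions(_fate(x), stomatal_rounds).as_mapping()
        return np.array([frac[k] - obs[k] for k in keys])

    if method == "least_squares":
        best = None
        grid = np.array([0.1, 0.5, 0.9])
        starts = (
            np.stack(np.meshgrid(*([grid] * len(free)), indexing="ij"), -1).reshape(
                -1, len(free)
            )
            if free
            else np.zeros((1, 0))
        )
        for x0 in starts:
            res = least_squares(
                _residuals, x0, bounds=(0.0, 1.0), xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
            if best is None or res.cost < best.cost:
                best = res
        assert best is not None
        x_hat, cost, converged = best.x, float(best.cost), bool(best.success)
    elif method == "multinomial":
        if n_nuclei is None:
            raise ConfigError("multinomial method requires n_nuclei")
        counts = {k: obs[k] * n_nuclei for k in keys}
        other = max(0.0, (1 - sum(obs.values()))) * n_nuclei if len(obs) < 4 else 0.0

        def _negloglik(x: np.ndarray) -> float:
            frac = expected_ploidy_fractions(_fate(x), stomatal_rounds).as_mapping()
            eps = 1e-12
            ll = sum(counts[k] * np.log(frac[k] + eps) for k in keys)
            if other > 0:
                rest = max(eps, 1 - sum(frac[k] for k in keys))
                ll += other * np.log(rest)
            return -ll

        best = None
        for x0 in np.linspace(0.1, 0.9, 3 if free else 1):
            res = minimize(
                _negloglik,
                np.full(len(free), x0),
                method="L-BFGS-B",
                bounds=[(1e-9, 1 - 1e-9)] * len(free),
            )
            if best is None or res.fun < best.fun:
                best = res
        assert best is not None
        x_hat, cost, converged = best.x, float(best.fun), bool(best.success)
    else:
        raise ConfigError(f"unknown fit method {method!r}")

    fate = _fate(x_hat)
    resid = _residuals(x_hat)
    return FitResult(
        fate=fate,
        free=free,
        residuals={k: float(r) for k, r in zip(keys, resid)},
        cost=cost,
        converged=converged,
        method=method,
        stomatal_rounds=stomatal_rounds,
    )


@dataclass
class BootstrapResult:
    intervals: dict[str, tuple[float, float]]
    samples: pd.DataFrame
    warnings: list[str]


def bootstrap_fit(
    observed: "PloidyFractions | Mapping[int, float]",
    n_nuclei: int,
    reps: int = 200,
    seed: int = 0,
    stomatal_rounds: int = 1,
    fixed: Mapping[str, float] | None = None,
    ci: float = 0.95,
) -> BootstrapResult:
    """Percentile confidence intervals on fitted probabilities.

    Resamples multinomial nucleus counts at the observed fractions (any
    unobserved remainder pooled into an "other" category), refits each
    replicate, and returns per-free-parameter percentile intervals.
    ``reps >= 100`` is recommended for stable interval endpoints.
    """
    if n_nuclei <= 0:
        raise ConfigError("n_nuclei must be positive")
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    obs = _normalize_observed(observed)
    keys = sorted(obs)
    warn: list[str] = []
    point = fit_probabilities(obs, stomatal_rounds, fixed)
    if any(obs[k] == 0 for k in keys):
        warn.append(
            "an observed fraction is exactly 0; the parameter it constrains "
            "is pinned to the boundary in every resample"
        )
    probs = [obs[k] for k in keys]
    rest = 1 - sum(probs)
    if rest > 1e-12:
        probs = probs + [rest]
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_nuclei, probs, size=reps)
    rows = []
    for rep in range(reps):
        frac = {k: draws[rep, i] / n_nuclei for i, k in enumerate(keys)}
        fit = fit_probabilities(frac, stomatal_rounds, fixed)
        rows.append({name: getattr(fit.fate, name) for name in point.free})
    samples = pd.DataFrame(rows)
    alpha = (1 - ci) / 2
    intervals = {
        name: (
            float(np.quantile(samples[name], alpha)),
            float(np.quantile(samples[name], 1 - alpha)),
        )
        for name in point.free
    }
    return BootstrapResult(intervals=intervals, samples=samples, warnings=warn)


def read_ploidy_fractions_csv(path: str | Path) -> dict[int, float]:
    """Read a ploidy-fraction table (columns ``ploidy_c, fraction``).

    A full four-class table must sum to 1 (validated); a partial table is
    returned as-is for partial fitting.
    """
    df = pd.read_csv(path, comment="#")
    required = {"ploidy_c", "fraction"}
    if not required.issubset(df.columns):
        raise ConfigError(
            f"ploidy CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    for i, row in df.iterrows():
        if int(row["ploidy_c"]) not in PLOIDIES:
            raise ConfigError(f"row {i}: invalid ploidy_c {row['ploidy_c']!r}")
    obs = {int(r["ploidy_c"]): float(r["fraction"]) for _, r in df.iterrows()}
    return _normalize_observed(obs)
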