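"""Preset simulation scenarios.

``wildtype`` derives (p1, p2) at runtime by fitting the branching model to
the measured epidermal flow-cytometry fractions (1.0% 16C, 5.5% 8C), with
p3 and p_s held at configured defaults.  ``lgo`` (loss of the LGO/SMR1
cell-cycle inhibitor) sets p1 = 0 — no cell commits at the first cycle, so
no 16C giant cells form — with a moderately shorter mean cycle time.
``krp1`` (epidermal KRP1 overexpression) sets p1 = 0.5, doubling early
endocycle entry, with a longer mean cycle time.  The cycle-time scale
factors (0.8x and 1.25x wild type) are package defaults, not measured
values, and can be overridden.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

from .config import CycleTimeDistribution, FateProbabilities, SimulationConfig
from .errors import ConfigError
from .ploidy import FitResult, fit_probabilities

#: Measured epidermal ploidy fractions used to pin down (p1, p2): 1.0% of
#: epidermal nuclei are 16C and 5.5% are 8C (pooled flow cytometry,
#: n = 31,744 nuclei).
WILDTYPE_OBSERVED_FRACTIONS: dict[int, float] = {16: 0.010, 8: 0.055}

#: Measured 16C fraction in pATML1::KRP1 epidermis (1.8%).
KRP1_16C_FRACTION: float = 0.018

#: Pooled nucleus count behind the wild-type fractions.
WILDTYPE_N_NUCLEI: int = 31_744

#: Defaults for the parameters the printed fractions do not constrain:
#: endocycle entry rises steeply by the third cycle (high p3), and a
#: moderate share of terminal 2C cells undergoes a stomatal division.
DEFAULT_FIXED: dict[str, float] = {"p3": 0.8, "p_s": 0.3}

SCENARIOS = ("wildtype", "lgo", "krp1")

LGO_CYCLE_SCALE = 0.8
KRP1_CYCLE_SCALE = 1.25


@lru_cache(maxsize=None)
def wildtype_fit(stomatal_rounds: int = 1) -> FitResult:
    """Fit (p1, p2) to the measured wild-type 16C/8C fractions."""
    return fit_probabilities(
        WILDTYPE_OBSERVED_FRACTIONS,
        stomatal_rounds=stomatal_rounds,
        fixed=DEFAULT_FIXED,
    )


def wildtype_fate(stomatal_rounds: int = 1) -> FateProbabilities:
    return wildtype_fit(stomatal_rounds).fate


def make_config(scenario: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` for a named scenario.

    Keyword overrides are applied on top of the scenario defaults (any
    ``SimulationConfig`` field may be overridden, including ``fate`` and
    ``cycle_dist``).
    """
    if scenario not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {scenario!r}; choose one of {', '.join(SCENARIOS)}"
        )
    base_dist = CycleTimeDistribution()
    wt = wildtype_fate()
    if scenario == "wildtype":
        fate, dist = wt, base_dist
    elif scenario == "lgo":
        fate = dataclasses.replace(wt, p1=0.0)
        dist = base_dist.scaled(LGO_CYCLE_SCALE)
    else:  # krp1
        fate = dataclasses.replace(wt, p1=0.5)
        dist = base_dist.scaled(KRP1_CYCLE_SCALE)
    # Mutant scenarios alter cycle times, not the tissue growth rate: the
    # areal doubling time is pinned at the wild-type mean cycle, which is
    # what makes shifted cycle times shift the cell-size distribution.
    kwargs = {
        "fate": fate,
        "cycle_dist": dist,
        "seed": seed,
        "doubling_time_hours": base_dist.mean,
    }
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
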