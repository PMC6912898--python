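"""Demographic scenarios, priors, and time/mutation-rate scaling.

Three backward-in-time histories for a pair of sampled populations
(SALS = saltmarsh sparrow, NESP = the sampled Nelson's sparrow lineage):

``SIMPLE_SPLIT``
    NESP splits from an ancestral Nelson's population at T2; that
    population and SALS merge into a common ancestor at T1 (T2 < T1).  The
    inland Nelson's lineage is a ghost: unsampled, no gene flow, its size
    never enters the likelihood, so it is not simulated at all.
``NE_CHANGE``
    As above, plus a piecewise-constant NESP size path: present size
    N_NESP until T_fall, N_largeNESP between T_fall and T_rise, and
    N_smallNESP from T_rise back to T2 (all backward in time).
``ADMIXTURE``
    As SIMPLE_SPLIT, plus a single admixture pulse at T_admix < T2 in
    which each sampled NESP lineage derives from the parental NESP lineage
    with probability r and from SALS with probability 1 - r.

All event times are in years; uniform priors; constraint violations are
resolved by whole-vector rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Scenario(str, Enum):
    SIMPLE_SPLIT = "SIMPLE_SPLIT"
    NE_CHANGE = "NE_CHANGE"
    ADMIXTURE = "ADMIXTURE"


@dataclass(frozen=True)
class ScalingConstants:
    """Mutation-rate and generation-time scaling.

    The per-generation mutation rate is derived from a substitution rate in
    units of substitutions/site/Myr and a generation time in years.
    """

    substitution_rate_per_myr: float = 3.3e-3
    generation_time_years: float = 2.3

    @property
    def mutation_rate_per_generation(self) -> float:
        return mutation_rate_per_generation(self)


def mutation_rate_per_generation(constants: ScalingConstants) -> float:
    """subs/site/Myr x 1e-6 x years/generation -> subs/site/generation."""
    return constants.substitution_rate_per_myr * 1e-6 * constants.generation_time_years


def years_to_generations(t_years: float, generation_time: float) -> float:
    if generation_time <= 0:
        raise ValueError("generation time must be positive")
    return t_years / generation_time


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

# uniform bounds, times in years, sizes in diploid individuals
DEFAULT_PRIORS: dict[str, tuple[float, float]] = {
    "T1": (400_000, 1_500_000),
    "T2": (100_000, 500_000),
    "N_SALS": (20_000, 150_000),
    "N_NESP": (1_000, 50_000),
    "N_AncestralNESP": (1_000, 150_000),
    "N_Ancestral": (100_000, 500_000),
    # NE_CHANGE only
    "T_rise": (50_000, 200_000),
    "T_fall": (10_000, 50_000),
    "N_smallNESP": (1_000, 50_000),
    "N_largeNESP": (50_000, 100_000),
    # ADMIXTURE only
    "T_admix": (0, 100_000),
    "r": (0.001, 0.999),
}

SCENARIO_PARAMS: dict[Scenario, tuple[str, ...]] = {
    Scenario.SIMPLE_SPLIT: ("T1", "T2", "N_SALS", "N_NESP", "N_AncestralNESP", "N_Ancestral"),
    Scenario.NE_CHANGE: ("T1", "T2", "N_SALS", "N_NESP", "N_AncestralNESP", "N_Ancestral",
                         "T_rise", "T_fall", "N_smallNESP", "N_largeNESP"),
    Scenario.ADMIXTURE: ("T1", "T2", "N_SALS", "N_NESP", "N_AncestralNESP", "N_Ancestral",
                         "T_admix", "r"),
}


@dataclass
class PriorSet:
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_PRIORS))

    def low_high(self, names: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in names], dtype=float)
        hi = np.array([self.bounds[n][1] for n in names], dtype=float)
        return lo, hi


def _constraints_ok(scenario: Scenario, p: dict[str, float]) -> bool:
    if not p["T2"] < p["T1"]:
        return False
    if scenario is Scenario.NE_CHANGE:
        if not (p["T_fall"] < p["T_rise"] < p["T2"]):
            return False
    if scenario is Scenario.ADMIXTURE:
        if not p["T_admix"] < p["T2"]:
            return False
    return True


def sample_prior(
    scenario: Scenario,
    priors: PriorSet | None = None,
    rng: np.random.Generator | int | None = None,
    max_tries: int = 100_000,
) -> dict[str, float]:
    """Draw one parameter vector; rejection enforces the time orderings."""
    priors = priors or PriorSet()
    rng = np.random.default_rng(rng)
    names = SCENARIO_PARAMS[scenario]
    lo, hi = priors.low_high(names)
    for _ in range(max_tries):
        draw = dict(zip(names, rng.uniform(lo, hi)))
        if _constraints_ok(scenario, draw):
            return draw
    raise RuntimeError(f"could not satisfy prior constraints for {scenario} "
                       f"after {max_tries} draws")


# ---------------------------------------------------------------------------
# event-table compilation (for the coalescent kernel)
# ---------------------------------------------------------------------------

# population indices inside the kernel
POP_SALS, POP_NESP, POP_ANC_NESP, POP_ANCESTOR = 0, 1, 2, 3
N_POPS = 4

# breakpoint event codes
EV_SIZE_ONLY = 0
EV_ADMIX = 1          # NESP lineages -> NESP w.p. r, else SALS
EV_NESP_TO_ANC = 2    # NESP -> ancestral NESP
EV_FINAL_MERGE = 3    # SALS + ancestral NESP -> ancestor


@dataclass
class EventTable:
    """Compiled, generation-scaled history for the structured coalescent.

    ``times`` are ascending breakpoints (generations); ``types`` the event
    applied on reaching each breakpoint; ``sizes[e, p]`` the diploid size
    of population p during epoch e (epoch e spans times[e-1]..times[e],
    with epoch 0 starting at 0 and the last epoch unbounded).
    """

    times: np.ndarray
    types: np.ndarray
    sizes: np.ndarray
    admix_r: float


def build_event_table(
    scenario: Scenario,
    params: dict[str, float],
    constants: ScalingConstants | None = None,
) -> EventTable:
    constants = constants or ScalingConstants()
    g = constants.generation_time_years
    if not _constraints_ok(scenario, {**params}):
        raise ValueError(f"parameters violate {scenario} ordering constraints")
    for k, v in params.items():
        if k.startswith("N_") and v <= 0:
            raise ValueError(f"non-positive population size {k}={v}")

    T1 = years_to_generations(params["T1"], g)
    T2 = years_to_generations(params["T2"], g)
    events: list[tuple[float, int]] = []
    admix_r = 0.0
    if scenario is Scenario.ADMIXTURE:
        events.append((years_to_generations(params["T_admix"], g), EV_ADMIX))
        admix_r = float(params["r"])
    if scenario is Scenario.NE_CHANGE:
        events.append((years_to_generations(params["T_fall"], g), EV_SIZE_ONLY))
        events.append((years_to_generations(params["T_rise"], g), EV_SIZE_ONLY))
    events.append((T2, EV_NESP_TO_ANC))
    events.append((T1, EV_FINAL_MERGE))
    events.sort(key=lambda e: e[0])

    times = np.array([t for t, _ in events], dtype=np.float64)
    types = np.array([k for _, k in events], dtype=np.int64)
    n_epochs = len(events) + 1
    sizes = np.ones((n_epochs, N_POPS), dtype=np.float64)
    # epoch boundaries in generations, for the NESP size path
    starts = np.concatenate([[0.0], times])
    for e in range(n_epochs):
        t0 = starts[e]
        sizes[e, POP_SALS] = params["N_SALS"]
        sizes[e, POP_ANC_NESP] = params["N_AncestralNESP"]
        sizes[e, POP_ANCESTOR] = params["N_Ancestral"]
        if scenario is Scenario.NE_CHANGE:
            t_fall = years_to_generations(params["T_fall"], g)
            t_rise = years_to_generations(params["T_rise"], g)
            if t0 < t_fall:
                sizes[e, POP_NESP] = params["N_NESP"]
            elif t0 < t_rise:
                sizes[e, POP_NESP] = params["N_largeNESP"]
            else:
                sizes[e, POP_NESP] = params["N_smallNESP"]
        else:
            sizes[e, POP_NESP] = params["N_NESP"]
    return EventTable(times=times, types=types, sizes=sizes, admix_r=admix_r)
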