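"""Forward-time simulation of the serial-transfer sporulation-bottleneck experiment.

Each cycle: vegetative growth (with an optional shared carrying capacity),
strain-specific sporulation, heat kill of vegetative cells, and a multinomial
transfer bottleneck acting on the survivors.  Surviving spores germinate and
seed the next cycle.  The census used for sequencing is taken after growth,
before the heat treatment.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from ..errors import InvalidInputError
from .panel import StrainGenotype


def _as_per_strain(value: float | Sequence[float], n: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise InvalidInputError(f"{name} must be scalar or length-{n}, got shape {arr.shape}")
    return arr


@dataclass
class SimulationParams:
    """Free parameters of the simulated experiment.

    ``growth_yield`` and ``sporulation_fraction`` may be scalars (shared) or
    per-strain sequences.  Defaults are neutral: every strain behaves alike.
    """

    growth_yield: float | Sequence[float] = 20.0
    sporulation_fraction: float | Sequence[float] = 0.5
    heat_kill_survival_vegetative: float = 0.0
    dilution_fraction: float = 1.0 / 20.0
    n_cycles: int = 9
    carrying_capacity: float | None = None
    initial_population: int = 1_000_000
    error_rate: float = 0.0
    depth: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.heat_kill_survival_vegetative <= 1.0:
            raise InvalidInputError("heat_kill_survival_vegetative must be in [0, 1]")
        if not 0.0 < self.dilution_fraction <= 1.0:
            raise InvalidInputError("dilution_fraction must be in (0, 1]")
        if self.n_cycles < 0:
            raise InvalidInputError("n_cycles must be >= 0")
        if self.depth < 0:
            raise InvalidInputError("depth must be >= 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise InvalidInputError("error_rate must be in [0, 1)")
        sf = np.atleast_1d(np.asarray(self.sporulation_fraction, dtype=float))
        if ((sf < 0) | (sf > 1)).any():
            raise InvalidInputError("sporulation_fraction values must be in [0, 1]")
        gy = np.atleast_1d(np.asarray(self.growth_yield, dtype=float))
        if (gy < 0).any():
            raise InvalidInputError("growth_yield values must be >= 0")
        if self.initial_population < 1:
            raise InvalidInputError("initial_population must be >= 1")

    # -- config file round trip ------------------------------------------------
    def to_yaml(self, path) -> None:
        data = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PopulationState:
    """Per-strain vegetative and spore counts between simulated wet-lab steps."""

    vegetative: np.ndarray
    spores: np.ndarray
    cycle_index: int = 0
    extinct: bool = False

    def __post_init__(self) -> None:
        self.vegetative = np.asarray(self.vegetative, dtype=np.int64)
        self.spores = np.asarray(self.spores, dtype=np.int64)
        if (self.vegetative < 0).any() or (self.spores < 0).any():
            raise InvalidInputError("population counts must be non-negative")
        if self.vegetative.shape != self.spores.shape:
            raise InvalidInputError("vegetative and spore arrays must have the same shape")

    @property
    def total(self) -> int:
        return int(self.vegetative.sum() + self.spores.sum())


@dataclass
class CycleOutcome:
    state: PopulationState
    census: np.ndarray  # post-growth, pre-heat composition (what gets sequenced)


def stream_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-(mix, replicate, cycle, ...) generator from one root seed.

    String keys are hashed with CRC-32 so streams are stable across platforms.
    """
    ints = [seed & 0xFFFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


def simulate_cycle(
    state: PopulationState,
    params: SimulationParams,
    rng: np.random.Generator,
    yield_multiplier: np.ndarray | None = None,
) -> CycleOutcome:
    """One growth / sporulation / heat-kill / bottleneck cycle.

    Extinction (zero survivors) is flagged on the returned state rather than
    raised.  ``yield_multiplier`` hooks in acquired-mutation effects as a
    per-strain scalar on this cycle's growth yield.
    """
    n = state.vegetative.shape[0]
    gy = _as_per_strain(params.growth_yield, n, "growth_yield")
    if yield_multiplier is not None:
        gy = gy * _as_per_strain(yield_multiplier, n, "yield_multiplier")
    sf = _as_per_strain(params.sporulation_fraction, n, "sporulation_fraction")

    if state.total <= 0:
        zero = np.zeros(n, dtype=np.int64)
        return CycleOutcome(
            PopulationState(zero, zero, state.cycle_index + 1, extinct=True), zero.copy()
        )

    # 1) growth: deterministic expansion, jointly rescaled to carrying capacity
    grown_f = state.vegetative.astype(float) * gy
    if params.carrying_capacity is not None:
        total = grown_f.sum() + state.spores.sum()
        if total > params.carrying_capacity:
            grown_f *= params.carrying_capacity / total
    grown = np.rint(grown_f).astype(np.int64)
    census = grown + state.spores

    # 2) sporulation: strain-specific binomial draw
    new_spores = rng.binomial(grown, sf)
    veg_left = grown - new_spores

    # 3) heat kill: vegetative survivors (default none); dormant spores persist
    veg_surv = rng.binomial(veg_left, params.heat_kill_survival_vegetative)
    survivors = new_spores + veg_surv + state.spores

    # 4) bottleneck: volume transfer of a well-mixed suspension
    total_surv = int(survivors.sum())
    if total_surv == 0:
        zero = np.zeros(n, dtype=np.int64)
        return CycleOutcome(
            PopulationState(zero, zero, state.cycle_index + 1, extinct=True), census
        )
    n_transfer = rng.binomial(total_surv, params.dilution_fraction)
    if n_transfer == 0:
        zero = np.zeros(n, dtype=np.int64)
        return CycleOutcome(
            PopulationState(zero, zero, state.cycle_index + 1, extinct=True), census
        )
    sampled = rng.multinomial(n_transfer, survivors / total_surv)
    # transferred spores germinate into vegetative cells of the next cycle
    next_state = PopulationState(
        vegetative=sampled,
        spores=np.zeros(n, dtype=np.int64),
        cycle_index=state.cycle_index + 1,
    )
    return CycleOutcome(next_state, census)


@dataclass
class Trajectory:
    """Per-cycle censuses of one simulated population."""

    strain_ids: list[str]
    censuses: list[np.ndarray]  # index 0 = inoculum; k>=1 = post-growth of cycle k
    extinct_at: int | None = None
    generations: list[float] = field(default_factory=list)

    @property
    def frequencies(self) -> pd.DataFrame:
        rows = []
        for cyc, census in enumerate(self.censuses):
            total = census.sum()
            freq = census / total if total > 0 else np.zeros_like(census, dtype=float)
            rows.append(freq)
        return pd.DataFrame(rows, columns=self.strain_ids).rename_axis("cycle")

    @property
    def final_frequencies(self) -> pd.Series:
        return self.frequencies.iloc[-1]


def simulate_experiment(
    panel: list[StrainGenotype],
    params: SimulationParams,
    rng: np.random.Generator | None = None,
    yield_modifier: Callable[[int], np.ndarray | None] | None = None,
) -> Trajectory:
    """Run ``n_cycles`` from an equal-ratio inoculum, recording each census.

    The census is recorded after the growth step of every cycle (before heat
    treatment), mirroring when DNA was sampled for sequencing.  Generations per
    cycle are reported as log2 of the population fold-expansion.
    """
    if not panel:
        raise InvalidInputError("panel must be non-empty")
    if rng is None:
        rng = stream_rng(params.seed, "experiment")
    n = len(panel)
    per_strain = params.initial_population // n
    inoculum = np.full(n, per_strain, dtype=np.int64)
    state = PopulationState(inoculum.copy(), np.zeros(n, dtype=np.int64))
    traj = Trajectory(
        strain_ids=[g.strain_id for g in panel], censuses=[inoculum.copy()]
    )
    for cyc in range(params.n_cycles):
        mult = yield_modifier(cyc) if yield_modifier is not None else None
        before = state.total
        outcome = simulate_cycle(state, params, rng, yield_multiplier=mult)
        traj.censuses.append(outcome.census)
        if before > 0:
            traj.generations.append(float(np.log2(outcome.census.sum() / before)))
        state = outcome.state
        if state.extinct and traj.extinct_at is None:
            traj.extinct_at = state.cycle_index
    return traj


# -- qualitative scenario presets ---------------------------------------------

def scenario_params(name: str, n_strains: int, focal: int = 0, **overrides) -> SimulationParams:
    """Named per-strain parameter presets for one focal strain against a
    uniform background.

    ``neutral``          — everyone identical.
    ``early_sporulator`` — focal strain sporulates much more readily.
    ``late_sporulator``  — focal strain grows longer but sporulates less.
    ``growth_deficient`` — focal strain has half the growth yield.
    """
    gy = np.full(n_strains, 20.0)
    sf = np.full(n_strains, 0.5)
    if name == "neutral":
        pass
    elif name == "early_sporulator":
        sf[:] = 0.3
        sf[focal] = 0.9
    elif name == "late_sporulator":
        gy[focal] = 30.0
        sf[focal] = 0.25
    elif name == "growth_deficient":
        gy[focal] = 10.0
    else:
        raise InvalidInputError(f"unknown scenario {name!r}")
    return SimulationParams(growth_yield=gy, sporulation_fraction=sf, **overrides)
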