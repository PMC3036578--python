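"""Individual-based life cycle and forward-time simulation.

Each generation proceeds in a fixed order: random mating and reproduction
(with recombination and mutation), death of all parents (generations do not
overlap), viability selection against the current environment, and random
culling to the carrying capacity.  Population-level quantitative-genetics
summaries (phenotypic variance, mid-parent heritability, additive variance)
are recorded every generation.

Fitness is a generalized-Gaussian function of the phenotype-environment
mismatch, ``RF = exp(-(|E - z| / s)**omega)``: ``omega`` tunes the breadth of
the selection function (1.5 = high tolerance for a mismatch, 2.5 = low
tolerance; Gaussian at ``omega = 2``) and ``s`` is the mismatch scale in
trait units.

The population is held internally as flat arrays (one row per individual) so
that a whole generation is a handful of vectorised operations; the
list-of-:class:`Individual` operations exposed here are thin adapters over
the same kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import genotype as gt
from .genotype import (
    InvalidParameterError,
    LinearChromosome,
    NetworkChromosome,
)

__all__ = [
    "Individual",
    "EnvironmentSchedule",
    "SimulationConfig",
    "GenerationRecord",
    "SimulationResult",
    "relative_fitness",
    "reproduce",
    "viability_select",
    "cull_to_capacity",
    "step_generation",
    "run_simulation",
    "load_config",
]

H2_CLAMP = (0.0, 1.5)  # guard against pathological regression slopes


@dataclass
class Individual:
    """One organism: its genotype, trait value, and pedigree record."""

    chromosome: NetworkChromosome | LinearChromosome
    phenotype: float
    rel_fitness: float | None = None
    midparent: float | None = None  # mean parental phenotype; None for founders


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Piecewise-constant environment with at most one downward step.

    ``mode`` is one of ``constant``, ``step_at_generation`` (the step lands
    at ``change_generation``, i.e. that generation is the first lived under
    the new value), or ``step_at_va_threshold`` (the step fires one
    generation after the population's additive variance first reaches
    ``va_threshold``; runs whose threshold is never reached are terminated,
    flagged, at ``horizon``).
    """

    initial: float = 70.0
    mode: Literal["constant", "step_at_generation", "step_at_va_threshold"] = "constant"
    delta: float = 0.0
    change_generation: int = 251
    va_threshold: float | None = None
    horizon: int = 1000
    post_change_generations: int = 750  # trigger mode: run length after firing

    def value_at(self, generation: int) -> float:
        if self.mode == "step_at_generation" and generation >= self.change_generation:
            return self.initial - self.delta
        return self.initial


@dataclass(frozen=True)
class SimulationConfig:
    """Complete parameterisation of one simulation run."""

    architecture: Literal["network", "linear"] = "network"
    n: int = 16
    topology: gt.Topology = "random"
    mu: float = 1e-4
    r: float = 0.5
    omega: float = 2.0
    fitness_scale: float = 10.0
    env_range: float = gt.ENV_RANGE
    K: int = 500
    founders: int | None = None  # defaults to K
    offspring_lambda: float = 1.5
    env: EnvironmentSchedule = field(default_factory=EnvironmentSchedule)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu", "r"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if self.omega <= 0:
            raise InvalidParameterError("omega must be positive")
        if self.offspring_lambda < 0:
            raise InvalidParameterError("offspring lambda must be non-negative")
        if self.K < 1:
            raise InvalidParameterError("carrying capacity must be >= 1")

    @property
    def n_founders(self) -> int:
        return self.K if self.founders is None else self.founders


@dataclass(frozen=True)
class GenerationRecord:
    """Per-generation population summary."""

    generation: int
    pop_size: int
    mean_phenotype: float
    V_P: float
    h2: float  # clamped mid-parent slope; NaN when undefined
    h2_raw: float
    V_A: float
    env: float
    extinct: bool = False
    changed: bool = False


@dataclass
class SimulationResult:
    """Full time series of a run plus schedule metadata."""

    records: list[GenerationRecord]
    config: SimulationConfig
    change_generation: int | None  # first generation lived under the new value
    fired: bool  # trigger-mode: whether the step occurred
    extinct: bool
    truncated: bool = False  # trigger never fired before the cutoff

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": [r.generation for r in self.records],
                "pop_size": [r.pop_size for r in self.records],
                "mean_phenotype": [r.mean_phenotype for r in self.records],
                "V_P": [r.V_P for r in self.records],
                "h2": [r.h2 for r in self.records],
                "h2_raw": [r.h2_raw for r in self.records],
                "V_A": [r.V_A for r in self.records],
                "env": [r.env for r in self.records],
                "extinct_flag": [r.extinct for r in self.records],
                "changed_flag": [r.changed for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def relative_fitness(
    phenotype: float | np.ndarray,
    env: float,
    omega: float,
    scale: float = 10.0,
) -> float | np.ndarray:
    """Viability fitness ``exp(-(|env - z| / scale)**omega)`` in (0, 1]."""
    if omega <= 0:
        raise InvalidParameterError("omega must be positive")
    delta = np.abs(np.asarray(phenotype, dtype=float) - env)
    rf = np.exp(-((delta / scale) ** omega))
    if np.isscalar(phenotype) or np.ndim(phenotype) == 0:
        return float(rf)
    return rf


# ---------------------------------------------------------------------------
# internal array population
# ---------------------------------------------------------------------------

@dataclass
class _Pop:
    """Flat-array population state (one row per individual)."""

    arch: str
    heads: np.ndarray | None
    funcs: np.ndarray | None
    root: np.ndarray | None
    bits: np.ndarray | None
    phenotype: np.ndarray
    midparent: np.ndarray  # NaN for founders

    @property
    def size(self) -> int:
        return self.phenotype.size

    def take(self, idx: np.ndarray) -> "_Pop":
        if self.arch == "network":
            return _Pop(
                self.arch, self.heads[idx], self.funcs[idx], self.root[idx],
                None, self.phenotype[idx], self.midparent[idx],
            )
        return _Pop(
            self.arch, None, None, None, self.bits[idx],
            self.phenotype[idx], self.midparent[idx],
        )


def _founders(config: SimulationConfig, rng: np.random.Generator) -> _Pop:
    m = config.n_founders
    if config.architecture == "network":
        heads, funcs, root = gt.build_networks_batch(config.n, config.topology, m, rng)
        ph = gt.phenotype_network_batch(heads, funcs, root, config.env_range)
        return _Pop("network", heads, funcs, root, None, ph, np.full(m, np.nan))
    bits = rng.integers(0, 2, size=(m, config.n), dtype=np.int8)
    ph = gt.phenotype_linear_batch(bits, config.env_range)
    return _Pop("linear", None, None, None, bits, ph, np.full(m, np.nan))


def _reproduce_arrays(
    pop: _Pop, config: SimulationConfig, rng: np.random.Generator
) -> _Pop:
    """Random mating: every individual initiates one mating with a uniformly
    chosen other individual; offspring per mating ~ Poisson(lambda)."""
    m = pop.size
    if m < 2:
        return pop.take(np.empty(0, dtype=np.int64))
    partner = rng.integers(0, m - 1, size=m)
    partner += partner >= np.arange(m)  # exclude selfing
    counts = rng.poisson(config.offspring_lambda, size=m)
    mom = np.repeat(np.arange(m), counts)
    dad = np.repeat(partner, counts)
    midparent = 0.5 * (pop.phenotype[mom] + pop.phenotype[dad])
    if mom.size == 0:
        return pop.take(np.empty(0, dtype=np.int64))
    if pop.arch == "network":
        heads, funcs, root = gt.recombine_network_batch(
            pop.heads, pop.funcs, pop.root, mom, dad, config.r, rng
        )
        heads, funcs, root = gt.mutate_network_batch(heads, funcs, root, config.mu, rng)
        ph = gt.phenotype_network_batch(heads, funcs, root, config.env_range)
        return _Pop("network", heads, funcs, root, None, ph, midparent)
    bits = gt.recombine_linear_batch(pop.bits, mom, dad, config.r, rng)
    bits = gt.mutate_linear_batch(bits, config.mu, rng)
    ph = gt.phenotype_linear_batch(bits, config.env_range)
    return _Pop("linear", None, None, None, bits, ph, midparent)


def _viability_arrays(
    pop: _Pop, env: float, config: SimulationConfig, rng: np.random.Generator
) -> tuple[_Pop, np.ndarray]:
    rf = relative_fitness(pop.phenotype, env, config.omega, config.fitness_scale)
    rf = np.atleast_1d(np.asarray(rf, dtype=float))
    survive = rf >= rng.random(pop.size)
    return pop.take(np.nonzero(survive)[0]), rf


def _cull_arrays(pop: _Pop, K: int, rng: np.random.Generator) -> _Pop:
    if pop.size <= K:
        return pop
    keep = rng.choice(pop.size, size=K, replace=False)
    return pop.take(np.sort(keep))


def _midparent_slope(mid: np.ndarray, off: np.ndarray) -> float:
    """OLS slope of offspring phenotype on mid-parent phenotype (NaN if degenerate)."""
    ok = np.isfinite(mid) & np.isfinite(off)
    mid, off = mid[ok], off[ok]
    if mid.size < 3:
        return np.nan
    vx = mid.var()
    if vx == 0.0:
        return np.nan
    return float(((mid - mid.mean()) * (off - off.mean())).mean() / vx)


def _record(pop: _Pop, generation: int, env: float, changed: bool) -> GenerationRecord:
    if pop.size == 0:
        return GenerationRecord(
            generation, 0, np.nan, np.nan, np.nan, np.nan, np.nan, env,
            extinct=True, changed=changed,
        )
    vp = float(pop.phenotype.var(ddof=1)) if pop.size > 1 else 0.0
    h2_raw = _midparent_slope(pop.midparent, pop.phenotype)
    h2 = float(np.clip(h2_raw, *H2_CLAMP)) if np.isfinite(h2_raw) else np.nan
    va = h2 * vp if np.isfinite(h2) else np.nan
    return GenerationRecord(
        generation, pop.size, float(pop.phenotype.mean()), vp, h2, h2_raw, va,
        env, extinct=False, changed=changed,
    )


def _step_arrays(
    pop: _Pop,
    env: float,
    config: SimulationConfig,
    rngs: dict[str, np.random.Generator],
) -> _Pop:
    offspring = _reproduce_arrays(pop, config, rngs["mating"])
    # parents die here: only offspring proceed (non-overlapping generations)
    survivors, _ = _viability_arrays(offspring, env, config, rngs["selection"])
    return _cull_arrays(survivors, config.K, rngs["culling"])


def _spawn_streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("founders", "mating", "selection", "culling")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


# ---------------------------------------------------------------------------
# Individual-level API (adapters over the array kernels)
# ---------------------------------------------------------------------------

def _to_pop(population: Sequence[Individual], config: SimulationConfig) -> _Pop:
    m = len(population)
    mid = np.array(
        [np.nan if ind.midparent is None else ind.midparent for ind in population]
    )
    ph = np.array([ind.phenotype for ind in population], dtype=float)
    if config.architecture == "network":
        nm1 = config.n - 1
        heads = np.empty((m, nm1), dtype=np.int64)
        funcs = np.empty((m, nm1), dtype=np.int8)
        root = np.empty(m, dtype=np.int8)
        for i, ind in enumerate(population):
            heads[i] = ind.chromosome.heads
            funcs[i] = ind.chromosome.functions
            root[i] = ind.chromosome.root_state
        return _Pop("network", heads, funcs, root, None, ph, mid)
    bits = np.stack([ind.chromosome.bits for ind in population]) if m else \
        np.empty((0, config.n), dtype=np.int8)
    return _Pop("linear", None, None, None, bits, ph, mid)


def _to_individuals(pop: _Pop) -> list[Individual]:
    out = []
    for i in range(pop.size):
        if pop.arch == "network":
            chrom = NetworkChromosome(
                pop.heads[i].copy(), pop.funcs[i].copy(), int(pop.root[i])
            )
        else:
            chrom = LinearChromosome(pop.bits[i].copy())
        mid = pop.midparent[i]
        out.append(
            Individual(chrom, float(pop.phenotype[i]),
                       midparent=None if np.isnan(mid) else float(mid))
        )
    return out


def reproduce(
    population: Sequence[Individual],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[Individual]:
    """Random-mating reproduction; empty if fewer than two individuals."""
    if len(population) < 2:
        return []
    return _to_individuals(_reproduce_arrays(_to_pop(population, config), config, rng))


def viability_select(
    offspring: Sequence[Individual],
    env: float,
    omega: float,
    rng: np.random.Generator,
    scale: float = 10.0,
) -> list[Individual]:
    """Keep each individual iff its relative fitness >= an independent U(0,1)."""
    survivors = []
    for ind in offspring:
        rf = float(relative_fitness(ind.phenotype, env, omega, scale))
        ind.rel_fitness = rf
        if rf >= rng.random():
            survivors.append(ind)
    return survivors


def cull_to_capacity(
    survivors: Sequence[Individual], K: int, rng: np.random.Generator
) -> list[Individual]:
    """Randomly remove individuals until at most ``K`` remain."""
    if K < 1:
        raise InvalidParameterError("carrying capacity must be >= 1")
    if len(survivors) <= K:
        return list(survivors)
    keep = rng.choice(len(survivors), size=K, replace=False)
    return [survivors[i] for i in np.sort(keep)]


def step_generation(
    population: Sequence[Individual],
    env: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    generation: int = 0,
    changed: bool = False,
) -> tuple[list[Individual], GenerationRecord]:
    """Advance one full life cycle and summarise the resulting generation."""
    rngs = {"mating": rng, "selection": rng, "culling": rng}
    new = _step_arrays(_to_pop(population, config), env, config, rngs)
    return _to_individuals(new), _record(new, generation, env, changed)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

def run_simulation(
    config: SimulationConfig,
    stop_after_recovery: bool = False,
    baseline_window: int = 50,
) -> SimulationResult:
    """Run a complete forward-time simulation under the environment schedule.

    The first record describes the founder population; every later record is
    the population after one full life cycle.  The run ends at the schedule's
    horizon, at extinction, or — in trigger mode — ``post_change_generations``
    after the additive-variance threshold fires (runs whose threshold is
    never reached stop, flagged as truncated, at the horizon).  Fully
    reproducible from ``config.seed``.

    ``stop_after_recovery`` ends the run early once the post-change
    population size first returns to the mean size of the ``baseline_window``
    generations preceding the change — everything needed to score recovery
    has been observed by then.
    """
    sched = config.env
    rngs = _spawn_streams(config.seed)
    pop = _founders(config, rngs["founders"])

    trigger = sched.mode == "step_at_va_threshold"
    fired = False
    change_gen: int | None = None
    if sched.mode == "step_at_generation":
        change_gen = sched.change_generation

    founder_rec = _record(pop, 1, sched.initial, changed=False)
    if config.architecture == "linear" and founder_rec.pop_size > 1:
        # iid loci, no environmental variance: the founder trait is exactly
        # additive, so h2 = 1 and V_A = V_P by construction (not estimated)
        founder_rec = replace(
            founder_rec, h2=1.0, h2_raw=1.0, V_A=founder_rec.V_P
        )
    records = [founder_rec]
    last_va = np.nan  # carried-forward V_A for the trigger check
    if np.isfinite(records[0].V_A):
        last_va = records[0].V_A

    horizon = sched.horizon
    gen = 1
    while gen < horizon:
        gen += 1
        if trigger and not fired and np.isfinite(last_va) and \
                sched.va_threshold is not None and last_va >= sched.va_threshold:
            fired = True
            change_gen = gen
            horizon = min(horizon, gen + sched.post_change_generations - 1)
        if trigger:
            env = sched.initial - sched.delta if fired else sched.initial
        else:
            env = sched.value_at(gen)
        changed = change_gen is not None and gen >= change_gen and (
            fired or sched.mode == "step_at_generation"
        )
        pop = _step_arrays(pop, env, config, rngs)
        rec = _record(pop, gen, env, changed)
        records.append(rec)
        if np.isfinite(rec.V_A):
            last_va = rec.V_A
        if rec.extinct:
            break
        if (
            stop_after_recovery
            and change_gen is not None
            and gen > change_gen
            and change_gen > baseline_window
        ):
            base = np.mean(
                [r.pop_size for r in records[change_gen - 1 - baseline_window : change_gen - 1]]
            )
            if rec.pop_size >= base:
                break

    extinct = records[-1].extinct
    truncated = trigger and not fired and not extinct
    return SimulationResult(
        records=records,
        config=config,
        change_generation=change_gen if (fired or sched.mode == "step_at_generation") else None,
        fired=fired,
        extinct=extinct,
        truncated=truncated,
    )


def load_config(path: str) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML or JSON file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    env_raw = raw.pop("env", None)
    env = EnvironmentSchedule(**env_raw) if env_raw else EnvironmentSchedule()
    return SimulationConfig(env=env, **raw)
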