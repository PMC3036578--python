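"""Directional epistasis assayed on single- and double-mutant networks.

For a randomly generated wild-type network, two distinct point mutations are
drawn from one mutation-location class — *function* (an activator/repressor
bit flips) or *topology* (a gene is rewired to a different upstream
regulator) — yielding a quartet: wild type, each single mutant, and the
double mutant.  Each member's viability fitness is evaluated against a fixed
reference environment, and epistasis is the deviation of the double mutant
from multiplicative expectation on raw fitnesses::

    epsilon = w_ab - w_a * w_b

Because fitnesses live in (0, 1], a pair of phenotypically neutral mutations
on a sub-optimal wild type (fitness w < 1) gives ``epsilon = w - w² > 0`` —
a structural positive bias of the assay that the experiment quantifies.

Group summaries weight epsilon by its within-network-size standard deviation
(to homogenise variances across sizes); unweighted means are reported
alongside, since the sign of the size trend depends on the weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genotype as gt
from .genotype import InvalidParameterError, NetworkChromosome
from .popdyn import relative_fitness

__all__ = [
    "DegenerateWeightError",
    "EpistasisTable",
    "SIGN_TOLERANCE",
    "DEFAULT_SIZES",
    "MUTATION_CLASSES",
    "make_mutant_quartet",
    "epsilon",
    "run_epistasis_experiment",
    "weighted_epistasis",
    "sign_fractions",
]

SIGN_TOLERANCE = 1e-12  # |epsilon| below this counts as no epistasis
DEFAULT_SIZES = (8, 16, 32, 64, 128, 256)
MUTATION_CLASSES = ("function", "topology")


class DegenerateWeightError(ValueError):
    """Within-size standard deviation is zero; weights are undefined."""


@dataclass
class EpistasisTable:
    """Full table of epistasis runs plus experiment metadata."""

    runs: pd.DataFrame
    meta: dict = field(default_factory=dict)


def _draw_point_mutation(
    chrom: NetworkChromosome, location_class: str, element: int,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Resolve one point mutation to a (field, gene, new value) triple.

    ``element`` indexes the class's mutable elements: function bits of genes
    1..n-1 for the *function* class; heads of genes 2..n-1 (gene 1's head is
    fixed) for the *topology* class.  The same triple applies identically in
    the single and the double mutant.
    """
    if location_class == "function":
        gene = element + 1
        return "functions", gene, int(chrom.functions[gene - 1]) ^ 1
    gene = element + 2
    u = int(rng.integers(0, gene - 1))
    return "heads", gene, u + (u >= int(chrom.heads[gene - 1]))


def _apply(chrom: NetworkChromosome, mutation: tuple[str, int, int]) -> None:
    arr_name, gene, value = mutation
    getattr(chrom, arr_name)[gene - 1] = value


def make_mutant_quartet(
    chrom: NetworkChromosome,
    location_class: str,
    rng: np.random.Generator,
) -> tuple[NetworkChromosome, NetworkChromosome, NetworkChromosome, NetworkChromosome]:
    """Build (wild type, mutant A, mutant B, double mutant AB).

    Two distinct mutable elements of ``location_class`` are chosen at random;
    A carries the first mutation, B the second, AB both.  A topology mutation
    redraws the gene's regulator uniformly among the lower-index genes
    excluding the current one, so acyclicity is preserved.
    """
    if location_class not in MUTATION_CLASSES:
        raise InvalidParameterError(f"unknown mutation class {location_class!r}")
    n_elements = chrom.n - 1 if location_class == "function" else chrom.n - 2
    if n_elements < 2:
        raise InvalidParameterError(
            f"need at least two mutable {location_class} elements (n too small)"
        )
    e1, e2 = rng.choice(n_elements, size=2, replace=False)
    m1 = _draw_point_mutation(chrom, location_class, int(e1), rng)
    m2 = _draw_point_mutation(chrom, location_class, int(e2), rng)
    wt = chrom.copy()
    a, b, ab = chrom.copy(), chrom.copy(), chrom.copy()
    _apply(a, m1)
    _apply(b, m2)
    _apply(ab, m1)
    _apply(ab, m2)
    return wt, a, b, ab


def epsilon(w_ab: float, w_a: float, w_b: float) -> float:
    """Epistasis on raw fitnesses: ``w_ab - w_a * w_b``."""
    return w_ab - w_a * w_b


def sign_fractions(eps: np.ndarray, tol: float = SIGN_TOLERANCE) -> dict:
    """Fractions of positive, negative, zero, and directional epistasis."""
    eps = np.asarray(eps, dtype=float)
    n = eps.size
    pos = float((eps > tol).sum() / n)
    neg = float((eps < -tol).sum() / n)
    return {
        "positive": pos,
        "negative": neg,
        "zero": 1.0 - pos - neg,
        "directional": pos + neg,
    }


def run_epistasis_experiment(
    sizes=DEFAULT_SIZES,
    topologies=gt.TOPOLOGIES,
    location_classes=MUTATION_CLASSES,
    reps: int = 1000,
    env: float = 70.0,
    omega: float = 2.0,
    fitness_scale: float = 10.0,
    env_range: float = gt.ENV_RANGE,
    seed: int | np.random.Generator = 0,
    wildtype_relative: bool = False,
) -> EpistasisTable:
    """Factorial single- vs double-mutant experiment on random networks.

    For every (size × topology × mutation-location class) cell, ``reps``
    random wild-type networks are generated, a mutant quartet is formed on
    each, all four fitnesses are evaluated against the reference environment,
    and epsilon is recorded.  ``wildtype_relative=True`` switches to the
    convention of normalising every fitness by the wild type's before
    computing epsilon (off by default: epsilon uses raw fitnesses).
    """
    if reps < 1:
        raise InvalidParameterError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for n in sizes:
        for topo in topologies:
            heads, funcs, roots = gt.build_networks_batch(n, topo, len(location_classes) * reps, rng)
            k = 0
            for mclass in location_classes:
                for _ in range(reps):
                    wt_chrom = NetworkChromosome(heads[k], funcs[k], int(roots[k]))
                    k += 1
                    quartet = make_mutant_quartet(wt_chrom, mclass, rng)
                    ph = [gt.phenotype_network(c, env_range) for c in quartet]
                    w = [relative_fitness(p, env, omega, fitness_scale) for p in ph]
                    w_wt, w_a, w_b, w_ab = w
                    if wildtype_relative:
                        w_a, w_b, w_ab = w_a / w_wt, w_b / w_wt, w_ab / w_wt
                    rows.append(
                        (n, topo, mclass, w_wt, w_a, w_b, w_ab, epsilon(w_ab, w_a, w_b))
                    )
    runs = pd.DataFrame(
        rows, columns=["n", "topology", "mclass", "w", "w_a", "w_b", "w_ab", "eps"]
    )
    meta = {
        "sizes": list(sizes),
        "note": (
            "six size levels default to {8,16,32,64,128,256}: the five main-design "
            "sizes plus 8 as the sixth level"
        ),
        "env": env,
        "omega": omega,
        "fitness_scale": fitness_scale,
        "reps_per_cell": reps,
        "wildtype_relative": wildtype_relative,
    }
    return EpistasisTable(runs=runs, meta=meta)


def weighted_epistasis(table: EpistasisTable | pd.DataFrame) -> pd.DataFrame:
    """Per-(size, topology) mean epistasis, SD-weighted and raw, with 95% CIs.

    Each epsilon is divided by the standard deviation of epsilon within its
    network size, which standardises the within-size spread to one.  Returns
    one row per (n, topology) group with normal-approximation confidence
    intervals; raises :class:`DegenerateWeightError` if any size has zero
    spread.
    """
    runs = table.runs if isinstance(table, EpistasisTable) else table
    sd = runs.groupby("n")["eps"].std(ddof=1)
    if (sd == 0).any() or sd.isna().any():
        raise DegenerateWeightError("zero within-size standard deviation")
    w = runs["eps"] / runs["n"].map(sd)
    df = runs.assign(eps_weighted=w)
    grouped = df.groupby(["n", "topology"])
    out = grouped.agg(
        mean_weighted=("eps_weighted", "mean"),
        sem_weighted=("eps_weighted", "sem"),
        mean_raw=("eps", "mean"),
        sem_raw=("eps", "sem"),
        n_runs=("eps", "size"),
    ).reset_index()
    for kind in ("weighted", "raw"):
        out[f"ci95_lo_{kind}"] = out[f"mean_{kind}"] - 1.96 * out[f"sem_{kind}"]
        out[f"ci95_hi_{kind}"] = out[f"mean_{kind}"] + 1.96 * out[f"sem_{kind}"]
    return out
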