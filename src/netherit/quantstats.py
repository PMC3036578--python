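"""Quantitative-genetics observables computed from simulation time series.

Narrow-sense heritability is estimated as the ordinary-least-squares slope of
offspring phenotype on mid-parent phenotype (the mid-parent regressor already
averages both parents, so the slope estimates h² directly, without the
single-parent doubling).  Additive genetic variance follows as
``V_A = h² · V_P``.  Rates of change of variance components are OLS slopes
against generation over a window; population recovery time is measured
against the mean population size of the 50 generations immediately preceding
an environmental change.

Undefined values (degenerate regressions, empty windows) are signalled as
NaN, never raised, and are excluded from window means and regressions rather
than zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import InvalidParameterError

__all__ = [
    "MidparentPair",
    "RecoveryResult",
    "midparent_heritability",
    "additive_variance",
    "rate_of_change",
    "window_mean",
    "recovery_time",
    "summarize_run",
]

BASELINE_WINDOW = 50  # generations entering the pre-change population baseline


@dataclass(frozen=True)
class MidparentPair:
    midparent: float
    offspring: float


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of a recovery-time scan.

    ``recovery_generation`` is the first post-change generation whose
    population size is at or above the pre-change baseline (ties count as
    recovered); it is None — and ``recovery_time`` NaN — when the population
    goes extinct or the series ends first.
    """

    baseline: float
    recovery_generation: int | None
    recovery_time: float

    @property
    def recovered(self) -> bool:
        return self.recovery_generation is not None


def midparent_heritability(pairs) -> float:
    """OLS slope of offspring on mid-parent phenotype; NaN when degenerate.

    Accepts an iterable of :class:`MidparentPair` or ``(midparent,
    offspring)`` tuples.  At least three pairs with non-zero mid-parent
    variance are required for a defined estimate.
    """
    mids, offs = [], []
    for p in pairs:
        if isinstance(p, MidparentPair):
            mids.append(p.midparent)
            offs.append(p.offspring)
        else:
            mids.append(p[0])
            offs.append(p[1])
    x = np.asarray(mids, dtype=float)
    y = np.asarray(offs, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or x.var() == 0.0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / x.var())


def additive_variance(V_P: float, h2: float) -> float:
    """``V_A = h² · V_P``."""
    if V_P < 0:
        raise InvalidParameterError("phenotypic variance must be non-negative")
    return h2 * V_P


def _window_values(series, window) -> tuple[np.ndarray, np.ndarray]:
    """Extract (generations, values) for a [start, stop] generation window.

    ``series`` is indexed positionally from generation 1; ``window`` is an
    inclusive ``(start, stop)`` pair in generation units.
    """
    v = np.asarray(series, dtype=float)
    start, stop = window
    if start < 1 or stop > v.size or start > stop:
        raise InvalidParameterError(
            f"window ({start}, {stop}) outside series of length {v.size}"
        )
    gens = np.arange(start, stop + 1)
    return gens, v[start - 1 : stop]


def rate_of_change(series, window: tuple[int, int]) -> float:
    """OLS slope of a per-generation series against generation over a window.

    NaN entries are excluded; fewer than two defined values give NaN.
    """
    gens, vals = _window_values(series, window)
    ok = np.isfinite(vals)
    gens, vals = gens[ok], vals[ok]
    if gens.size < 2:
        return np.nan
    g = gens - gens.mean()
    return float((g * (vals - vals.mean())).sum() / (g * g).sum())


def window_mean(series, window: tuple[int, int]) -> float:
    """Arithmetic mean of the defined values in an inclusive window."""
    _, vals = _window_values(series, window)
    ok = np.isfinite(vals)
    if not ok.any():
        return np.nan
    return float(vals[ok].mean())


def recovery_time(
    pop_sizes, change_generation: int, baseline_window: int = BASELINE_WINDOW
) -> RecoveryResult:
    """Generations needed for the population to return to its pre-change size.

    The baseline is the mean population size over the ``baseline_window``
    generations immediately preceding ``change_generation`` (the first
    generation lived under the new environment); recovery is the first
    generation strictly after the change at or above that baseline.
    """
    sizes = np.asarray(pop_sizes, dtype=float)
    if change_generation < baseline_window + 1:
        raise InvalidParameterError(
            "change generation leaves no room for the baseline window"
        )
    if sizes.size < change_generation:
        raise InvalidParameterError("series ends before the environmental change")
    base = sizes[change_generation - 1 - baseline_window : change_generation - 1]
    baseline = float(base.mean())
    post = sizes[change_generation:]  # generations change+1, change+2, ...
    hits = np.nonzero(post >= baseline)[0]
    if hits.size == 0 or np.any(post[: hits[0] + 1] == 0):
        return RecoveryResult(baseline, None, np.nan)
    gen = change_generation + 1 + int(hits[0])
    return RecoveryResult(baseline, gen, float(gen - change_generation))


def summarize_run(
    df: pd.DataFrame,
    change_generation: int | None,
    pre_change_generations: int = 250,
) -> dict:
    """Per-run summary of a simulation time series.

    ``df`` is the per-generation table emitted by the population module
    (columns ``generation, pop_size, V_P, h2, V_A, ...``).  Rates of change
    are estimated over the pre-change window; heritability is averaged both
    over the last 100 pre-change generations and over the 50 generations
    immediately before the change (both windows the field uses).
    """
    end = pre_change_generations
    if change_generation is not None:
        end = min(end, change_generation - 1)
    end = min(end, len(df))
    va = df["V_A"].to_numpy()
    vp = df["V_P"].to_numpy()
    h2 = df["h2"].to_numpy()
    sizes = df["pop_size"].to_numpy()

    out = {
        "dVA_dt": rate_of_change(va, (1, end)),
        "dVP_dt": rate_of_change(vp, (1, end)),
        "mean_h2_last100": window_mean(h2, (max(1, end - 99), end)),
        "mean_h2_last50_prechange": window_mean(h2, (max(1, end - 49), end)),
        "VA_prechange": window_mean(va, (max(1, end - 49), end)),
        "extinct": bool(df["extinct_flag"].iloc[-1]) if "extinct_flag" in df else False,
        "recovery_time": np.nan,
        "recovered": False,
    }
    if change_generation is not None and len(df) > change_generation:
        res = recovery_time(sizes, change_generation)
        out["recovery_time"] = res.recovery_time
        out["recovered"] = res.recovered
        out["baseline_popsize"] = res.baseline
    return out
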