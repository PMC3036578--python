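"""Factorial simulation designs and their statistical summaries.

Three designs are built in:

``network_main``
    5 network sizes (16..256) × 2 topologies × 3 mutation rates × 2
    recombination rates × 2 fitness-function widths × 2 degrees of
    environmental change, 3 replicates — 720 runs.
``linear_main``
    The same crossing without topology and with doubled mutation rates (the
    network's mutational target is ``2n - 1`` elements versus ``n`` loci) —
    360 runs.
``va_trigger``
    The network crossing with the fixed change generation replaced by an
    additive-variance trigger (thresholds 5, 10, 20) and a hard cutoff for
    runs whose threshold is never reached — 720 runs at 1 replicate.

Each run gets its own seed derived from the design's master seed, so a
design executes bit-reproducibly.  Scale factors (population, horizon,
replicates) allow desk-scale execution; whatever scale is used is recorded
in the summary's metadata.

Variance partitioning uses sequential (type-I) sums of squares on an
ordinary least-squares fit (statsmodels), with terms entered in the order
given — percent-of-variance figures are order-sensitive, so the order is
part of the analysis definition.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import InvalidParameterError
from .popdyn import EnvironmentSchedule, SimulationConfig, run_simulation
from .quantstats import summarize_run

__all__ = [
    "SingularDesignError",
    "FactorialDesign",
    "VariancePartition",
    "DESIGN_KINDS",
    "PROFILES",
    "build_design",
    "execute_design",
    "partition_variance",
    "summarize_figures",
    "aic_comparison",
    "write_summary",
]

DESIGN_KINDS = ("network_main", "linear_main", "va_trigger")

NETWORK_SIZES = (16, 32, 64, 128, 256)
TOPOLOGIES = ("random", "scale_free")
MUTATION_RATES = (1e-3, 1e-4, 1e-5)
RECOMBINATION_RATES = (0.05, 0.5)  # 0.25 available via custom designs
OMEGAS = (1.5, 2.0)
DELTAS = (20.0, 30.0)
VA_THRESHOLDS = (5.0, 10.0, 20.0)

#: Execution profiles: ``paper`` reproduces the published scale, ``desk``
#: is the reduced scale used for routine verification.
PROFILES = {
    "paper": {"population": 500, "horizon": 1000, "replicates": None},
    "desk": {"population": 250, "horizon": 250, "replicates": 1},
}


class SingularDesignError(ValueError):
    """The model matrix is rank-deficient; the partition is undefined."""


@dataclass
class FactorialDesign:
    """A fully crossed simulation design with per-run derived seeds."""

    kind: str
    factors: dict
    replicates: int
    master_seed: int
    table: pd.DataFrame

    @property
    def n_runs(self) -> int:
        return len(self.table)


def _derive_seeds(master_seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n, dtype=np.uint64) % np.uint64(2**31)).astype(np.int64)


def build_design(
    kind: str, replicates: int | None = None, master_seed: int = 0
) -> FactorialDesign:
    """Construct one of the built-in factorial designs.

    ``replicates`` defaults to 3 for the main designs (720 / 360 runs) and
    1 for the trigger design (720 runs).
    """
    if kind not in DESIGN_KINDS:
        raise InvalidParameterError(f"unknown design kind {kind!r}")
    if kind == "network_main":
        reps = 3 if replicates is None else replicates
        factors = {
            "n": NETWORK_SIZES,
            "topology": TOPOLOGIES,
            "mu": MUTATION_RATES,
            "r": RECOMBINATION_RATES,
            "omega": OMEGAS,
            "dE": DELTAS,
        }
        arch = "network"
    elif kind == "linear_main":
        reps = 3 if replicates is None else replicates
        factors = {
            "n": NETWORK_SIZES,
            "mu": tuple(2 * m for m in MUTATION_RATES),
            "r": RECOMBINATION_RATES,
            "omega": OMEGAS,
            "dE": DELTAS,
        }
        arch = "linear"
    else:  # va_trigger
        reps = 1 if replicates is None else replicates
        factors = {
            "n": NETWORK_SIZES,
            "topology": TOPOLOGIES,
            "mu": MUTATION_RATES,
            "r": RECOMBINATION_RATES,
            "omega": OMEGAS,
            "dE": DELTAS,
            "va_threshold": VA_THRESHOLDS,
        }
        arch = "network"

    names = list(factors)
    cells = list(itertools.product(*factors.values()))
    rows = []
    for rep in range(1, reps + 1):
        for cell in cells:
            rows.append(dict(zip(names, cell)) | {"replicate": rep})
    table = pd.DataFrame(rows)
    table.insert(0, "run_id", [f"{kind}-{i:05d}" for i in range(len(table))])
    table["architecture"] = arch
    table["seed"] = _derive_seeds(master_seed, len(table))
    return FactorialDesign(kind, factors, reps, master_seed, table)


def _config_for_row(row: pd.Series, kind: str, scale: dict) -> SimulationConfig:
    pop = scale["population"]
    if kind == "va_trigger":
        env = EnvironmentSchedule(
            initial=70.0,
            mode="step_at_va_threshold",
            delta=float(row["dE"]),
            va_threshold=float(row["va_threshold"]),
            horizon=scale.get("trigger_horizon", 1500),
            post_change_generations=scale.get("post_change_generations", 750),
        )
    else:
        env = EnvironmentSchedule(
            initial=70.0,
            mode="step_at_generation",
            delta=float(row["dE"]),
            change_generation=scale.get("change_generation", 251),
            horizon=scale["horizon"],
        )
    return SimulationConfig(
        architecture=row["architecture"],
        n=int(row["n"]),
        topology=row.get("topology", "random"),
        mu=float(row["mu"]),
        r=float(row["r"]),
        omega=float(row["omega"]),
        K=pop,
        env=env,
        seed=int(row["seed"]),
    )


def execute_design(
    design: FactorialDesign,
    population: int = 500,
    horizon: int = 1000,
    change_generation: int = 251,
    stop_after_recovery: bool = False,
    existing: pd.DataFrame | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every cell of a design and summarise each run.

    ``population`` and ``horizon`` are the scale knobs; a ``horizon`` at or
    below ``change_generation - 1`` yields canalization-only runs (the
    environment never changes).  Pass a previously saved summary as
    ``existing`` to skip completed run_ids (simple resumability).
    Returns one row per run: the design factors plus the per-run
    quantitative-genetics summary; execution metadata lives in
    ``DataFrame.attrs['meta']``.
    """
    scale = {
        "population": population,
        "horizon": horizon,
        "change_generation": change_generation,
    }
    done = set(existing["run_id"]) if existing is not None else set()
    out_rows = [] if existing is None else [existing]
    new_rows = []
    for _, row in design.table.iterrows():
        if row["run_id"] in done:
            continue
        config = _config_for_row(row, design.kind, scale)
        result = run_simulation(config, stop_after_recovery=stop_after_recovery)
        change = result.change_generation
        summary = summarize_run(
            result.to_dataframe(),
            change,
            pre_change_generations=min(horizon, change_generation - 1),
        )
        rec = row.to_dict() | summary | {
            "fired": result.fired,
            "truncated": result.truncated,
            "n_generations": len(result.records),
            "change_generation": change,
        }
        new_rows.append(rec)
        if progress:
            print(f"  {row['run_id']} done ({len(result.records)} generations)")
    if new_rows:
        out_rows.append(pd.DataFrame(new_rows))
    out = pd.concat(out_rows, ignore_index=True) if len(out_rows) > 1 else (
        out_rows[0] if out_rows else pd.DataFrame()
    )
    out.attrs["meta"] = {
        "kind": design.kind,
        "master_seed": design.master_seed,
        "replicates": design.replicates,
        "population": population,
        "horizon": horizon,
        "change_generation": change_generation,
        "stop_after_recovery": stop_after_recovery,
    }
    return out


@dataclass
class VariancePartition:
    """Sequential-SS decomposition of a response over design terms."""

    table: pd.DataFrame  # columns: term, percent_ss, sum_sq, df, F, p
    residual_percent: float
    directions: dict
    response: str

    @property
    def explained_percent(self) -> float:
        """Summed percent of total SS over all non-residual terms."""
        return float(self.table["percent_ss"].sum())


def _numeric_coding(df: pd.DataFrame, term: str) -> np.ndarray | None:
    """Numeric coding of a (possibly categorical or interaction) term."""
    parts = [p.strip() for p in term.split(":")]
    vals = np.ones(len(df))
    for p in parts:
        name = p[2:-1] if p.startswith("C(") else p
        if name not in df.columns:
            return None
        col = df[name]
        if col.dtype == object:
            codes = pd.Categorical(col).codes.astype(float)
        else:
            codes = col.to_numpy(dtype=float)
        vals = vals * codes
    return vals


def partition_variance(
    table: pd.DataFrame,
    response: str,
    terms: list[str],
    log_transform: bool = True,
    min_defined_fraction: float = 0.8,
) -> VariancePartition:
    """Partition a response's variance over design terms (type-I ANOVA).

    ``terms`` are patsy-style model terms (e.g. ``"C(n)"``,
    ``"VA_prechange"``, ``"C(n):VA_prechange"``) entered sequentially in the
    given order.  The response is log-transformed by default (heritability
    distributions are right-skewed); non-finite or non-positive responses
    are dropped, provided at least ``min_defined_fraction`` of runs remain.
    Effect directions are the signs of the response's correlation with a
    numeric coding of each term (network size treated as continuous).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.copy()
    y = df[response].to_numpy(dtype=float)
    ok = np.isfinite(y)
    if log_transform:
        ok &= y > 0
    if ok.sum() < min_defined_fraction * len(df):
        raise InvalidParameterError(
            f"response {response!r} defined for only {ok.sum()}/{len(df)} runs"
        )
    df = df.loc[ok].copy()
    df["_resp"] = np.log(df[response]) if log_transform else df[response]
    formula = "_resp ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise SingularDesignError("design matrix is rank-deficient")
    fit = model.fit()
    anova = sm.stats.anova_lm(fit, typ=1)
    total_ss = float(anova["sum_sq"].sum())
    rows = []
    for term in anova.index:
        if term == "Residual":
            continue
        rows.append(
            {
                "term": term,
                "sum_sq": float(anova.loc[term, "sum_sq"]),
                "percent_ss": 100.0 * float(anova.loc[term, "sum_sq"]) / total_ss,
                "df": float(anova.loc[term, "df"]),
                "F": float(anova.loc[term, "F"]),
                "p": float(anova.loc[term, "PR(>F)"]),
            }
        )
    out = pd.DataFrame(rows)
    residual_percent = 100.0 * float(anova.loc["Residual", "sum_sq"]) / total_ss
    directions = {}
    for term in out["term"]:
        coding = _numeric_coding(df, term)
        if coding is None or np.std(coding) == 0:
            directions[term] = 0
        else:
            r = np.corrcoef(coding, df["_resp"])[0, 1]
            directions[term] = int(np.sign(r))
    return VariancePartition(out, residual_percent, directions, response)


def aic_comparison(
    table: pd.DataFrame,
    response: str,
    reduced_terms: list[str],
    full_terms: list[str],
    log_transform: bool = True,
) -> dict:
    """AIC of a reduced versus a richer model for the same response."""
    import statsmodels.formula.api as smf

    df = table.copy()
    y = df[response].to_numpy(dtype=float)
    ok = np.isfinite(y) & ((y > 0) if log_transform else True)
    df = df.loc[ok].copy()
    df["_resp"] = np.log(df[response]) if log_transform else df[response]
    fits = {
        "reduced": smf.ols("_resp ~ " + " + ".join(reduced_terms), data=df).fit(),
        "full": smf.ols("_resp ~ " + " + ".join(full_terms), data=df).fit(),
    }
    return {
        "aic_reduced": float(fits["reduced"].aic),
        "aic_full": float(fits["full"].aic),
        "delta_aic": float(fits["reduced"].aic - fits["full"].aic),
    }


def _group_ci(df: pd.DataFrame, by: list[str], value: str) -> pd.DataFrame:
    sub = df[np.isfinite(df[value].astype(float))]
    g = sub.groupby(by)[value]
    out = g.agg(mean="mean", sem="sem", count="size").reset_index()
    out["ci95_lo"] = out["mean"] - 1.96 * out["sem"]
    out["ci95_hi"] = out["mean"] + 1.96 * out["sem"]
    return out


def summarize_figures(summary: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Figure-ready group means with 95% CIs.

    Rates of change of V_A and V_P by (size × recombination rate),
    heritability by (size × topology) and (size × fitness width), and
    recovery time by (size × degree of environmental change).  Groupings
    whose columns are absent (e.g. topology for linear designs) are skipped;
    empty groups are simply missing rows.
    """
    out = {}
    specs = {
        "dVA_dt_by_size_r": (["n", "r"], "dVA_dt"),
        "dVP_dt_by_size_r": (["n", "r"], "dVP_dt"),
        "h2_by_size_topology": (["n", "topology"], "mean_h2_last100"),
        "h2_by_size_omega": (["n", "omega"], "mean_h2_last100"),
        "recovery_by_size_dE": (["n", "dE"], "recovery_time"),
    }
    for name, (by, value) in specs.items():
        if all(c in summary.columns for c in by) and value in summary.columns:
            out[name] = _group_ci(summary, by, value)
    return out


def write_summary(summary: pd.DataFrame, path: str) -> None:
    """Write a summary table as CSV with a JSON metadata sidecar."""
    summary.to_csv(path, index=False)
    meta = dict(summary.attrs.get("meta", {}))
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
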