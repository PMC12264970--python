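"""Accuracy statistics for RBFE benchmark tables.

The substrate is a tidy table with one row per (ligand pair, structure
record): columns ``pair_id``, ``ddg_exp`` (kcal/mol, positive by the
more-potent-ligand-as-state-A convention), ``ddg_calc`` (kcal/mol),
``affinity`` ("higher"/"lower" — which of the pair's two complexes holds
the more potent ligand), optionally ``source_consistency``
("same"/"different" experimental data source), a ``structure_id`` and the
structural features ``res``, ``lig_bf``, ``n_wat``, ``prot_bf``.

Statistics follow the benchmark conventions: the unsigned error
UE = |ΔΔG_calc − ΔΔG_exp| per record, the average unsigned error (AUE)
over a class with a bootstrap standard error (10,000 resamples), per-pair
consensus (mean of the two structure estimates) and "best set" (the
estimate closest to experiment), splits by relative affinity and by data
source, an ordinary least-squares fit of UE against crystallographic
resolution with ±0.1 Å binned AUE, the nominal resolution implied for a
predicted structure by inverting that fit at its AUE, and the percentage
of pairs whose calculated ΔΔG has the correct (positive) sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AueResult",
    "FitResult",
    "NominalResolution",
    "BENCHMARK_COLUMNS",
    "unsigned_error",
    "add_unsigned_error",
    "aue",
    "consensus_ddg",
    "consensus_aue",
    "pooled_aue",
    "best_set_select",
    "best_set_aue",
    "split_by_affinity",
    "split_by_source",
    "split_by_affinity_and_source",
    "fit_ue_resolution",
    "binned_aue",
    "nominal_resolution",
    "sign_accuracy",
    "read_benchmark_table",
    "write_benchmark_table",
]

BENCHMARK_COLUMNS = [
    "pair_id",
    "target",
    "structure_id",
    "affinity",
    "source_consistency",
    "ddg_exp",
    "ddg_calc",
    "se",
    "res",
    "lig_bf",
    "n_wat",
    "prot_bf",
]


@dataclass
class AueResult:
    """Average unsigned error (kcal/mol) with bootstrap SE and class size."""

    aue: float
    se: float
    n: int


@dataclass
class FitResult:
    """OLS fit of UE (kcal/mol) on resolution (Å)."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float

    def predict(self, res):
        return self.slope * np.asarray(res, dtype=float) + self.intercept


@dataclass
class NominalResolution:
    """Resolution implied by inverting the UE-vs-resolution line at an AUE.

    ``censored`` flags values beyond the fitted resolution range, which
    are reported as "> max observed" rather than extrapolated blindly.
    """

    value: float
    censored: bool = False

    def __str__(self) -> str:
        return f"> {self.value:.1f} Å" if self.censored else f"{self.value:.1f} Å"


def unsigned_error(ddg_calc, ddg_exp):
    """UE = |ΔΔG_calc − ΔΔG_exp| (kcal/mol); elementwise on arrays."""
    return np.abs(np.asarray(ddg_calc, dtype=float) - np.asarray(ddg_exp, dtype=float))


def add_unsigned_error(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the table with a ``ue`` column."""
    if "ue" in table.columns:
        return table
    out = table.copy()
    out["ue"] = unsigned_error(out["ddg_calc"], out["ddg_exp"])
    return out


def aue(ues: Sequence[float], n_boot: int = 10000, seed: int = 0) -> AueResult:
    """Mean unsigned error with a bootstrap SE over entries."""
    u = np.asarray(ues, dtype=float)
    if u.size == 0:
        raise ValueError("cannot compute an AUE of an empty set")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, u.size, size=(n_boot, u.size))
    boot = u[idx].mean(axis=1)
    se = float(np.std(boot, ddof=1)) if n_boot > 1 else 0.0
    return AueResult(aue=float(u.mean()), se=se, n=int(u.size))


def _paired(table: pd.DataFrame) -> pd.core.groupby.DataFrameGroupBy:
    t = add_unsigned_error(table)
    sizes = t.groupby("pair_id").size()
    bad = sizes[sizes != 2]
    if len(bad):
        raise ValueError(f"pairs without exactly two structure records: {list(bad.index)}")
    return t.groupby("pair_id", sort=True)


def consensus_ddg(table: pd.DataFrame) -> pd.Series:
    """Per-pair mean of the two structure-based ΔΔG estimates (kcal/mol)."""
    return _paired(table)["ddg_calc"].mean()


def consensus_aue(table: pd.DataFrame, n_boot: int = 10000, seed: int = 0) -> AueResult:
    """AUE of the per-pair consensus estimates."""
    g = _paired(table)
    ue = (g["ddg_calc"].mean() - g["ddg_exp"].first()).abs()
    return aue(ue.to_numpy(), n_boot=n_boot, seed=seed)


def pooled_aue(table: pd.DataFrame, n_boot: int = 10000, seed: int = 0) -> AueResult:
    """AUE over all structure records (both estimates of every pair)."""
    t = add_unsigned_error(table)
    return aue(t["ue"].to_numpy(), n_boot=n_boot, seed=seed)


def best_set_select(table: pd.DataFrame) -> pd.DataFrame:
    """Per pair, the record with the smaller UE; ties go to the
    higher-affinity structure."""
    t = add_unsigned_error(table)
    rows = []
    for _, grp in _paired(t):
        grp = grp.sort_values("affinity")  # 'higher' < 'lower' lexically
        best = grp.iloc[int(np.argmin(grp["ue"].to_numpy()))]
        rows.append(best)
    return pd.DataFrame(rows).reset_index(drop=True)


def best_set_aue(table: pd.DataFrame, n_boot: int = 10000, seed: int = 0) -> AueResult:
    """AUE of the per-pair best (closest-to-experiment) estimates."""
    return aue(best_set_select(table)["ue"].to_numpy(), n_boot=n_boot, seed=seed)


def _class_aues(table, key, n_boot, seed):
    t = add_unsigned_error(table)
    out = {}
    for i, (label, grp) in enumerate(t.groupby(key, sort=True)):
        out[label] = aue(grp["ue"].to_numpy(), n_boot=n_boot, seed=seed + i)
    return out


def split_by_affinity(table: pd.DataFrame, n_boot: int = 10000, seed: int = 0) -> dict:
    """AUE per relative-affinity class ('higher' vs 'lower' affinity
    structure); absent classes are simply absent from the dict."""
    return _class_aues(table, "affinity", n_boot, seed)


def split_by_source(table: pd.DataFrame, n_boot: int = 10000, seed: int = 0) -> dict:
    """AUE per experimental-source-consistency class ('same'/'different')."""
    return _class_aues(table, "source_consistency", n_boot, seed)


def split_by_affinity_and_source(
    table: pd.DataFrame, n_boot: int = 10000, seed: int = 0
) -> dict:
    """AUE for each (affinity, source_consistency) cross-class."""
    t = add_unsigned_error(table)
    out = {}
    for i, (label, grp) in enumerate(
        t.groupby(["affinity", "source_consistency"], sort=True)
    ):
        out[label] = aue(grp["ue"].to_numpy(), n_boot=n_boot, seed=seed + i)
    return out


def fit_ue_resolution(res: Sequence[float], ue: Sequence[float]) -> FitResult:
    """Unweighted ordinary least squares of UE on resolution."""
    r = np.asarray(res, dtype=float)
    u = np.asarray(ue, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 points for the UE-vs-resolution fit")
    if np.isclose(r.std(), 0.0):
        raise ValueError("all resolutions equal: fit undefined")
    fit = stats.linregress(r, u)
    return FitResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        se_slope=float(fit.stderr),
        se_intercept=float(fit.intercept_stderr),
    )


def binned_aue(
    res: Sequence[float], ue: Sequence[float], half_width: float = 0.1
) -> pd.DataFrame:
    """AUE of all points within ±``half_width`` Å of each distinct
    resolution (centered sliding windows)."""
    r = np.asarray(res, dtype=float)
    u = np.asarray(ue, dtype=float)
    centers = np.unique(r)
    rows = []
    for c in centers:
        mask = np.abs(r - c) <= half_width
        rows.append((c, u[mask].mean(), int(mask.sum())))
    return pd.DataFrame(rows, columns=["res", "aue", "n"])


def nominal_resolution(
    aue_value: float, fit: FitResult, max_res: float | None = None
) -> NominalResolution:
    """Invert the fitted UE-vs-resolution line at an observed AUE.

    Requires a positive slope (worse resolution → larger error). When the
    implied resolution exceeds ``max_res`` (the largest resolution in the
    fitted data), the result is clamped there and flagged as censored.
    """
    if fit.slope <= 0:
        raise ValueError("nominal resolution is undefined for a non-positive slope")
    value = (aue_value - fit.intercept) / fit.slope
    if max_res is not None and value > max_res:
        return NominalResolution(value=float(max_res), censored=True)
    return NominalResolution(value=float(value), censored=False)


def sign_accuracy(
    ddg_calc: Sequence[float],
    ddg_exp: Sequence[float] | None = None,
    n_boot: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentage of records whose calculated ΔΔG is positive, i.e. has
    the sign of the (positive-by-convention) experimental ΔΔG.

    Exact zeros count as incorrect. Returns (percentage, bootstrap SE).
    """
    c = np.asarray(ddg_calc, dtype=float)
    if c.size == 0:
        raise ValueError("no records")
    if ddg_exp is not None and np.any(np.asarray(ddg_exp, dtype=float) <= 0):
        raise ValueError("experimental ΔΔG must be positive by convention")
    correct = (c > 0).astype(float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, c.size, size=(n_boot, c.size))
    boot = correct[idx].mean(axis=1) * 100.0
    se = float(np.std(boot, ddof=1)) if n_boot > 1 else 0.0
    return float(correct.mean() * 100.0), se


def read_benchmark_table(path_or_buf) -> pd.DataFrame:
    """Read a benchmark CSV and validate the documented schema."""
    df = pd.read_csv(path_or_buf)
    required = {"pair_id", "ddg_exp", "ddg_calc", "affinity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"benchmark table is missing columns: {sorted(missing)}")
    if (df["ddg_exp"] <= 0).any():
        raise ValueError("ddg_exp must be positive (state A = more potent ligand)")
    return df


def write_benchmark_table(table: pd.DataFrame, path_or_buf) -> None:
    """Write a benchmark table as CSV with the documented column order."""
    cols = [c for c in BENCHMARK_COLUMNS if c in table.columns] + [
        c for c in table.columns if c not in BENCHMARK_COLUMNS
    ]
    table.loc[:, cols].to_csv(path_or_buf, index=False)
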