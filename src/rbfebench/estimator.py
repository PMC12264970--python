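"""Free-energy estimation from nonequilibrium work distributions.

The free energy difference of an alchemical transformation is estimated
from the work values of fast forward (λ: 0→1) and reverse (λ: 1→0)
switching trajectories via the maximum-likelihood estimator based on the
Crooks fluctuation theorem — the Bennett acceptance ratio (BAR) form.
Work values are obtained by integrating dH/dλ over the switching path.

ΔG solves the self-consistent equation

    Σ_i 1 / (1 + exp(β(M + W_F,i − ΔG)))
        = Σ_j 1 / (1 + exp(−β(M − W_R,j − ΔG)))

with β = 1/kT, M = kT·ln(n_F/n_R), forward works W_F and reverse works
W_R reported for the 1→0 process (so −W_R is the work in the forward
frame). The left-minus-right residual is strictly increasing in ΔG, so a
bracketed root-finder converges unconditionally whenever the bracket
straddles the root.

Per-pair ΔΔG is assembled from the protein-complex and water legs of the
thermodynamic cycle, or read off directly for double-system-single-box
(DSSB) setups where both legs switch simultaneously in one box.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .units import KT_298

__all__ = [
    "DhdlTrace",
    "WorkSet",
    "LegEstimate",
    "EstimatorConfig",
    "ConvergenceError",
    "integrate_work",
    "estimate_dg",
    "assemble_ddg",
    "assemble_ddg_dssb",
    "average_replicas",
    "read_xvg",
    "read_work_table",
    "write_work_table",
    "work_sets_from_table",
]

LEGS = ("protein", "water", "dssb")


class ConvergenceError(RuntimeError):
    """The self-consistent ΔG equation did not converge.

    Carries the last iterate in ``last_iterate`` (kJ/mol).
    """

    def __init__(self, message: str, last_iterate: float):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class EstimatorConfig:
    """Numerical settings for the ML/BAR solve.

    kT : thermal energy in kJ/mol (default 298.15 K).
    tolerance : absolute convergence threshold on ΔG, kJ/mol.
    max_iter : iteration cap for the root search.
    """

    kT: float = KT_298
    tolerance: float = 1e-8
    max_iter: int = 500

    def __post_init__(self):
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class DhdlTrace:
    """One switching trajectory: λ grid and dH/dλ values (kJ/mol).

    ``direction`` is "forward" (0→1) or "reverse" (1→0); λ is stored in
    traversal order and must be strictly monotone with endpoints 0 and 1.
    """

    lambdas: np.ndarray
    dhdl: np.ndarray
    direction: str = "forward"

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.dhdl = np.asarray(self.dhdl, dtype=float)
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.lambdas.shape != self.dhdl.shape or self.lambdas.ndim != 1:
            raise ValueError("lambdas and dhdl must be 1-D and equal length")
        if self.lambdas.size < 2:
            raise ValueError("a dhdl trace needs at least 2 points")
        d = np.diff(self.lambdas)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("lambda grid must be strictly monotone")
        lo, hi = min(self.lambdas[0], self.lambdas[-1]), max(self.lambdas[0], self.lambdas[-1])
        if not (np.isclose(lo, 0.0) and np.isclose(hi, 1.0)):
            raise ValueError("lambda endpoints 0 and 1 must be present")


@dataclass
class WorkSet:
    """Forward and reverse work samples (kJ/mol) for one leg of one replica."""

    forward: np.ndarray
    reverse: np.ndarray
    leg: str = "protein"
    replica_id: int = 0

    def __post_init__(self):
        self.forward = np.atleast_1d(np.asarray(self.forward, dtype=float))
        self.reverse = np.atleast_1d(np.asarray(self.reverse, dtype=float))
        if self.leg not in LEGS:
            raise ValueError(f"leg must be one of {LEGS}, got {self.leg!r}")
        if not (np.all(np.isfinite(self.forward)) and np.all(np.isfinite(self.reverse))):
            raise ValueError("work values must be finite")

    @property
    def n_forward(self) -> int:
        return self.forward.size

    @property
    def n_reverse(self) -> int:
        return self.reverse.size


@dataclass
class LegEstimate:
    """ΔG (kJ/mol) for one leg of one replica, with sample counts.

    ``se`` is the plug-in asymptotic standard error of the ML estimate; the
    headline uncertainties in this package come from the bootstrap pipeline
    instead (see :mod:`rbfebench.uncertainty`).
    """

    dg: float
    leg: str
    replica_id: int
    n_forward: int
    n_reverse: int
    se: float = field(default=float("nan"))


def integrate_work(trace: DhdlTrace) -> float:
    """Integrate dH/dλ over the switching path (trapezoid rule).

    Returns the work (kJ/mol) for the process in the trace's own direction:
    ∫₀¹ for forward traces, ∫₁⁰ for reverse traces.
    """
    w = float(np.trapezoid(trace.dhdl, trace.lambdas))
    increasing = trace.lambdas[-1] > trace.lambdas[0]
    if trace.direction == "forward":
        return w if increasing else -w
    return -w if increasing else w


def _bar_residual(dg, wf, wr, kT, M):
    """Left-minus-right of the self-consistent equation; increasing in dg."""
    return np.sum(expit(-(M + wf - dg) / kT), axis=-1) - np.sum(
        expit((M - wr - dg) / kT), axis=-1
    )


def _bracket(wf, wr, kT, M):
    vals = np.concatenate([np.ravel(wf), -np.ravel(wr)])
    pad = 10.0 * kT + abs(M)
    return float(vals.min() - pad), float(vals.max() + pad)


def _bar_asymptotic_se(wf, wr, dg, kT) -> float:
    """Plug-in asymptotic SE of the ML estimate (Fermi-function variance)."""
    nf, nr = wf.size, wr.size
    M = kT * np.log(nf / nr)
    ff = expit(-(M + wf - dg) / kT)
    fr = expit((M - wr - dg) / kT)
    mf2, mf = np.mean(ff**2), np.mean(ff)
    mr2, mr = np.mean(fr**2), np.mean(fr)
    if mf == 0 or mr == 0:
        return float("inf")
    var = (mf2 / mf**2 - 1.0) / nf + (mr2 / mr**2 - 1.0) / nr
    return float(kT * np.sqrt(max(var, 0.0)))


def estimate_dg(work_set: WorkSet, config: EstimatorConfig | None = None) -> LegEstimate:
    """Solve the CFT maximum-likelihood (BAR) equation for one work set.

    Raises :class:`ConvergenceError` when the root search does not meet the
    configured tolerance within ``max_iter`` iterations (non-overlapping
    work distributions).
    """
    config = config or EstimatorConfig()
    wf, wr = work_set.forward, work_set.reverse
    if wf.size == 0 or wr.size == 0:
        raise ValueError("both forward and reverse works are required")
    kT = config.kT
    M = kT * np.log(wf.size / wr.size)
    lo, hi = _bracket(wf, wr, kT, M)
    try:
        dg = brentq(
            _bar_residual,
            lo,
            hi,
            args=(wf, wr, kT, M),
            xtol=config.tolerance,
            maxiter=config.max_iter,
        )
    except (RuntimeError, ValueError) as exc:
        raise ConvergenceError(
            f"ML estimate did not converge within {config.max_iter} iterations: {exc}",
            last_iterate=0.5 * (lo + hi),
        ) from exc
    dg = float(dg)
    return LegEstimate(
        dg=dg,
        leg=work_set.leg,
        replica_id=work_set.replica_id,
        n_forward=wf.size,
        n_reverse=wr.size,
        se=_bar_asymptotic_se(wf, wr, dg, kT),
    )


def _estimate_dg_many(wf: np.ndarray, wr: np.ndarray, config: EstimatorConfig) -> np.ndarray:
    """Vectorised bisection on the same self-consistent equation.

    ``wf``/``wr`` are 2-D arrays of shape (n_sets, n_samples); one ΔG per
    row. Used by the bootstrap pipeline where thousands of resampled sets
    are solved at once.
    """
    kT = config.kT
    M = kT * np.log(wf.shape[1] / wr.shape[1])
    pad = 10.0 * kT + abs(M)
    lo = np.minimum(wf.min(axis=1), (-wr).min(axis=1)) - pad
    hi = np.maximum(wf.max(axis=1), (-wr).max(axis=1)) + pad
    for _ in range(config.max_iter):
        mid = 0.5 * (lo + hi)
        r = _bar_residual(mid[:, None], wf, wr, kT, M)
        lo = np.where(r < 0, mid, lo)
        hi = np.where(r < 0, hi, mid)
        if np.max(hi - lo) < config.tolerance:
            return 0.5 * (lo + hi)
    raise ConvergenceError(
        "vectorised bisection did not converge", last_iterate=float(np.mean(0.5 * (lo + hi)))
    )


def assemble_ddg(protein: LegEstimate, water: LegEstimate) -> float:
    """ΔΔG = ΔG(protein leg) − ΔG(water leg), kJ/mol.

    With the more potent ligand as state A, the experimental ΔΔG is
    positive by convention and this difference is directly comparable.
    """
    if {protein.leg, water.leg} != {"protein", "water"}:
        raise ValueError(
            f"expected one 'protein' and one 'water' leg, got {protein.leg!r}/{water.leg!r}"
        )
    if protein.leg != "protein":
        protein, water = water, protein
    if protein.replica_id != water.replica_id:
        raise ValueError("legs belong to different replicas")
    return protein.dg - water.dg


def assemble_ddg_dssb(work_set: WorkSet, config: EstimatorConfig | None = None) -> float:
    """ΔΔG (kJ/mol) from a double-system-single-box work set.

    In DSSB the bound and solvated transformations run simultaneously in
    alternate states, so each work value already carries the leg
    difference and the ML estimate on the combined works is the ΔΔG.
    """
    if work_set.leg != "dssb":
        raise ValueError("assemble_ddg_dssb requires a work set with leg='dssb'")
    return estimate_dg(work_set, config).dg


def average_replicas(ddgs: Sequence[float]) -> float:
    """Arithmetic mean of per-replica ΔΔG values."""
    ddgs = np.asarray(ddgs, dtype=float)
    if ddgs.size == 0:
        raise ValueError("need at least one replica")
    return float(ddgs.mean())


# ---------------------------------------------------------------------------
# I/O

def read_xvg(source) -> np.ndarray:
    """Read a GROMACS-style xvg file into an (n, 2) array.

    Lines starting with '#' or '@' are ignored; the first two whitespace-
    separated numeric columns (λ or time, dH/dλ) are kept.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source
    ):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    rows = []
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "@")):
            continue
        parts = line.split()
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except (IndexError, ValueError) as exc:
            raise ValueError(f"unparseable xvg data line {i}: {line!r}") from exc
    if not rows:
        raise ValueError("no data rows found in xvg input")
    return np.asarray(rows, dtype=float)


WORK_TABLE_COLUMNS = ["pair_id", "leg", "replica", "direction", "work_kj"]


def write_work_table(work_sets: Iterable[WorkSet], path_or_buf, pair_id: str = "pair") -> None:
    """Write work sets as a tidy CSV (pair_id, leg, replica, direction, work_kj)."""
    rows = []
    for ws in work_sets:
        for w in ws.forward:
            rows.append((pair_id, ws.leg, ws.replica_id, "forward", w))
        for w in ws.reverse:
            rows.append((pair_id, ws.leg, ws.replica_id, "reverse", w))
    pd.DataFrame(rows, columns=WORK_TABLE_COLUMNS).to_csv(path_or_buf, index=False)


def read_work_table(path_or_buf) -> pd.DataFrame:
    """Read a work-value CSV; validates the documented schema."""
    df = pd.read_csv(path_or_buf)
    missing = set(WORK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"work table is missing columns: {sorted(missing)}")
    return df


def work_sets_from_table(df: pd.DataFrame) -> dict:
    """Group a tidy work table into WorkSets keyed by (pair_id, leg, replica)."""
    out = {}
    for (pair, leg, rep), grp in df.groupby(["pair_id", "leg", "replica"]):
        fwd = grp.loc[grp["direction"] == "forward", "work_kj"].to_numpy()
        rev = grp.loc[grp["direction"] == "reverse", "work_kj"].to_numpy()
        out[(pair, leg, int(rep))] = WorkSet(fwd, rev, leg=leg, replica_id=int(rep))
    return out
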