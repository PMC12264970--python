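"""Scoring of predicted water placements against crystal waters.

A predicted water is counted as correctly placed when it lies within a
1 Å cutoff of a crystal-water position in the ligand binding site (the
region within 5 Å of any ligand heavy atom). Waters are treated as
points at their oxygen position; hydrogens are ignored.

Counting is by maximum-cardinality one-to-one matching on the bipartite
graph of predicted/reference pairs closer than the cutoff, so one
crystal water can never be "predicted" twice. A greedy nearest-first
variant is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "WaterSet",
    "MatchResult",
    "binding_site_waters",
    "match_waters",
    "site_restricted_match",
    "prediction_percentage",
]


@dataclass
class WaterSet:
    """Oxygen positions (Å) of a set of waters with a provenance label."""

    positions: np.ndarray
    label: str = "predicted"  # crystal | predicted | equilibrated

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("water positions must be finite")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class MatchResult:
    """Outcome of predicted-vs-reference matching.

    ``percentage`` is 100·n_matched/n_reference, or None when there are
    no reference waters (a distinct "no-reference" outcome, not 0).
    ``pairs`` holds (predicted index, reference index, distance Å).
    """

    n_reference: int
    n_predicted: int
    n_matched: int
    pairs: list = field(default_factory=list)

    @property
    def percentage(self) -> Optional[float]:
        if self.n_reference == 0:
            return None
        return 100.0 * self.n_matched / self.n_reference

    @property
    def has_reference(self) -> bool:
        return self.n_reference > 0


def binding_site_waters(structure, cutoff: float = 5.0) -> WaterSet:
    """Waters whose oxygen lies within ``cutoff`` (inclusive) of any
    ligand heavy atom of ``structure``."""
    lig = structure.ligand_heavy_positions()
    if lig.size == 0:
        raise ValueError("structure has no ligand heavy atoms")
    wat = structure.water_oxygen_positions()
    if wat.size == 0:
        return WaterSet(np.empty((0, 3)), label="crystal")
    dmin = cdist(wat, lig).min(axis=1)
    return WaterSet(wat[dmin <= cutoff], label="crystal")


def _match_optimal(d: np.ndarray, cutoff: float):
    allowed = d <= cutoff
    big = d.max(initial=1.0) * d.size + cutoff * (d.size + 1) + 1.0
    cost = np.where(allowed, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j), float(d[i, j])) for i, j in zip(rows, cols) if allowed[i, j]]


def _match_greedy(d: np.ndarray, cutoff: float):
    order = np.argsort(d, axis=None)
    used_p, used_r, pairs = set(), set(), []
    n_ref = d.shape[1]
    for flat in order:
        i, j = divmod(int(flat), n_ref)
        if d[i, j] > cutoff:
            break
        if i in used_p or j in used_r:
            continue
        used_p.add(i)
        used_r.add(j)
        pairs.append((i, j, float(d[i, j])))
    return pairs


def match_waters(
    predicted: WaterSet,
    reference: WaterSet,
    cutoff: float = 1.0,
    method: str = "optimal",
) -> MatchResult:
    """One-to-one matching of predicted to reference waters at ``cutoff``.

    "optimal" maximises the number of matches (minimum total distance
    among maximum-cardinality assignments); "greedy" pairs nearest first.
    """
    n_p, n_r = len(predicted), len(reference)
    if n_p == 0 or n_r == 0:
        return MatchResult(n_reference=n_r, n_predicted=n_p, n_matched=0)
    d = cdist(predicted.positions, reference.positions)
    if method == "optimal":
        pairs = _match_optimal(d, cutoff)
    elif method == "greedy":
        pairs = _match_greedy(d, cutoff)
    else:
        raise ValueError(f"unknown matching method {method!r}")
    return MatchResult(n_reference=n_r, n_predicted=n_p, n_matched=len(pairs), pairs=pairs)


def site_restricted_match(
    structure,
    predicted: WaterSet,
    site_cutoff: float = 5.0,
    match_cutoff: float = 1.0,
    method: str = "optimal",
) -> MatchResult:
    """Match predicted waters against the crystal waters of the binding
    site, ignoring (not penalising) predicted waters outside the site.

    The site is defined on the reference structure: within ``site_cutoff``
    of its ligand heavy atoms.
    """
    reference = binding_site_waters(structure, cutoff=site_cutoff)
    lig = structure.ligand_heavy_positions()
    if len(predicted):
        dmin = cdist(predicted.positions, lig).min(axis=1)
        predicted = WaterSet(predicted.positions[dmin <= site_cutoff], label=predicted.label)
    return match_waters(predicted, reference, cutoff=match_cutoff, method=method)


def prediction_percentage(
    results: Sequence[MatchResult], n_boot: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Mean per-structure placement percentage with a bootstrap SE.

    Structures with no reference waters are excluded from the mean (their
    percentage is undefined); at least one structure with references is
    required. The SE resamples structures (``n_boot`` draws, seeded).
    """
    pct = np.array([r.percentage for r in results if r.has_reference], dtype=float)
    if pct.size == 0:
        raise ValueError("no structures with reference waters")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pct.size, size=(n_boot, pct.size))
    boot = pct[idx].mean(axis=1)
    se = float(np.std(boot, ddof=1)) if n_boot > 1 else 0.0
    return float(pct.mean()), se
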