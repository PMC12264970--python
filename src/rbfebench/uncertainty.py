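"""Bootstrap uncertainty propagation for ΔΔG.

The standard error on a per-pair ΔΔG is built in four steps:

1. For every leg (protein, water) and every replica, the forward and
   reverse work values are resampled with replacement ``n_boot`` times and
   ΔG re-estimated for each resample; a Normal distribution is then
   constructed with mean equal to the un-bootstrapped point estimate and
   standard deviation equal to the SD of the bootstrapped ΔG values, and
   ``n_boot`` draws are taken from it.
2. The draws from all replicas of a leg are pooled into a set S_l and the
   leg standard error is SE(l) = sqrt(variance(S_l) / n_replica).
3. (Pooling is the concatenation in replica order.)
4. SE(ΔΔG) = sqrt(SE(protein)² + SE(water)²).

Variances and SDs use the unbiased (n−1) convention. All randomness flows
from a single integer seed; convergence failures on individual resamples
are skipped and redrawn (with a warning).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .estimator import (
    ConvergenceError,
    EstimatorConfig,
    WorkSet,
    _estimate_dg_many,
    estimate_dg,
)
from .units import kj_to_kcal

__all__ = [
    "BootstrapConfig",
    "PooledLegSamples",
    "DdgEstimate",
    "bootstrap_leg",
    "pool_replicas",
    "leg_se",
    "combine_se",
    "ddg_with_uncertainty",
]

logger = logging.getLogger(__name__)


def _workset_rng(seed: int, work_set: WorkSet) -> np.random.Generator:
    """A generator keyed by the seed and the work values themselves.

    Seeding on content (not on leg label or processing order) makes the
    reported SE exactly invariant under exchanging the two legs' labels.
    """
    h = zlib.crc32(work_set.forward.tobytes())
    h = zlib.crc32(work_set.reverse.tobytes(), h)
    return np.random.default_rng(np.random.SeedSequence([seed, h]))


@dataclass(frozen=True)
class BootstrapConfig:
    """n_boot resamples per leg/replica, n_replica replicas, one seed."""

    n_boot: int = 1000
    n_replica: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_boot < 1 or self.n_replica < 1:
            raise ValueError("n_boot and n_replica must be >= 1")


@dataclass
class PooledLegSamples:
    """Pooled Normal-redraw ΔG samples (kJ/mol) for one leg, all replicas."""

    leg: str
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class DdgEstimate:
    """Replica-averaged ΔΔG with its bootstrap SE, in kcal/mol."""

    ddg: float
    se: float
    pair_id: str = "pair"
    structure_source: str = "synthetic"

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("se must be >= 0")


def bootstrap_leg(
    work_set: WorkSet,
    config: BootstrapConfig,
    estimator_config: EstimatorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Step-1 samples for one leg of one replica.

    Returns ``n_boot`` draws from Normal(ΔG_point, SD(ΔG_b)), where
    ΔG_point uses the original works and ΔG_b the bootstrap resamples.
    """
    estimator_config = estimator_config or EstimatorConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    point = estimate_dg(work_set, estimator_config).dg
    wf, wr = work_set.forward, work_set.reverse
    n_boot = config.n_boot
    dgb = np.empty(n_boot)
    todo = n_boot
    filled = 0
    while todo > 0:
        f_idx = rng.integers(0, wf.size, size=(todo, wf.size))
        r_idx = rng.integers(0, wr.size, size=(todo, wr.size))
        try:
            got = _estimate_dg_many(wf[f_idx], wr[r_idx], estimator_config)
        except ConvergenceError:
            # Fall back to per-resample solves so only the bad ones are redrawn.
            got = []
            for k in range(todo):
                try:
                    got.append(
                        estimate_dg(
                            WorkSet(wf[f_idx[k]], wr[r_idx[k]], leg=work_set.leg),
                            estimator_config,
                        ).dg
                    )
                except ConvergenceError:
                    logger.warning("bootstrap resample failed to converge; redrawing")
            got = np.asarray(got)
        dgb[filled : filled + got.size] = got
        filled += got.size
        todo -= got.size
    sd = float(np.std(dgb, ddof=1)) if n_boot > 1 else 0.0
    return rng.normal(point, sd, size=n_boot)


def pool_replicas(per_replica_samples: Sequence[np.ndarray], leg: str) -> PooledLegSamples:
    """Concatenate per-replica sample vectors (equal lengths) in order."""
    arrays = [np.asarray(a, dtype=float) for a in per_replica_samples]
    if not arrays:
        raise ValueError("no replica samples to pool")
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("replica sample vectors differ in length")
    return PooledLegSamples(leg=leg, samples=np.concatenate(arrays))


def leg_se(pooled: PooledLegSamples, n_replica: int) -> float:
    """SE(l) = sqrt(variance(S_l) / n_replica), unbiased variance."""
    s = pooled.samples
    if s.size == 0:
        raise ValueError("empty pooled sample set")
    var = float(np.var(s, ddof=1)) if s.size > 1 else 0.0
    return float(np.sqrt(var / n_replica))


def combine_se(se_protein: float, se_water: float) -> float:
    """SE(ΔΔG) = sqrt(SE(protein)² + SE(water)²)."""
    if se_protein < 0 or se_water < 0:
        raise ValueError("standard errors must be non-negative")
    return float(np.hypot(se_protein, se_water))


def ddg_with_uncertainty(
    protein_sets: Sequence[WorkSet],
    water_sets: Sequence[WorkSet],
    config: BootstrapConfig | None = None,
    estimator_config: EstimatorConfig | None = None,
    pair_id: str = "pair",
    structure_source: str = "synthetic",
) -> DdgEstimate:
    """Full pipeline: per-replica ΔΔG average plus the four-step SE.

    ``protein_sets`` and ``water_sets`` hold one WorkSet per replica (same
    order). Output is converted to kcal/mol.
    """
    config = config or BootstrapConfig()
    estimator_config = estimator_config or EstimatorConfig()
    if len(protein_sets) != len(water_sets):
        raise ValueError("protein and water legs must have the same replica count")
    if len(protein_sets) != config.n_replica:
        raise ValueError(
            f"expected {config.n_replica} replicas per leg, got {len(protein_sets)}"
        )
    per_leg = {}
    for leg, sets in (("protein", protein_sets), ("water", water_sets)):
        per_replica = [
            bootstrap_leg(ws, config, estimator_config, rng=_workset_rng(config.seed, ws))
            for ws in sets
        ]
        per_leg[leg] = leg_se(pool_replicas(per_replica, leg), config.n_replica)
    ddgs = [
        estimate_dg(p, estimator_config).dg - estimate_dg(w, estimator_config).dg
        for p, w in zip(protein_sets, water_sets)
    ]
    se = combine_se(per_leg["protein"], per_leg["water"])
    return DdgEstimate(
        ddg=kj_to_kcal(float(np.mean(ddgs))),
        se=kj_to_kcal(se),
        pair_id=pair_id,
        structure_source=structure_source,
    )
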