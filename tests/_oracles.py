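"""Independent oracles the tests check the implementation against.

Each oracle takes a different computational route from the code under
test: the ML free energy is found by grid-minimising the Fermi-function
log-likelihood (not by root-finding the self-consistent equation), water
matching is solved by exhaustive enumeration of assignments, features by
O(N²) distance scans, and the OLS fit by the closed-form normal
equations.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def bar_nll(dg, wf, wr, kT):
    """Fermi-function negative log-likelihood of the two work samples.

    ``dg`` may be an array (broadcast against the samples). Reverse works
    ``wr`` are for the 1→0 process; their forward-frame works are −wr.
    """
    dg = np.asarray(dg, dtype=float)[..., None]
    M = kT * np.log(wf.size / wr.size)
    x = (M + wf - dg) / kT
    y = (M - wr - dg) / kT
    return np.logaddexp(0.0, -x).sum(axis=-1) + np.logaddexp(0.0, y).sum(axis=-1)


def grid_search_dg(wf, wr, kT, rounds=5, n_grid=401):
    """Dense-grid minimiser of the ML objective, iteratively refined.

    The likelihood is convex in ΔG, so each round keeps a ±2-bin margin
    around the argmin and zooms. Final precision ~ width/(n_grid/4)^rounds.
    """
    lo = min(wf.min(), (-wr).min()) - 10.0 * kT
    hi = max(wf.max(), (-wr).max()) + 10.0 * kT
    for _ in range(rounds):
        grid = np.linspace(lo, hi, n_grid)
        k = int(np.argmin(bar_nll(grid, wf, wr, kT)))
        lo = grid[max(k - 2, 0)]
        hi = grid[min(k + 2, n_grid - 1)]
    return 0.5 * (lo + hi)


def exhaustive_max_matching(pred: np.ndarray, ref: np.ndarray, cutoff: float) -> int:
    """Maximum number of one-to-one predicted/reference pairs within
    ``cutoff``, by enumerating all injective assignments (≤ 8 waters)."""
    pred = np.asarray(pred, dtype=float).reshape(-1, 3)
    ref = np.asarray(ref, dtype=float).reshape(-1, 3)
    n_p, n_r = len(pred), len(ref)
    if n_p == 0 or n_r == 0:
        return 0
    d = np.linalg.norm(pred[:, None, :] - ref[None, :, :], axis=-1)
    allowed = d <= cutoff
    if n_p <= n_r:
        perms = np.array(list(permutations(range(n_r), n_p)))
        hits = allowed[np.arange(n_p)[None, :], perms]
    else:
        perms = np.array(list(permutations(range(n_p), n_r)))
        hits = allowed[perms, np.arange(n_r)[None, :]]
    return int(hits.sum(axis=1).max())


def brute_force_site_waters(structure, cutoff=5.0):
    """All-pairs distance scan for waters within ``cutoff`` of the ligand."""
    lig = [a.pos for a in structure.atoms if a.role == "ligand" and a.element != "H"]
    out = []
    for a in structure.atoms:
        if a.role != "water" or a.element == "H":
            continue
        if min(float(np.linalg.norm(a.pos - l)) for l in lig) <= cutoff:
            out.append(a.pos)
    return np.asarray(out, dtype=float).reshape(-1, 3)


def brute_force_features(structure, cutoff=5.0):
    """Per-residue O(N²) recomputation of (lig_bf, n_wat, prot_bf)."""
    lig = [a.pos for a in structure.atoms if a.role == "ligand" and a.element != "H"]
    lig_b = [a.b_factor for a in structure.atoms if a.role == "ligand"]
    residues = {}
    for a in structure.atoms:
        if a.role == "protein":
            residues.setdefault(a.res_id, []).append(a)
    prot_b = []
    for _, atoms in residues.items():
        near = any(
            min(float(np.linalg.norm(a.pos - l)) for l in lig) <= cutoff for a in atoms
        )
        if near:
            prot_b.extend(a.b_factor for a in atoms)
    n_wat = len(brute_force_site_waters(structure, cutoff))
    return (
        float(np.mean(lig_b)),
        n_wat,
        float(np.mean(prot_b)) if prot_b else float("nan"),
    )


def ols_normal_equations(x, y):
    """Closed-form least squares: slope and intercept from the normal
    equations, with the textbook standard errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    s2 = np.sum(resid**2) / (n - 2) if n > 2 else 0.0
    se_slope = np.sqrt(s2 / sxx)
    se_intercept = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    return slope, intercept, se_slope, se_intercept


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random 3-D rotation matrix (QR of a Gaussian)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
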