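"""Spatially constrained permutations (spin test) and matched reference sets.

The spin test produces geometry-preserving null permutations of regions: a
uniform random 3D rotation is applied to the left-hemisphere centroids on the
unit sphere and its sagittal mirror conjugate to the right hemisphere, and
rotated positions are matched one-to-one to original positions by greedy
nearest-distance assignment within each hemisphere. Because parcels are
represented by centroids (not vertex patches), contiguity is preserved only
approximately — in spirit, through the rigid rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import special_ortho_group

from .graph_metrics import Connectome

__all__ = [
    "SpinEnsemble",
    "spin_rotations",
    "spun_sets",
    "profile_matched_set",
    "sum_matched_set",
    "spin_pvalue",
]


@dataclass
class SpinEnsemble:
    """Hemisphere-preserving node permutations from random sphere rotations."""

    permutations: np.ndarray  # (n_perm, N) each row a bijection
    n_perm: int
    seed: int | None = None


def _greedy_match(orig: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """One-to-one assignment: repeatedly take the globally closest pair.

    Returns ``assign`` with ``assign[i] = j`` meaning original position i is
    taken over by node j (the node whose rotated centroid lands nearest).
    """
    n = len(orig)
    d = np.linalg.norm(orig[:, None, :] - rotated[None, :, :], axis=2)
    order = np.argsort(d, axis=None)
    assign = np.full(n, -1)
    used_rows = np.zeros(n, dtype=bool)
    used_cols = np.zeros(n, dtype=bool)
    filled = 0
    for flat in order:
        i, j = divmod(int(flat), n)
        if used_rows[i] or used_cols[j]:
            continue
        assign[i] = j
        used_rows[i] = True
        used_cols[j] = True
        filled += 1
        if filled == n:
            break
    return assign


def spin_rotations(
    coordinates: np.ndarray,
    hemispheres: np.ndarray,
    n_perm: int,
    seed: int | None = None,
    _identity: bool = False,
) -> SpinEnsemble:
    """Draw ``n_perm`` hemisphere-preserving spin permutations.

    ``_identity=True`` is a test hook replacing every rotation with the
    identity, which must yield identity permutations.
    """
    if coordinates is None or hemispheres is None:
        raise ValueError("spin test needs coordinates and hemisphere labels")
    coordinates = np.asarray(coordinates, dtype=float)
    hemispheres = np.asarray(hemispheres)
    n = len(coordinates)
    left = np.flatnonzero(hemispheres == "L")
    right = np.flatnonzero(hemispheres == "R")
    if len(left) + len(right) != n:
        raise ValueError("hemisphere labels must be 'L' or 'R' for every node")
    mirror = np.diag([-1.0, 1.0, 1.0])
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=int)
    for k in range(n_perm):
        rot = np.eye(3) if _identity else special_ortho_group.rvs(3, random_state=rng)
        rot_right = mirror @ rot @ mirror  # sagittal mirror conjugate
        perm = np.empty(n, dtype=int)
        for idx, r in ((left, rot), (right, rot_right)):
            if len(idx) == 0:
                continue
            pts = coordinates[idx]
            assign = _greedy_match(pts, pts @ r.T)
            perm[idx] = idx[assign]
        perms[k] = perm
    return SpinEnsemble(permutations=perms, n_perm=n_perm, seed=seed)


def spun_sets(target, ens: SpinEnsemble) -> list[np.ndarray]:
    """Image of a node set under each spin permutation (sizes preserved)."""
    target = np.asarray(list(target), dtype=int)
    if len(target) == 0:
        raise ValueError("target set must be non-empty")
    return [np.sort(perm[target]) for perm in ens.permutations]


def _profile_criterion(w: np.ndarray, members: np.ndarray) -> float:
    """Mean pairwise correlation of connectivity rows among set members."""
    rows = w[members]
    r = np.corrcoef(rows)
    iu = np.triu_indices(len(members), k=1)
    return float(np.nanmean(r[iu]))


def _sum_criterion(w: np.ndarray, members: np.ndarray) -> float:
    sub = w[np.ix_(members, members)]
    return float(sub.sum() / 2.0)


def _matched_set(
    c: Connectome, target, n_candidates: int, seed, criterion
) -> np.ndarray:
    target = np.asarray(list(target), dtype=int)
    n = c.n_nodes
    if len(target) >= n:
        raise ValueError("target set must be smaller than the network")
    rng = np.random.default_rng(seed)
    goal = criterion(c.weights, target)
    best: np.ndarray | None = None
    best_dist = np.inf
    for _ in range(n_candidates):
        cand = rng.choice(n, size=len(target), replace=False)
        dist = abs(criterion(c.weights, cand) - goal)
        if dist < best_dist:  # strict: first sampled minimum wins ties
            best, best_dist = np.sort(cand), dist
    return best


def profile_matched_set(
    c: Connectome, target, n_candidates: int = 500, seed: int | None = None
) -> np.ndarray:
    """Random size-matched set whose within-set connectivity-profile
    similarity (mean pairwise row correlation) is closest to the target's."""
    return _matched_set(c, target, n_candidates, seed, _profile_criterion)


def sum_matched_set(
    c: Connectome, target, n_candidates: int = 500, seed: int | None = None
) -> np.ndarray:
    """Random size-matched set whose summed within-set connection weight is
    closest to the target's."""
    return _matched_set(c, target, n_candidates, seed, _sum_criterion)


def spin_pvalue(
    empirical: float, null_values, alternative: str = "greater"
) -> float:
    """Permutation p-value by plain exceedance counting (ties count).

    ``greater``: fraction of nulls >= empirical; ``less``: mirrored;
    ``two-sided``: twice the smaller side, capped at 1. Zero is a legal value
    (plug-in formula without the +1 correction).
    """
    null_values = np.asarray(list(null_values), dtype=float)
    if len(null_values) == 0:
        raise ValueError("need at least one null value")
    p_greater = float(np.mean(null_values >= empirical))
    p_less = float(np.mean(null_values <= empirical))
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise ValueError(f"unknown alternative {alternative!r}")
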