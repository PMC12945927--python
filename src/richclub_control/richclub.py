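"""Weighted rich-club detection against degree-preserving rewired nulls.

The weighted rich-club coefficient phi_w(k) compares the total weight among
nodes of degree > k to the sum of the equally many strongest weights anywhere
in the network. Because random graphs with heavy-tailed degree sequences show
elevated phi_w by chance, the empirical curve is normalized by the mean curve
of an ensemble of Maslov–Sneppen rewired surrogates (degree sequence and
weight multiset preserved exactly). The normalized coefficient Phi(k) peaks at
k_max_phi inside the significant regime; nodes of degree > k_max_phi form the
rich club.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_metrics import Connectome

__all__ = [
    "RichClubCurve",
    "RichClubAssignment",
    "weighted_rich_club_curve",
    "rewire_preserving_degree",
    "normalized_rich_club",
    "individual_rich_club",
    "group_rich_club",
    "group_size_from_fraction",
    "individual_topk_rich_club",
]


@dataclass
class RichClubCurve:
    """Empirical, null and normalized rich-club coefficients per degree level.

    Levels where phi is undefined (no edges remain above the threshold) carry
    NaN. ``k_max_phi`` is None when no degree level is significant.
    """

    k_levels: np.ndarray
    phi_emp: np.ndarray
    phi_null_mean: np.ndarray
    phi_norm: np.ndarray
    p_per_k: np.ndarray
    k_max_phi: int | None
    alpha: float = 0.05
    n_nulls: int = 0


@dataclass
class RichClubAssignment:
    """Rich-club membership flags for one connectome."""

    member_flags: np.ndarray
    k_cutoff: int | None
    source: str  # individual-curve | individual-topk | group

    def __post_init__(self) -> None:
        self.member_flags = np.asarray(self.member_flags, dtype=bool)

    @property
    def members(self) -> np.ndarray:
        return np.flatnonzero(self.member_flags)

    @property
    def size(self) -> int:
        return int(self.member_flags.sum())


# ---------------------------------------------------------------------------
# curve computation on edge arrays (degree sequence is rewiring-invariant, so
# nulls reuse the same machinery on swapped endpoint arrays)

def _edges(c: Connectome) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(c.n_nodes, k=1)
    present = c.weights[iu, ju] > 0
    return iu[present], ju[present], c.weights[iu, ju][present]


def _phi_from_edges(
    deg: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    w: np.ndarray,
    k_levels: np.ndarray,
    cum_top_w: np.ndarray,
) -> np.ndarray:
    """phi_w at each level from edge arrays.

    An edge lies within the degree->k club iff min(deg[u], deg[v]) > k, so a
    single sort of edges by that minimum yields every level at once.
    ``cum_top_w[e]`` must hold the sum of the e largest weights network-wide.
    """
    m = np.minimum(deg[u], deg[v])
    order = np.argsort(m, kind="stable")
    m_sorted = m[order]
    w_sorted = w[order]
    # suffix sums: weight of all edges with m > k
    suffix = np.concatenate([np.cumsum(w_sorted[::-1])[::-1], [0.0]])
    pos = np.searchsorted(m_sorted, k_levels, side="right")
    e_k = len(m) - pos
    w_k = suffix[pos]
    phi = np.full(len(k_levels), np.nan)
    defined = e_k > 0
    phi[defined] = w_k[defined] / cum_top_w[e_k[defined]]
    return phi


def weighted_rich_club_curve(c: Connectome) -> tuple[np.ndarray, np.ndarray]:
    """Empirical phi_w(k) for k = 1..max degree.

    Returns ``(k_levels, phi)`` with NaN where no edges survive the threshold.
    """
    deg = (c.weights > 0).sum(axis=1)
    u, v, w = _edges(c)
    if len(w) == 0:
        raise ValueError("rich-club curve undefined on an empty graph")
    k_levels = np.arange(1, deg.max() + 1)
    cum_top_w = np.concatenate([[0.0], np.cumsum(np.sort(w)[::-1])])
    return k_levels, _phi_from_edges(deg, u, v, w, k_levels, cum_top_w)


# ---------------------------------------------------------------------------
# Maslov–Sneppen rewiring

def _rewire_kernel(u, v, adj, pick_i, pick_j, flip):
    """Attempt double-edge swaps in place; weights ride along with edge slots."""
    for t in range(pick_i.shape[0]):
        i = pick_i[t]
        j = pick_j[t]
        if i == j:
            continue
        a = u[i]
        b = v[i]
        c = u[j]
        d = v[j]
        if flip[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        v[i] = d
        u[j] = c
        v[j] = b


try:  # optional JIT of the identical kernel
    from numba import njit

    _rewire_kernel = njit(cache=False)(_rewire_kernel)
except Exception:  # pragma: no cover - numba present in the supported env
    pass


def _rewired_edges(
    c_or_edges, n_nodes: int, iters_per_edge: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u, v, w = c_or_edges
    u = u.astype(np.int64).copy()
    v = v.astype(np.int64).copy()
    n_edges = len(u)
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    adj[u, v] = True
    adj[v, u] = True
    n_attempts = iters_per_edge * n_edges
    pick = rng.integers(0, n_edges, size=(n_attempts, 2))
    flip = rng.integers(0, 2, size=n_attempts).astype(bool)
    _rewire_kernel(u, v, adj, pick[:, 0], pick[:, 1], flip)
    return u, v, w


def rewire_preserving_degree(
    c: Connectome, iters_per_edge: int = 10, seed: int | None = None
) -> Connectome:
    """Degree-preserving randomization via double-edge swaps.

    Each of ``iters_per_edge * E`` attempts picks two edges (a,b), (c,d) and
    rewires them to (a,d), (c,b) unless that would create a self-loop or
    duplicate edge. Every edge keeps its weight, so the degree sequence and
    the weight multiset are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    u, v, w = _rewired_edges(_edges(c), c.n_nodes, iters_per_edge, rng)
    out = np.zeros_like(c.weights)
    out[u, v] = w
    out[v, u] = w
    return Connectome(
        out,
        node_ids=list(c.node_ids),
        coordinates=c.coordinates,
        hemisphere=c.hemisphere,
    )


def normalized_rich_club(
    c: Connectome,
    n_nulls: int = 200,
    iters_per_edge: int = 10,
    alpha: float = 0.05,
    seed: int | None = None,
) -> RichClubCurve:
    """Normalized rich-club curve Phi(k) against a rewired null ensemble.

    ``p_per_k`` is the one-sided exceedance fraction of null curves above the
    empirical curve; the significant regime is ``p < alpha`` (uncorrected),
    and ``k_max_phi`` maximizes Phi within it (ties to the smallest k).
    """
    if n_nulls < 20:
        raise ValueError("need at least 20 null networks")
    rng = np.random.default_rng(seed)
    deg = (c.weights > 0).sum(axis=1)
    edges = _edges(c)
    k_levels = np.arange(1, deg.max() + 1)
    cum_top_w = np.concatenate([[0.0], np.cumsum(np.sort(edges[2])[::-1])])
    phi_emp = _phi_from_edges(deg, *edges, k_levels, cum_top_w)

    null_curves = np.empty((n_nulls, len(k_levels)))
    for i in range(n_nulls):
        nu, nv, nw = _rewired_edges(edges, c.n_nodes, iters_per_edge, rng)
        null_curves[i] = _phi_from_edges(deg, nu, nv, nw, k_levels, cum_top_w)

    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN tail levels
        phi_null_mean = np.nanmean(null_curves, axis=0)
        phi_norm = phi_emp / phi_null_mean
        exceed = np.sum(null_curves >= phi_emp[None, :], axis=0)
    p_per_k = np.where(np.isnan(phi_emp), np.nan, exceed / n_nulls)

    significant = (p_per_k < alpha) & np.isfinite(phi_norm)
    k_max_phi: int | None = None
    if significant.any():
        sig_idx = np.flatnonzero(significant)
        best = sig_idx[np.argmax(phi_norm[sig_idx])]  # argmax takes first tie
        k_max_phi = int(k_levels[best])
    return RichClubCurve(
        k_levels=k_levels,
        phi_emp=phi_emp,
        phi_null_mean=phi_null_mean,
        phi_norm=phi_norm,
        p_per_k=p_per_k,
        k_max_phi=k_max_phi,
        alpha=alpha,
        n_nulls=n_nulls,
    )


# ---------------------------------------------------------------------------
# membership definitions

def individual_rich_club(curve: RichClubCurve, c: Connectome) -> RichClubAssignment:
    """Members are the nodes of degree strictly greater than k_max_phi."""
    if curve.k_max_phi is None:
        raise ValueError(
            "no significant rich-club regime; use individual_topk_rich_club "
            "with a fixed size instead"
        )
    deg = (c.weights > 0).sum(axis=1)
    return RichClubAssignment(
        member_flags=deg > curve.k_max_phi,
        k_cutoff=curve.k_max_phi,
        source="individual-curve",
    )


def group_size_from_fraction(fraction: float, n_nodes: int) -> int:
    """Round-half-away-from-zero of fraction * n_nodes."""
    return int(np.floor(fraction * n_nodes + 0.5))


def group_rich_club(
    assignments: list[RichClubAssignment],
    n_nodes: int,
    mean_degree: np.ndarray | None = None,
    fraction: float | None = None,
) -> RichClubAssignment:
    """Consensus rich club: the most consistently assigned nodes.

    The group size is the rounded mean individual membership fraction times
    ``n_nodes`` (or an explicit ``fraction``); members are the nodes most
    frequently assigned across individuals, frequency ties broken by higher
    mean degree, then by lower node index.
    """
    if not assignments:
        raise ValueError("need at least one individual assignment")
    freq = np.mean([a.member_flags for a in assignments], axis=0)
    if fraction is None:
        fraction = float(np.mean([a.size for a in assignments])) / n_nodes
    size = group_size_from_fraction(fraction, n_nodes)
    if mean_degree is None:
        mean_degree = np.zeros(n_nodes)
    order = np.lexsort((np.arange(n_nodes), -np.asarray(mean_degree), -freq))
    flags = np.zeros(n_nodes, dtype=bool)
    flags[order[:size]] = True
    return RichClubAssignment(member_flags=flags, k_cutoff=None, source="group")


def individual_topk_rich_club(c: Connectome, size: int) -> RichClubAssignment:
    """The ``size`` highest-degree nodes (ties by strength, then node index)."""
    if size > c.n_nodes:
        raise ValueError(f"requested size {size} exceeds {c.n_nodes} nodes")
    deg = (c.weights > 0).sum(axis=1)
    st = c.weights.sum(axis=1)
    order = np.lexsort((np.arange(c.n_nodes), -st, -deg))
    flags = np.zeros(c.n_nodes, dtype=bool)
    flags[order[:size]] = True
    return RichClubAssignment(member_flags=flags, k_cutoff=None, source="individual-topk")
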