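"""Node-level connectome descriptors and the cohort outlier rule.

The central container is :class:`Connectome`: a symmetric nonnegative weight
matrix over N cortical regions, optionally carrying unit-sphere region
coordinates and hemisphere labels. Weights are typically fractional-anisotropy
(FA) values in (0, 1], but number-of-streamlines (NOS) and binary variants are
supported through :func:`reweight`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Connectome",
    "RegionalMap",
    "degree",
    "strength",
    "participation_coefficient",
    "communicability",
    "cohort_outliers",
    "reweight",
]

_SYMMETRY_TOL = 1e-10


@dataclass
class Connectome:
    """A weighted undirected structural brain network.

    Parameters
    ----------
    weights
        (N, N) symmetric nonnegative matrix with an exactly-zero diagonal.
    node_ids
        Optional ordered region identifiers (defaults to ``"n000"...``).
    coordinates
        Optional (N, 3) unit-sphere region centroids.
    hemisphere
        Optional length-N array of ``"L"`` / ``"R"`` labels.
    planted_core
        Indices of a synthetically planted dense core, when the connectome
        came out of the cohort generator; ``None`` for real data.
    """

    weights: np.ndarray
    node_ids: list[str] | None = None
    coordinates: np.ndarray | None = None
    hemisphere: np.ndarray | None = None
    planted_core: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite entries")
        asym = np.abs(w - w.T).max() if w.size else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"weights not symmetric (max asymmetry {asym:.3g})")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        self.weights = (w + w.T) / 2.0
        np.fill_diagonal(self.weights, 0.0)
        if self.node_ids is None:
            self.node_ids = [f"n{i:03d}" for i in range(self.n_nodes)]
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.hemisphere is not None:
            self.hemisphere = np.asarray(self.hemisphere)
        if self.planted_core is not None:
            self.planted_core = np.asarray(self.planted_core, dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.weights > 0, directed=False)
        return bool(n_comp == 1)


@dataclass
class RegionalMap:
    """A scalar value per region (degree, gradient position, rank, ...)."""

    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("RegionalMap values must be one-dimensional")


def degree(c: Connectome) -> RegionalMap:
    """Per-node count of strictly positive connections."""
    return RegionalMap((c.weights > 0).sum(axis=1).astype(float), name="degree")


def strength(c: Connectome) -> RegionalMap:
    """Per-node sum of connection weights."""
    return RegionalMap(c.weights.sum(axis=1), name="strength")


def participation_coefficient(
    c: Connectome, labels: np.ndarray, use_binary: bool = False
) -> RegionalMap:
    """Participation coefficient of each node over a module partition.

    ``P_i = 1 - sum_m (s_im / s_i)**2`` with ``s_im`` node i's summed weight to
    module m and ``s_i`` its strength. High values mean a node's connections
    are spread evenly across modules; ``P_i = 0`` for isolated nodes.

    By default weights enter the sums; ``use_binary=True`` counts edges
    instead (degree-based variant).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != c.n_nodes:
        raise ValueError("labels length must match number of nodes")
    w = (c.weights > 0).astype(float) if use_binary else c.weights
    s = w.sum(axis=1)
    uniq = np.unique(labels)
    # s_im for all i, m at once
    per_module = np.stack([w[:, labels == m].sum(axis=1) for m in uniq], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = per_module / s[:, None]
    p = 1.0 - np.nansum(frac**2, axis=1)
    p[s == 0] = 0.0
    return RegionalMap(p, name="participation")


def communicability(c: Connectome) -> RegionalMap:
    """Regional communicability: weighted walks of all lengths.

    Computes ``G = expm(D^{-1/2} W D^{-1/2})`` with ``D = diag(strength)`` and
    returns the off-diagonal row sum per region. Zero-strength nodes cannot be
    normalized; they are excluded from the exponential and assigned 0, with a
    warning.
    """
    s = c.weights.sum(axis=1)
    out = np.zeros(c.n_nodes)
    alive = s > 0
    if not np.all(alive):
        warnings.warn(
            f"{int((~alive).sum())} zero-strength node(s) assigned "
            "communicability 0",
            stacklevel=2,
        )
    if alive.any():
        w = c.weights[np.ix_(alive, alive)]
        d_inv_sqrt = 1.0 / np.sqrt(s[alive])
        g = expm(d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :])
        out[alive] = g.sum(axis=1) - np.diag(g)
    return RegionalMap(out, name="communicability")


def cohort_outliers(cohort: list[Connectome]) -> np.ndarray:
    """Flag subjects whose connectome deviates from the group prevalence.

    Builds the group prevalence matrix (per edge, the number of subjects in
    which it is present), scores each subject by the summed prevalence of its
    own present edges, and flags scores outside ``[Q1 - 2*IQR, Q3 + 2*IQR]``
    (quartiles by linear interpolation).
    """
    if len(cohort) < 4:
        raise ValueError("cohort outlier rule needs at least 4 subjects")
    presence = np.stack([(c.weights > 0) for c in cohort])
    prevalence = presence.sum(axis=0)
    # upper triangle only so each edge counts once
    iu = np.triu_indices(prevalence.shape[0], k=1)
    scores = np.array(
        [(prevalence[iu] * p[iu]).sum() for p in presence], dtype=float
    )
    q1, q3 = np.percentile(scores, [25, 75])
    iqr = q3 - q1
    return (scores > q3 + 2 * iqr) | (scores < q1 - 2 * iqr)


def reweight(c: Connectome, scheme: str) -> Connectome:
    """Return the connectome under a weighting scheme.

    ``"fa"`` and ``"nos"`` are pass-through tags for already-weighted input;
    ``"binary"`` sets every positive weight to exactly 1.
    """
    if scheme in ("fa", "nos"):
        return c
    if scheme == "binary":
        return Connectome(
            (c.weights > 0).astype(float),
            node_ids=list(c.node_ids),
            coordinates=c.coordinates,
            hemisphere=c.hemisphere,
            planted_core=c.planted_core,
        )
    raise ValueError(f"unknown weighting scheme {scheme!r}")
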