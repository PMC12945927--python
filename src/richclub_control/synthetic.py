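"""Synthetic cohorts of weighted connectomes with a planted rich club.

The generator emulates the statistical structure the downstream analysis
relies on, with a known ground truth:

* bi-hemispheric unit-sphere region coordinates (right hemisphere a sagittal
  mirror of the left),
* a distance-decayed random graph with FA-like uniform weights and a planted
  densely interconnected core (elevated density and boosted weights) that
  produces a heavy right tail of degree and a genuine rich-club regime,
* per-subject variants of one template (weight resampling plus sparse edge
  toggling) standing in for inter-individual variability,
* per task a pair of activation states with a designed stability asymmetry:
  state A lives on the slow eigenmodes of the stabilized dynamics (cheap to
  hold), state B is tilted toward fast modes (expensive to hold).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import eigh

from .control import BrainState, stabilize
from .graph_metrics import Connectome

__all__ = [
    "CohortConfig",
    "generate_coordinates",
    "generate_template_connectome",
    "generate_cohort",
    "generate_state_pair",
    "generate_network_labels",
    "write_cohort",
]


@dataclass
class CohortConfig:
    """Generative law of a synthetic cohort.

    Defaults are desk-scale: 10 subjects on 100 regions with a fully dense
    10-node core over a distance-decayed background (density ratio 5), whose
    weights carry a mild boost. The mild boost matters: strongly boosted core
    weights make tiny sub-core clubs dominate the normalized rich-club curve
    (their few edges are the globally strongest), which spoils recovery of
    the full planted core, whereas the density contrast alone places the
    peak of the curve at the core itself.
    """

    n_subjects: int = 10
    n_nodes: int = 100
    core_size: int = 10
    base_density: float = 0.2
    core_density: float = 1.0
    weight_low: float = 0.1
    weight_high: float = 1.0
    core_weight_boost: float = 1.2
    feeder_boost: float = 1.5
    distance_decay: float = 1.0
    subject_jitter: float = 0.1
    n_tasks: int = 2
    state_gap: float = 1.0
    state_noise_sd: float = 0.05
    n_state_modes: int = 5
    core_activation_damping: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes % 2:
            raise ValueError("n_nodes must be even (two hemispheres)")
        if not 0 <= self.core_size < self.n_nodes:
            raise ValueError("core_size must be in [0, n_nodes)")
        if not 0 < self.base_density <= 1:
            raise ValueError("base_density must be in (0, 1]")
        if not self.base_density <= self.core_density <= 1:
            raise ValueError("core_density must be in [base_density, 1]")
        if self.weight_low <= 0 or self.weight_high < self.weight_low:
            raise ValueError("need 0 < weight_low <= weight_high")
        if self.core_weight_boost < 1:
            raise ValueError("core_weight_boost must be >= 1")
        if self.feeder_boost < 1:
            raise ValueError("feeder_boost must be >= 1")
        if self.distance_decay < 0 or self.state_gap < 0 or self.state_noise_sd < 0:
            raise ValueError("rates and noise levels must be nonnegative")
        if not 0 <= self.subject_jitter <= 1:
            raise ValueError("subject_jitter must be a fraction in [0, 1]")
        if not 0 <= self.core_activation_damping <= 1:
            raise ValueError("core_activation_damping must be in [0, 1]")

    def subject_seed(self, subject_index: int) -> int:
        """Per-subject seed: config.seed + 1000 * subject_index (documented)."""
        return self.seed + 1000 * subject_index


def generate_coordinates(
    n_nodes: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-sphere region centroids with mirrored hemispheres.

    The left hemisphere (x < 0) holds ``n_nodes/2`` points drawn uniformly on
    the half-sphere; the right hemisphere is its exact sagittal (x -> -x)
    mirror image. Returns ``(coordinates, hemisphere labels)`` with left nodes
    first.
    """
    if n_nodes % 2:
        raise ValueError("n_nodes must be even")
    rng = np.random.default_rng(seed)
    half = n_nodes // 2
    pts = rng.normal(size=(half, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts[:, 0] = -np.abs(pts[:, 0])  # left: x < 0
    mirror = pts * np.array([-1.0, 1.0, 1.0])
    coords = np.vstack([pts, mirror])
    hemi = np.array(["L"] * half + ["R"] * half)
    return coords, hemi


def _great_circle(coords: np.ndarray) -> np.ndarray:
    dots = np.clip(coords @ coords.T, -1.0, 1.0)
    return np.arccos(dots)


def generate_template_connectome(config: CohortConfig) -> Connectome:
    """Distance-decayed random graph with a planted dense core.

    Edge probability is ``base_density * exp(-distance_decay * d)`` for
    great-circle distance d, overridden to ``core_density`` between core
    nodes and multiplied by ``feeder_boost`` (capped at 1) for core-periphery
    pairs — hubs are hubs through abundant feeder edges, and without them an
    excluded core would be unreachable from the remaining controllers.
    Weights are uniform FA-like values in [weight_low, weight_high], boosted
    (capped at weight_high) on core-core edges. Disconnected draws are
    regenerated, up to 100 attempts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    coords, hemi = generate_coordinates(n, config.seed)
    core = np.sort(rng.choice(n, size=config.core_size, replace=False))
    is_core = np.zeros(n, dtype=bool)
    is_core[core] = True
    prob = config.base_density * np.exp(
        -config.distance_decay * _great_circle(coords)
    )
    core_pair = np.outer(is_core, is_core)
    feeder_pair = np.outer(is_core, ~is_core) | np.outer(~is_core, is_core)
    prob[feeder_pair] = np.minimum(prob[feeder_pair] * config.feeder_boost, 1.0)
    prob[core_pair] = config.core_density
    np.fill_diagonal(prob, 0.0)
    iu = np.triu_indices(n, k=1)
    for _ in range(100):
        present = rng.random(len(iu[0])) < prob[iu]
        w_edges = rng.uniform(config.weight_low, config.weight_high, len(iu[0]))
        boost = core_pair[iu]
        w_edges[boost] = np.minimum(
            w_edges[boost] * config.core_weight_boost, config.weight_high
        )
        w = np.zeros((n, n))
        w[iu] = np.where(present, w_edges, 0.0)
        w = w + w.T
        c = Connectome(
            w, coordinates=coords, hemisphere=hemi, planted_core=core
        )
        if c.is_connected():
            return c
    raise RuntimeError(
        "failed to generate a connected template in 100 attempts; "
        "increase base_density or lower distance_decay"
    )


def generate_cohort(config: CohortConfig) -> list[Connectome]:
    """n_subjects connectomes jittered from one template.

    Per subject, a ``subject_jitter`` fraction of existing edge weights is
    independently resampled, and a ``subject_jitter/2`` fraction of edges is
    toggled (equally many removals and additions, symmetry preserved). If the
    toggling disconnects the graph the removals are reverted, keeping the
    additions, so every subject stays connected.
    """
    template = generate_template_connectome(config)
    n = config.n_nodes
    core = template.planted_core
    is_core = np.zeros(n, dtype=bool)
    is_core[core] = True
    iu = np.triu_indices(n, k=1)
    cohort: list[Connectome] = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng(config.subject_seed(s))
        w = template.weights.copy()
        upper = w[iu]
        present_idx = np.flatnonzero(upper > 0)
        absent_idx = np.flatnonzero(upper == 0)
        core_edge = np.outer(is_core, is_core)[iu]

        # resample a jitter fraction of weights
        n_resample = int(round(config.subject_jitter * len(present_idx)))
        if n_resample:
            sel = rng.choice(present_idx, size=n_resample, replace=False)
            new_w = rng.uniform(config.weight_low, config.weight_high, n_resample)
            boost = core_edge[sel]
            new_w[boost] = np.minimum(
                new_w[boost] * config.core_weight_boost, config.weight_high
            )
            upper[sel] = new_w

        # toggle a jitter/2 fraction of edges on/off
        n_toggle = int(round(config.subject_jitter / 2 * len(present_idx)))
        n_toggle = min(n_toggle, len(absent_idx), len(present_idx))
        if n_toggle:
            off = rng.choice(present_idx, size=n_toggle, replace=False)
            on = rng.choice(absent_idx, size=n_toggle, replace=False)
            saved = upper[off].copy()
            upper[off] = 0.0
            new_w = rng.uniform(config.weight_low, config.weight_high, n_toggle)
            boost = core_edge[on]
            new_w[boost] = np.minimum(
                new_w[boost] * config.core_weight_boost, config.weight_high
            )
            upper[on] = new_w
            w2 = np.zeros((n, n))
            w2[iu] = upper
            w2 = w2 + w2.T
            if Connectome(w2).is_connected():
                w = w2
            else:
                upper[off] = saved  # keep additions, revert removals
                w2 = np.zeros((n, n))
                w2[iu] = upper
                w = w2 + w2.T
        else:
            w2 = np.zeros((n, n))
            w2[iu] = upper
            w = w2 + w2.T

        cohort.append(
            Connectome(
                w,
                node_ids=list(template.node_ids),
                coordinates=template.coordinates,
                hemisphere=template.hemisphere,
                planted_core=core,
            )
        )
    return cohort


def generate_state_pair(
    connectome: Connectome,
    config: CohortConfig,
    task_index: int,
    seed: int | None = None,
) -> tuple[BrainState, BrainState]:
    """A (more stable, less stable) activation pair for one task.

    State A is a unit-norm random combination of the ``n_state_modes`` slowest
    eigenmodes of the stabilized system (largest, least-negative eigenvalues)
    plus Gaussian noise; state B adds the same construction over the fastest
    modes with weight ``state_gap`` before renormalization. Both are scaled to
    the same Euclidean norm, so they differ in where — not how much —
    activation sits.

    Activation on the planted core is damped by ``core_activation_damping``
    (task-evoked amplitudes are empirically weakest on hub regions); this is
    what makes the planted core *passive*: it carries little state amplitude
    of its own while remaining the network's densest relay.
    """
    if seed is None:
        seed = config.seed + 7919 * (task_index + 1)
    rng = np.random.default_rng(seed)
    sys = stabilize(connectome)
    evals, evecs = eigh(sys.S)  # ascending: fast modes first
    s = min(config.n_state_modes, connectome.n_nodes)
    w_slow = rng.normal(size=s)
    w_fast = rng.normal(size=s)
    slow = evecs[:, -s:] @ w_slow
    slow /= np.linalg.norm(slow)
    fast = evecs[:, :s] @ w_fast
    fast /= np.linalg.norm(fast)

    noise_a = rng.normal(scale=config.state_noise_sd, size=connectome.n_nodes)
    noise_b = rng.normal(scale=config.state_noise_sd, size=connectome.n_nodes)
    a = slow + noise_a
    b_core = slow + config.state_gap * fast
    b_core /= np.linalg.norm(b_core)
    b = b_core + noise_b
    if connectome.planted_core is not None and len(connectome.planted_core):
        a[connectome.planted_core] *= config.core_activation_damping
        b[connectome.planted_core] *= config.core_activation_damping
    b *= np.linalg.norm(a) / np.linalg.norm(b)
    return (
        BrainState(a, label=f"task{task_index}-A"),
        BrainState(b, label=f"task{task_index}-B"),
    )


def generate_network_labels(
    n_nodes: int, n_networks: int, seed: int
) -> np.ndarray:
    """Spatially contiguous module labels in 1..n_networks.

    Runs a k-means-style assignment on the sphere coordinates: seed centroids
    from random nodes, assign each node to its nearest centroid, recenter,
    iterate. Every label is used at least once by construction.
    """
    if n_networks > n_nodes:
        raise ValueError("cannot have more networks than nodes")
    coords, _ = generate_coordinates(n_nodes, seed)
    rng = np.random.default_rng(seed)
    centers = coords[rng.choice(n_nodes, size=n_networks, replace=False)]
    labels = np.zeros(n_nodes, dtype=int)
    for _ in range(25):
        d = np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2)
        # nearest centroid, but guarantee each label keeps its seed node
        new_labels = d.argmin(axis=1)
        for m in range(n_networks):
            if not np.any(new_labels == m):
                new_labels[d[:, m].argmin()] = m
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for m in range(n_networks):
            pts = coords[labels == m]
            if len(pts):
                ctr = pts.mean(axis=0)
                nrm = np.linalg.norm(ctr)
                if nrm > 0:
                    centers[m] = ctr / nrm
    return labels + 1


def write_cohort(config: CohortConfig, outdir: str | Path) -> Path:
    """Materialize a cohort on disk in the package's TSV dialect.

    Writes one square TSV per subject, coordinates, labels, per-task state
    pairs, and a JSON manifest recording the config and the planted core.
    """
    from . import io as rcio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    template = cohort[0]
    rcio.write_coordinates(
        outdir / "coordinates.tsv", template.coordinates, template.hemisphere
    )
    labels = generate_network_labels(config.n_nodes, min(17, config.n_nodes), config.seed)
    rcio.write_vector(outdir / "labels.tsv", labels.astype(float))
    states_dir = outdir / "states"
    states_dir.mkdir(exist_ok=True)
    for s, c in enumerate(cohort):
        rcio.write_matrix(outdir / f"sub-{s:03d}_connectome.tsv", c.weights)
        for t in range(config.n_tasks):
            a, b = generate_state_pair(
                c, config, t, seed=config.subject_seed(s) + 31 * (t + 1)
            )
            rcio.write_vector(states_dir / f"sub-{s:03d}_task-{t}_state-A.tsv", a.x)
            rcio.write_vector(states_dir / f"sub-{s:03d}_task-{t}_state-B.tsv", b.x)
    manifest = {
        "config": asdict(config),
        "planted_core": [int(i) for i in template.planted_core],
        "n_subjects": config.n_subjects,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
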