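"""Desk-scale orchestration of the full analysis.

Given (or simulating) a cohort of weighted connectomes and per-task state
pairs, the pipeline detects the group rich club, builds size-matched null
sets, computes stability and transition energies under full, rich-club-
excluded and null-set-excluded control, and runs the covariate-adjusted
repeated-measures comparison per task and measure. Every number in the
report is a deterministic function of the run configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rcio
from .control import (
    BrainState,
    ControlSet,
    UncontrollableSetError,
    state_stability,
    stabilize,
    transition_energy,
)
from .graph_metrics import Connectome, cohort_outliers, degree, reweight
from .nulls import (
    profile_matched_set,
    spin_rotations,
    spun_sets,
    sum_matched_set,
)
from .richclub import (
    group_rich_club,
    individual_rich_club,
    individual_topk_rich_club,
    normalized_rich_club,
)
from .stats import (
    PairedDesign,
    activation_covariate,
    paired_effect_size,
    paired_t_one_tailed,
    rm_anova_covariate,
)
from .synthetic import CohortConfig, generate_cohort, generate_state_pair

__all__ = ["RunConfig", "RunReport", "run_within_task", "run_between_task",
           "run_parameter_sweep", "load_cohort"]

VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    mode: str = "simulate"  # simulate | load
    cohort: CohortConfig | None = None
    cohort_dir: str | None = None
    T_values: tuple = (1.0,)
    rho: float = 1.0
    n_steps: int = 1000
    weighting: str = "fa"  # fa | nos | binary
    richclub_mode: str = "group"  # group | individual-curve | individual-topk
    null_mode: str = "spin"  # spin | profile-matched | sum-matched
    n_perm_network: int = 50
    n_perm_regional: int = 1000
    n_nulls: int = 200
    iters_per_edge: int = 10
    n_candidates: int = 500
    alpha: float = 0.05
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.mode == "simulate" and self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)
        if any(t <= 0 for t in self.T_values):
            raise ValueError("all time horizons must be positive")
        for name in ("n_perm_network", "n_perm_regional", "n_nulls", "n_steps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def hash(self) -> str:
        payload = asdict(self)
        payload["T_values"] = list(self.T_values)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Tidy result tables plus a provenance block."""

    state_metrics: pd.DataFrame
    transition_metrics: pd.DataFrame
    exclusion_metrics: pd.DataFrame
    tests: pd.DataFrame
    provenance: dict
    between_task: pd.DataFrame | None = None

    def hash(self) -> str:
        h = hashlib.sha256()
        for df in (self.state_metrics, self.transition_metrics,
                   self.exclusion_metrics, self.tests, self.between_task):
            if df is not None:
                h.update(df.round(12).to_csv(index=False).encode())
        h.update(json.dumps(self.provenance, sort_keys=True, default=str).encode())
        return h.hexdigest()[:16]

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.state_metrics.to_csv(outdir / "state_metrics.tsv", sep="\t", index=False)
        self.transition_metrics.to_csv(
            outdir / "transition_metrics.tsv", sep="\t", index=False
        )
        self.exclusion_metrics.to_csv(
            outdir / "exclusion_metrics.tsv", sep="\t", index=False
        )
        self.tests.to_csv(outdir / "tests.tsv", sep="\t", index=False)
        if self.between_task is not None:
            self.between_task.to_csv(
                outdir / "between_task.tsv", sep="\t", index=False
            )
        (outdir / "report.json").write_text(
            json.dumps(
                {"provenance": self.provenance, "report_hash": self.hash()},
                indent=2,
                default=str,
            )
            + "\n"
        )
        return outdir


def load_cohort(cohort_dir: str | Path) -> tuple[list[Connectome], dict, dict]:
    """Load a cohort directory written by :func:`synthetic.write_cohort`.

    Returns ``(connectomes, states, manifest)`` where states maps
    ``(subject, task)`` to a (BrainState, BrainState) pair.
    """
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    coords, hemi = rcio.read_coordinates(cohort_dir / "coordinates.tsv")
    core = np.array(manifest.get("planted_core", []), dtype=int)
    cohort, states = [], {}
    n_tasks = manifest["config"]["n_tasks"]
    for s in range(manifest["n_subjects"]):
        w = rcio.read_matrix(cohort_dir / f"sub-{s:03d}_connectome.tsv")
        cohort.append(
            Connectome(w, coordinates=coords, hemisphere=hemi,
                       planted_core=core if len(core) else None)
        )
        for t in range(n_tasks):
            a = rcio.read_vector(
                cohort_dir / "states" / f"sub-{s:03d}_task-{t}_state-A.tsv",
                expected_n=w.shape[0],
            )
            b = rcio.read_vector(
                cohort_dir / "states" / f"sub-{s:03d}_task-{t}_state-B.tsv",
                expected_n=w.shape[0],
            )
            states[(s, t)] = (
                BrainState(a, label=f"task{t}-A"),
                BrainState(b, label=f"task{t}-B"),
            )
    return cohort, states, manifest


def _prepare(config: RunConfig):
    """Cohort, states, rich-club members and null sets for one run."""
    if config.mode == "simulate":
        cohort = generate_cohort(config.cohort)
        states = {
            (s, t): generate_state_pair(
                cohort[s], config.cohort, t,
                seed=config.cohort.subject_seed(s) + 31 * (t + 1),
            )
            for s in range(len(cohort))
            for t in range(config.cohort.n_tasks)
        }
        n_tasks = config.cohort.n_tasks
    elif config.mode == "load":
        cohort, states, manifest = load_cohort(config.cohort_dir)
        n_tasks = manifest["config"]["n_tasks"]
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # cohort screening, then reweighting
    n_total = len(cohort)
    keep = ~cohort_outliers(cohort) if len(cohort) >= 4 else np.ones(len(cohort), bool)
    kept = [i for i in range(len(cohort)) if keep[i]]
    n_excluded = n_total - len(kept)
    cohort = [reweight(cohort[i], config.weighting) for i in kept]
    states = {
        (new, t): states[(old, t)]
        for new, old in enumerate(kept)
        for t in range(n_tasks)
    }

    # rich-club membership
    assignments, sizes = [], []
    for i, c in enumerate(cohort):
        curve = normalized_rich_club(
            c, n_nulls=config.n_nulls, iters_per_edge=config.iters_per_edge,
            alpha=config.alpha, seed=config.seed + 17 * (i + 1),
        )
        if curve.k_max_phi is not None:
            assignments.append(individual_rich_club(curve, c))
            sizes.append(assignments[-1].size)
        else:
            assignments.append(None)
    fallback = int(round(np.mean(sizes))) if sizes else max(
        1, int(round(0.1 * cohort[0].n_nodes))
    )
    assignments = [
        a if a is not None else individual_topk_rich_club(c, fallback)
        for a, c in zip(assignments, cohort)
    ]
    mean_deg = np.mean([degree(c).values for c in cohort], axis=0)
    group = group_rich_club(assignments, cohort[0].n_nodes, mean_degree=mean_deg)

    if config.richclub_mode == "group":
        rc_sets = [group.members] * len(cohort)
    elif config.richclub_mode == "individual-curve":
        rc_sets = [a.members for a in assignments]
    elif config.richclub_mode == "individual-topk":
        rc_sets = [
            individual_topk_rich_club(c, group.size).members for c in cohort
        ]
    else:
        raise ValueError(f"unknown richclub_mode {config.richclub_mode!r}")

    # size-matched null sets per subject
    null_sets: list[list[np.ndarray]] = []
    template = cohort[0]
    if config.null_mode == "spin":
        ens = spin_rotations(
            template.coordinates, template.hemisphere,
            config.n_perm_network, seed=config.seed + 424243,
        )
        for rc in rc_sets:
            null_sets.append(spun_sets(rc, ens))
    elif config.null_mode in ("profile-matched", "sum-matched"):
        builder = (
            profile_matched_set
            if config.null_mode == "profile-matched"
            else sum_matched_set
        )
        for i, (c, rc) in enumerate(zip(cohort, rc_sets)):
            null_sets.append(
                [
                    builder(c, rc, n_candidates=config.n_candidates,
                            seed=config.seed + 1000 * i + k)
                    for k in range(config.n_perm_network)
                ]
            )
    else:
        raise ValueError(f"unknown null_mode {config.null_mode!r}")

    return cohort, states, n_tasks, rc_sets, null_sets, group, n_excluded


def _condition_metrics(sys, a, b, excluded, T, rho, n_steps):
    """(stability_A, stability_B, energy_AB, energy_BA) for one control set."""
    n = sys.n_nodes
    cs = (
        ControlSet.full(n)
        if excluded is None or len(excluded) == 0
        else ControlSet.excluding(n, excluded)
    )
    return (
        state_stability(sys, a, cs, T=T, rho=rho, n_steps=n_steps),
        state_stability(sys, b, cs, T=T, rho=rho, n_steps=n_steps),
        transition_energy(sys, a, b, cs, T=T, rho=rho, n_steps=n_steps),
        transition_energy(sys, b, a, cs, T=T, rho=rho, n_steps=n_steps),
    )


_MEASURES = ("stability_A", "stability_B", "energy_AB", "energy_BA")


def run_within_task(config: RunConfig) -> RunReport:
    """Within-task analysis: stabilities, transition energies, rich-club vs.
    null-set exclusion, and the covariate-adjusted repeated-measures tests."""
    (cohort, states, n_tasks, rc_sets, null_sets, group, n_excluded) = _prepare(config)
    T = config.T_values[0]
    state_rows, trans_rows, excl_rows = [], [], []
    failures = 0
    per_subject: dict = {}
    for s, c in enumerate(cohort):
        sys = stabilize(c)
        for t in range(n_tasks):
            a, b = states[(s, t)]
            try:
                full = _condition_metrics(
                    sys, a, b, None, T, config.rho, config.n_steps
                )
                rc = _condition_metrics(
                    sys, a, b, rc_sets[s], T, config.rho, config.n_steps
                )
                nulls = [
                    _condition_metrics(
                        sys, a, b, ns, T, config.rho, config.n_steps
                    )
                    for ns in null_sets[s]
                ]
            except UncontrollableSetError:
                failures += 1
                continue
            null_mean = tuple(np.mean([nv[i] for nv in nulls]) for i in range(4))
            per_subject[(s, t)] = {
                "full": full, "richclub": rc, "null_mean": null_mean,
                "cov": activation_covariate(a, b),
            }
            state_rows += [
                {"subject": s, "task": t, "state": "A", "stability": full[0]},
                {"subject": s, "task": t, "state": "B", "stability": full[1]},
            ]
            trans_rows += [
                {"subject": s, "task": t, "direction": "A->B", "energy": full[2]},
                {"subject": s, "task": t, "direction": "B->A", "energy": full[3]},
            ]
            for cond, vals in (("richclub", rc),) + tuple(
                (f"null_{k:02d}", nv) for k, nv in enumerate(nulls)
            ):
                for m, v in zip(_MEASURES, vals):
                    excl_rows.append(
                        {"subject": s, "task": t, "condition": cond,
                         "measure": m, "value": v}
                    )

    test_rows = []
    for t in range(n_tasks):
        subj = [s for s in range(len(cohort)) if (s, t) in per_subject]
        if len(subj) < 3:
            warnings.warn(f"task {t}: fewer than 3 usable subjects; tests skipped")
            continue
        for i, m in enumerate(_MEASURES):
            a_vals = np.array([per_subject[(s, t)]["richclub"][i] for s in subj])
            b_vals = np.array([per_subject[(s, t)]["null_mean"][i] for s in subj])
            cov = np.array(
                [per_subject[(s, t)]["cov"] for s in subj]
                if m.startswith("energy")
                else [0.0] * len(subj)
            )
            res = rm_anova_covariate(PairedDesign(a_vals, b_vals, cov))
            direction = "greater" if res.direction >= 0 else "less"
            t_stat, t_p = paired_t_one_tailed(a_vals, b_vals, direction)
            test_rows.append(
                {"task": t, "measure": m, "F": res.F, "p": res.p,
                 "direction": res.direction, "t": t_stat, "t_p_one_tailed": t_p,
                 "effect_size_d": paired_effect_size(a_vals, b_vals),
                 "n_subjects": len(subj), "df2": res.df2,
                 "n_null_sets": config.n_perm_network}
            )

    provenance = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": VERSION,
        "weighting": config.weighting,
        "T": T,
        "n_subjects_used": len(cohort),
        "n_outliers_excluded": n_excluded,
        "solver_failures": failures,
        "group_rich_club": [int(i) for i in group.members],
        "group_rich_club_size": group.size,
        "null_mode": config.null_mode,
        "richclub_mode": config.richclub_mode,
    }
    report = RunReport(
        state_metrics=pd.DataFrame(state_rows),
        transition_metrics=pd.DataFrame(trans_rows),
        exclusion_metrics=pd.DataFrame(excl_rows),
        tests=pd.DataFrame(test_rows),
        provenance=provenance,
    )
    if config.outdir:
        report.write(config.outdir)
    return report


def run_between_task(config: RunConfig, representative: str = "A") -> RunReport:
    """Between-task transitions among each task's representative state.

    Evaluates every ordered pair of representative states under rich-club vs.
    null-set exclusion, the per-target-state mean effect size, and its
    correlation with the target state's stability difference.
    """
    (cohort, states, n_tasks, rc_sets, null_sets, group, _) = _prepare(config)
    if n_tasks < 2:
        raise ValueError("between-task analysis needs at least 2 tasks")
    T = config.T_values[0]
    rep_idx = 0 if representative == "A" else 1
    reps = {
        (s, t): states[(s, t)][rep_idx]
        for s in range(len(cohort))
        for t in range(n_tasks)
    }
    systems = [stabilize(c) for c in cohort]

    # stability of each representative state under both exclusions
    stab = {}
    for s in range(len(cohort)):
        for t in range(n_tasks):
            x = reps[(s, t)]
            cs_rc = ControlSet.excluding(cohort[s].n_nodes, rc_sets[s])
            stab_rc = state_stability(
                systems[s], x, cs_rc, T=T, rho=config.rho, n_steps=config.n_steps
            )
            stab_null = np.mean(
                [
                    state_stability(
                        systems[s], x,
                        ControlSet.excluding(cohort[s].n_nodes, ns),
                        T=T, rho=config.rho, n_steps=config.n_steps,
                    )
                    for ns in null_sets[s]
                ]
            )
            stab[(s, t)] = (stab_rc, stab_null)

    pair_rows = []
    for t_from in range(n_tasks):
        for t_to in range(n_tasks):
            if t_from == t_to:
                continue
            e_rc, e_null = [], []
            for s in range(len(cohort)):
                x0, xt = reps[(s, t_from)], reps[(s, t_to)]
                cs_rc = ControlSet.excluding(cohort[s].n_nodes, rc_sets[s])
                e_rc.append(
                    transition_energy(
                        systems[s], x0, xt, cs_rc,
                        T=T, rho=config.rho, n_steps=config.n_steps,
                    )
                )
                e_null.append(
                    np.mean(
                        [
                            transition_energy(
                                systems[s], x0, xt,
                                ControlSet.excluding(cohort[s].n_nodes, ns),
                                T=T, rho=config.rho, n_steps=config.n_steps,
                            )
                            for ns in null_sets[s]
                        ]
                    )
                )
            pair_rows.append(
                {
                    "task_from": t_from,
                    "task_to": t_to,
                    # positive d: null-set exclusion costs more than rich-club
                    "effect_size_d": paired_effect_size(e_null, e_rc),
                    "mean_energy_richclub": float(np.mean(e_rc)),
                    "mean_energy_null": float(np.mean(e_null)),
                }
            )
    pairs = pd.DataFrame(pair_rows)

    target_rows = []
    for t_to in range(n_tasks):
        d_mean = pairs.loc[pairs.task_to == t_to, "effect_size_d"].mean()
        stab_diff = float(
            np.mean([stab[(s, t_to)][1] - stab[(s, t_to)][0]
                     for s in range(len(cohort))])
        )
        target_rows.append(
            {"task_to": t_to, "mean_effect_size": d_mean,
             "stability_diff_null_minus_rc": stab_diff}
        )
    targets = pd.DataFrame(target_rows)
    finite = targets.dropna()
    if len(finite) >= 3 and finite["mean_effect_size"].std() > 0 and (
        finite["stability_diff_null_minus_rc"].std() > 0
    ):
        r = float(
            np.corrcoef(
                finite["mean_effect_size"],
                finite["stability_diff_null_minus_rc"],
            )[0, 1]
        )
    else:
        r = float("nan")

    provenance = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": VERSION,
        "representative_state": representative,
        "effect_vs_stability_r": r,
        "group_rich_club": [int(i) for i in group.members],
    }
    report = RunReport(
        state_metrics=targets,
        transition_metrics=pairs,
        exclusion_metrics=pd.DataFrame(),
        tests=pd.DataFrame(),
        provenance=provenance,
        between_task=pairs,
    )
    if config.outdir:
        report.write(config.outdir)
    return report


def run_parameter_sweep(
    config: RunConfig, weightings: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Repeat the within-task analysis per time horizon / weighting scheme.

    Returns the concatenated test tables with ``T`` and ``weighting`` columns
    for side-by-side comparison of normalized energies.
    """
    weightings = weightings or (config.weighting,)
    frames = []
    for weighting in weightings:
        for t_horizon in config.T_values:
            sub = replace(
                config, T_values=(t_horizon,), weighting=weighting, outdir=None
            )
            rep = run_within_task(sub)
            tests = rep.tests.copy()
            tests["T"] = t_horizon
            tests["weighting"] = weighting
            tests["config_hash"] = sub.hash()
            frames.append(tests)
    return pd.concat(frames, ignore_index=True)
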