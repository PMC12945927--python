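"""Inferential layer: covariate-adjusted repeated-measures comparison,
one-tailed paired tests, regional control-impact ranks, and spin-based
inference on sets, maps and networks.

The headline model compares, within subject, a control metric computed with
the rich club excluded from the control set against the mean of the same
metric over size-matched null sets, adjusting for the mean regional
activation difference between initial and target state:

    metric ~ condition + covariate        (two-level within-subject factor)

With exactly two within-subject levels this is equivalent to regressing the
paired difference on the (centered) covariate and testing the intercept; the
F statistic reported here is that test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .graph_metrics import RegionalMap
from .nulls import SpinEnsemble, spin_pvalue

__all__ = [
    "RegionalRankTable",
    "PairedDesign",
    "RmAnovaResult",
    "activation_covariate",
    "rm_anova_covariate",
    "paired_t_one_tailed",
    "rank_regions",
    "set_mean_rank_test",
    "map_rank_correlation",
    "network_mean_ranks",
    "paired_effect_size",
]


@dataclass
class RegionalRankTable:
    """Control-impact ranks per region, task and measure (1 = most impact)."""

    ranks: pd.DataFrame  # columns: node, task, measure, rank
    mean_rank: np.ndarray  # per region, averaged over tasks x measures
    n_nodes: int


@dataclass
class PairedDesign:
    """Per-subject paired metric values with a continuous covariate."""

    condition_a: np.ndarray
    condition_b: np.ndarray
    covariate: np.ndarray

    def __post_init__(self) -> None:
        self.condition_a = np.asarray(self.condition_a, dtype=float)
        self.condition_b = np.asarray(self.condition_b, dtype=float)
        self.covariate = np.asarray(self.covariate, dtype=float)
        n = len(self.condition_a)
        if len(self.condition_b) != n or len(self.covariate) != n:
            raise ValueError("design arrays must have equal length")
        if n < 3:
            raise ValueError("need at least 3 subjects")
        for arr in (self.condition_a, self.condition_b, self.covariate):
            if not np.all(np.isfinite(arr)):
                raise ValueError("design contains non-finite values")


@dataclass
class RmAnovaResult:
    F: float
    p: float
    direction: int  # sign of mean(a - b)
    df1: int
    df2: int


def activation_covariate(x0, xT) -> float:
    """Mean regional activation difference between target and initial state."""
    a = np.asarray(getattr(x0, "x", x0), dtype=float)
    b = np.asarray(getattr(xT, "x", xT), dtype=float)
    if a.shape != b.shape:
        raise ValueError("states must have equal length")
    return float(np.mean(b - a))


def rm_anova_covariate(d: PairedDesign) -> RmAnovaResult:
    """Condition main effect of a two-level within-subject design with a
    continuous covariate.

    Realized as OLS of the paired difference on the mean-centered covariate;
    the intercept F-test (df 1, n-2) is the condition effect. A covariate
    without variance is dropped (df 1, n-1).
    """
    diff = d.condition_a - d.condition_b
    n = len(diff)
    if np.var(d.condition_a) == 0 and np.var(d.condition_b) == 0:
        if np.allclose(diff, 0):
            return RmAnovaResult(F=0.0, p=1.0, direction=0, df1=1, df2=n - 1)
        raise ValueError("zero variance in both conditions")
    if np.allclose(diff, diff[0]):
        if diff[0] == 0:
            return RmAnovaResult(F=0.0, p=1.0, direction=0, df1=1, df2=n - 1)
        raise ValueError(
            "paired differences are constant; F statistic undefined"
        )
    cv = d.covariate - d.covariate.mean()
    if np.allclose(cv, 0):
        x = np.ones((n, 1))
    else:
        x = np.column_stack([np.ones(n), cv])
    fit = sm.OLS(diff, x).fit()
    t0 = fit.tvalues[0]
    f = float(t0**2)
    df2 = int(fit.df_resid)
    p = float(sps.f.sf(f, 1, df2))
    direction = int(np.sign(diff.mean()))
    return RmAnovaResult(F=f, p=p, direction=direction, df1=1, df2=df2)


def paired_t_one_tailed(a, b, direction: str = "greater") -> tuple[float, float]:
    """Paired t-test with one-sided p in the stated direction of a vs b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(a) != len(b):
        raise ValueError("need at least 2 equal-length pairs")
    if np.allclose(a - b, (a - b)[0]) and np.std(a - b) == 0:
        raise ValueError("zero-variance differences; t statistic undefined")
    res = sps.ttest_rel(a, b, alternative=direction)
    return float(res.statistic), float(res.pvalue)


def rank_regions(lesion_deltas: dict) -> RegionalRankTable:
    """Rank regions by their control impact across tasks and measures.

    ``lesion_deltas`` maps task name to a dict with ``energy_delta`` and
    ``stability_delta`` arrays from :func:`control.regional_lesion_scan`.
    Impact is the energy increase (energy measure) or the stability decrease
    (stability measure) upon lesioning; rank 1 = largest impact. Ties resolve
    by node index; regions with missing (failed) lesions rank last with a
    warning.
    """
    records = []
    n_nodes = None
    for task, deltas in lesion_deltas.items():
        for measure, impact in (
            ("energy", np.asarray(deltas["energy_delta"], dtype=float)),
            ("stability", -np.asarray(deltas["stability_delta"], dtype=float)),
        ):
            if n_nodes is None:
                n_nodes = len(impact)
            missing = ~np.isfinite(impact)
            if missing.any():
                warnings.warn(
                    f"{int(missing.sum())} region(s) missing in task {task!r} "
                    f"{measure} scan; ranked last",
                    stacklevel=2,
                )
            key = np.where(missing, -np.inf, impact)
            order = np.lexsort((np.arange(n_nodes), -key))
            rank = np.empty(n_nodes, dtype=int)
            rank[order] = np.arange(1, n_nodes + 1)
            for node in range(n_nodes):
                records.append(
                    {"node": node, "task": task, "measure": measure,
                     "rank": int(rank[node])}
                )
    df = pd.DataFrame.from_records(records)
    mean_rank = (
        df.groupby("node")["rank"].mean().reindex(range(n_nodes)).to_numpy()
    )
    return RegionalRankTable(ranks=df, mean_rank=mean_rank, n_nodes=n_nodes)


def set_mean_rank_test(
    table: RegionalRankTable,
    node_set,
    ens: SpinEnsemble,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mean rank of a node set against spin-rotated sets.

    Default alternative 'greater' tests whether the set ranks higher (i.e.,
    contributes *less* control) than spatially rotated counterparts.
    """
    node_set = np.asarray(list(node_set), dtype=int)
    if len(node_set) == 0:
        raise ValueError("node set must be non-empty")
    emp = float(table.mean_rank[node_set].mean())
    nulls = [
        float(table.mean_rank[perm[node_set]].mean())
        for perm in ens.permutations
    ]
    return emp, spin_pvalue(emp, nulls, alternative=alternative)


def map_rank_correlation(
    table_or_ranks,
    regional_map: RegionalMap,
    ens: SpinEnsemble,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Product-moment correlation between ranks and a regional map, with a
    spin p-value obtained by rotating the map."""
    ranks = (
        table_or_ranks.mean_rank
        if isinstance(table_or_ranks, RegionalRankTable)
        else np.asarray(table_or_ranks, dtype=float)
    )
    values = regional_map.values
    if len(values) != len(ranks):
        raise ValueError("map length must match number of regions")
    if np.std(values) == 0:
        raise ValueError("zero-variance map; correlation undefined")
    r = float(np.corrcoef(ranks, values)[0, 1])
    nulls = [
        float(np.corrcoef(ranks, values[perm])[0, 1])
        for perm in ens.permutations
    ]
    return r, spin_pvalue(r, nulls, alternative=alternative)


def network_mean_ranks(
    table: RegionalRankTable, labels, ens: SpinEnsemble
) -> pd.DataFrame:
    """Mean regional rank per network with two one-sided spin p-values.

    ``p_low`` asks whether the network ranks lower than chance (more control
    contribution), ``p_high`` whether it ranks higher (less contribution).
    Empty labels are skipped with a warning.
    """
    labels = np.asarray(labels)
    if len(labels) != table.n_nodes:
        raise ValueError("labels length must match number of regions")
    rows = []
    for net in np.unique(labels):
        members = np.flatnonzero(labels == net)
        if len(members) == 0:  # pragma: no cover - np.unique excludes this
            warnings.warn(f"network {net!r} has no members; skipped")
            continue
        emp = float(table.mean_rank[members].mean())
        nulls = [
            float(table.mean_rank[perm[members]].mean())
            for perm in ens.permutations
        ]
        rows.append(
            {
                "network": net,
                "n_regions": len(members),
                "mean_rank": emp,
                "p_low": spin_pvalue(emp, nulls, alternative="less"),
                "p_high": spin_pvalue(emp, nulls, alternative="greater"),
            }
        )
    return pd.DataFrame(rows)


def paired_effect_size(a, b) -> float:
    """Cohen's d for paired samples: mean(a-b) / sd(a-b, ddof=1).

    A zero-variance difference yields the signed infinite sentinel.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(a) != len(b):
        raise ValueError("need at least 2 equal-length pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        return float(np.copysign(np.inf, diff.mean())) if diff.mean() != 0 else 0.0
    return float(diff.mean() / sd)
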