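# richclub-control

Network control theory of the rich club on weighted structural connectomes.

Hub regions of the brain preferentially wire to each other, forming a densely
interconnected **rich club**. Is that club a *control center* — the set of
regions doing the work of holding brain states in place and steering
transitions between them — or a passive relay that is itself easily driven by
the periphery? This package implements the full analysis needed to ask that
question quantitatively on any cohort of weighted, undirected connectomes:
rich-club detection against degree-preserving rewired nulls, optimal control
energy and state stability under manipulations of the control set, spatially
constrained (spin) null models, and the repeated-measures inference layer.
A synthetic cohort generator with a planted, ground-truth core makes every
stage testable without any imaging data.

Audience: researchers in network neuroscience / connectomics who want a
tested, reusable, scriptable version of this analysis, and methodologists who
want the pieces (solver, rich-club machinery, spin tests) individually.

## The model

Regional activity `x(t)` follows linear dynamics on the stabilized
connectivity matrix,

```
dx/dt = S x + B u,        S = A / (1 + λ_max(A)) − I,
```

where `A` is the (FA-, NOS- or binary-weighted) connectome and `B` selects
the **control set**: the regions allowed to inject input `u(t)`. The optimal
transition from state `x0` to `xT` over horizon `T` minimizes

```
J = ∫₀ᵀ (xT − x)ᵀ(xT − x) + ρ uᵀu  dt,     x(0) = x0,  x(T) = xT,
```

solved in closed form through the matrix exponential of the Hamiltonian block
matrix `[[S, −BBᵀ/2ρ], [−2I, −Sᵀ]]`. **Control energy** is the per-region
integral of `uᵢ(t)²` (normalized by the number of reference timesteps in `T`)
averaged over all regions; **stability** of a state is the inverse of the
energy needed to hold it (`x0 = xT`).

The weighted rich-club coefficient `φʷ(k)` is the total edge weight among
nodes of degree > k divided by the sum of the equally many strongest weights
anywhere in the network; the normalized coefficient `Φ(k) = φʷ(k) / ⟨φʷ_null(k)⟩`
uses Maslov–Sneppen rewired surrogates (degree sequence and weight multiset
preserved exactly), and the club is the set of nodes with degree above the
`Φ`-maximizing level within the significant regime.

Rich-club vs. reference-set contributions are compared by excluding each set
from `B` (excluded nodes stay in the dynamics — they can be driven, but not
drive) and testing, per task and measure,

```
metric  ~  condition (rich club / reference)  +  activation-difference covariate
```

as a two-level repeated-measures model, with spin-rotated or
connectivity-matched size-equated reference sets.

## Worked example

```python
from richclub_control import CohortConfig, RunConfig, run_within_task

config = RunConfig(
    mode="simulate",
    cohort=CohortConfig(n_subjects=6, n_tasks=1, seed=7),
    n_perm_network=10, n_nulls=100, n_steps=500, seed=7,
)
report = run_within_task(config)
print("group rich club:", report.provenance["group_rich_club"])
print(report.tests[["task", "measure", "F", "p", "direction", "effect_size_d"]])
```

prints

```
group rich club: [5, 22, 30, 54, 57, 63, 80, 84]
 task     measure          F        p  direction  effect_size_d
    0 stability_A  47.427220 0.000988          1       2.811501
    0 stability_B   3.978343 0.102648          1       0.814283
    0   energy_AB   4.655253 0.097150         -1      -0.681069
    0   energy_BA 158.751930 0.000228         -1      -3.887739
```

The detected group rich club is a subset of the generator's planted 10-node
core (`[5, 22, 30, 54, 57, 63, 74, 80, 84, 85]` for this seed). `direction`
is the sign of (rich-club-excluded − reference-excluded): positive for the
stability rows and negative for the energy rows means states stay *more*
stable and transitions cost *less* energy when the rich club is barred from
control than when a size-matched reference set is — the planted core is a
passive relay, not a driver. `F` and `p` come from the covariate-adjusted
repeated-measures comparison across the 6 simulated subjects (here with 10
reference sets; a real analysis would use 50, and `p ≈ 0.1` rows show how
weaker effects look at this small n).

A thin CLI wraps the same stages:

```bash
richclub-control simulate --n-subjects 10 --out cohort/
richclub-control richclub cohort/sub-000_connectome.tsv --out rc/
richclub-control run-all --cohort-dir cohort/ --out report/
```

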