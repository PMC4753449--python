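# ringflex

Conformational-plasticity analysis for ring-shaped oligomers of
two-domain protomers — hexameric replication initiators and their
relatives, where a rigid C6 ring of oligomerisation domains (OD) carries
mobile origin-binding domains (OBD) on hinges. The package is aimed at
structural biologists who have several conformers of such a ring
(crystal forms, symmetrised models, simulation snapshots) plus a
small-angle X-ray scattering (SAXS) curve, and want to know *which
motions connect the conformers* and *which conformer or mixture is
present in solution*.

Three connected analyses:

1. **Elastic-network normal modes and transition overlap.** A Cα
   anisotropic network model (spring cutoff 13 Å) yields modes v_i; the
   transition between two superposed conformers is the unit vector T,
   and the cumulative overlap

       dot_j = Σ_{i=1..j} (v_i · T)²

   measures how much of the transition the j lowest modes encode. Its
   chance level for random T is exactly j/3N (0.00055 for j = 2 at
   N = 1206 beads), and a seeded Monte-Carlo null provides Z-scores.
2. **Cn symmetrisation.** Any protomer is propagated around the
   invariant OD ring into an exactly six-fold model; models are ranked
   by inter-protomer Cα clashes (< 3.5 Å).
3. **SAXS fitting.** Debye-sum profiles from bead models, Guinier Rg,
   regularised p(r)/D_max estimation, error-weighted χ with closed-form
   scaling, OLIGOMER-style non-negative volume-fraction mixtures, and an
   EOM-style genetic algorithm that selects a fixed-size sub-ensemble
   from a conformer pool.

A synthetic-data module generates two-domain toy rings with prescribed
per-protomer hinge angles (C6/C3-like/C2-like symmetry classes),
mode-perturbed conformer pools, and noisy scattering curves with planted
mixture truth, so the entire pipeline is testable without downloads.

## Worked example

The numbered drivers under `analysis/` run the pipeline on the toy
system and write tables to `results/`. The SAXS arm
(`python analysis/04_saxs_mixture.py`) synthesises a noisy (1%) curve
from a planted 0.30/0.15/0.55 mixture of the C2-like, C3-like and
closed-C6 rings, then analyses it blind:

```
per-model fits:
model    chi  scale
   C2  7.845  0.977
   C6  9.981  1.070
   C3 15.796  0.739

mixture fit (chi = 0.89):
model  fitted_fraction  planted_fraction
   C6            0.542              0.55
   C2            0.317              0.30
   C3            0.141              0.15

GA ensemble selection: planted members (98, 99) -> picked (98, 99) with chi = 0.96
```

No single conformer explains the curve (χ ≈ 8–16), the fitted mixture
recovers the planted volume fractions to ±0.02 with χ at the noise
floor, and the genetic algorithm finds the planted two-member ensemble
inside a 100-conformer pool. The transition arm
(`python analysis/02_transition_overlap.py`) shows that toy-ring
transitions are strongly encoded in the low modes, e.g. dot10 = 0.74
for the C6→C2 transition against a chance level of 0.0074
(Z ≈ 224).

A `ringflex` command-line interface exposes the same steps on PDB files
(`ringflex inspect | rmsd | modes | overlap | morph | symmetrize |
saxs-fit | ensemble | simulate`).

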