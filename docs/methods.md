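# Methods

`ringflex` analyses the conformational plasticity of ring-shaped
oligomers built from two-domain protomers: a rigid inner ring of
oligomerisation domains (OD) carrying mobile outer origin-binding domains
(OBD) attached through a hinge. The reference system is a hexameric
replication initiator whose crystal forms show C2- and C3-symmetric OBD
arrangements over an invariant C6 OD ring. The pipeline has two arms —
elastic-network normal-mode analysis of the transitions between
conformers, and small-angle X-ray scattering (SAXS) model/mixture
fitting — joined by a Cn symmetrisation step that builds idealised
six-fold models from single protomers.

## Elastic network and normal modes

The anisotropic network model (ANM) is built on Cα beads: every pair
within a cutoff R_c is joined by a Hookean spring of uniform stiffness γ.
The Hessian superelements are

    H_ij = −γ (r_ij ⊗ r_ij) / d_ij²   (contacts, i ≠ j),
    H_ii = −Σ_{j≠i} H_ij,

giving a positive-semidefinite matrix with exactly six zero eigenvalues
(rigid translations and rotations) for a connected network. Modes are
obtained by dense symmetric diagonalisation; the six rigid modes are
identified by an eigenvalue threshold of 1e-6·λ_max and removed. More
than six near-zero eigenvalues is treated as an error (disconnected or
under-constrained network) rather than silently dropped.

Parameters: cutoff default 13 Å (the standard Cα-ANM range; the
accession-validation driver scans 10–18 Å), γ = 1 (every statistic
reported downstream is scale-invariant in γ), no mass weighting
(conventional for Cα-only networks). Degenerate eigenvalue pairs —
forced in multiplets by Cn symmetry — are reported as returned by the
solver; all cumulative statistics are invariant to rotations inside a
degenerate subspace, and `ModeSet.degenerate_pairs` flags them so
single-mode numbers can be interpreted with care. Eigenvector signs are
fixed (largest-magnitude component positive) for reproducible
serialisation only.

## Transition vectors and cumulative overlap

The transition vector T between two conformers is the 3N displacement of
the second conformer after least-squares (Kabsch) superposition onto the
first, unit-normalised, on the label intersection of the two bead sets
(missing residues are never imputed). The cumulative overlap with the
first j modes is the sum of squared projections

    dot_j = Σ_{i=1..j} (v_i · T)²  ∈ [0, 1].

Squared projections are used because their chance expectation for a
uniformly random unit T is exactly j/dof with dof = 3N — for the
1206-bead hexamer (residues 4–204 × 6 protomers) this gives 0.00055,
0.0014 and 0.0028 for j = 2, 5, 10 — whereas a signed sum has
expectation zero and no comparable calibration. dof = 3N rather than
3N−6 is a convention; the two are indistinguishable at two significant
figures at this size. Significance is quantified by a Z-score against a
seeded Monte-Carlo null of uniformly random unit vectors (normalised
Gaussians; default 10⁴ draws).

Dot products between two transitions are only defined when both are
expressed on the same labels in the same frame; for transitions sharing
a conformer both endpoints are superposed onto the shared conformer
first (`transition_vector_in_frame`).

## Ring-aware RMSD and symmetrisation

For ring oligomers the RMSD between two conformers is minimised over the
cyclic relabelings of one ring's protomers (`symmetry_rmsd`); order
reversal is not explored because the rings are oriented. Reflections
are excluded from all superpositions (backbone chirality).

A Cn-symmetrised model propagates one chosen protomer: its OD Cα set is
superposed onto each of the n OD positions of a template ring and each
rigid transform is applied to the whole protomer. The ring axis is the
smallest-variance principal axis of the OD centroids, anchored at their
mean. Steric plausibility is scored as the number of inter-protomer Cα
pairs closer than 3.5 Å; because no number defines "severe clash"
canonically, rankings across models (with the threshold anywhere in
3–4 Å) are the contract, not absolute counts. The toy demonstration
reproduces the expected behaviour: protomers whose outer domain is swung
far out of plane produce heavily clashing six-fold models, protomers
near the closed state produce clash-free ones.

## SAXS

Model profiles use the Debye double sum over one bead per residue with a
constant effective form factor,

    I(s) = Σ_i Σ_j f_i f_j sin(s d_ij)/(s d_ij),

with the i = j and s → 0 limits equal to f_i f_j. No hydration shell or
excluded-volume model is included. Consequently absolute χ values
against real detector data are not comparable with hydration-aware
predictors; χ *orderings* between models computed the same way, and
volume fractions of mixtures of such models, are the meaningful outputs.
An optional pair-distance-histogram evaluation (bin 0.2–0.5 Å) speeds up
large clouds with relative error well below other model error sources.

Guinier fits minimise weighted least squares of ln I vs s², iterating
the window to s·Rg ≤ 1.3 and then shrinking it (never below s·Rg ≈ 0.8)
while a quadratic term in s² would absorb more than 20% of the residual
variance — without this curvature guard the 1.3 window carries a ≈1.6%
systematic Rg overestimate on compact globular scatterers such as a
uniform sphere; with it the sphere error is ≈0.5%.

p(r) is estimated from data by a regularised indirect Fourier transform:
p on an n-point grid pinned to zero at r = 0 and r = D_max, solved by
non-negative least squares on the σ-whitened design matrix augmented
with a second-difference smoothness penalty (relative weight α = 1e-5
after normalising by the design/penalty Frobenius norms — weak enough
that the data term dominates, strong enough to suppress oscillation).
D_max is the smallest scan value whose reduced χ² is within 5% of the
scan minimum: larger D_max can always fit at least as well, so the
smallest statistically equivalent value is the defensible choice.

χ between an experimental and a computed curve uses the closed-form
optimal scale and an N−1 denominator; computed curves are interpolated
linearly in s onto the experimental grid with no extrapolation.
Volume-fraction mixtures are solved by non-negative least squares on
σ-whitened curves and normalised to the simplex. Ensemble selection runs
a genetic algorithm over fixed-size multisets of pool members (uniform
ensemble weighting, scale-fitted χ as fitness; tournament selection,
one-point crossover at rate 0.8, per-slot mutation at rate 0.1, elitism
of 1, population 100 × 200 generations by default), followed by a
mixture fit over the selected members to attach fractions.

## Synthetic data

The toy generator emulates the two-domain ring architecture: each domain
is a compact helix bundle of Cα-like beads (ideal α-helix geometry,
~3.8 Å virtual bonds; turns between bundle helices are looser but well
inside the ANM cutoff), the inner domains are placed with exact Cn
symmetry (default ring radius 14 Å keeps adjacent inner domains in
elastic contact at 13 Å), and each outer domain is rigidly rotated about
its hinge by a per-protomer angle, about an axis tilted 45° to the ring
axis. Angle patterns select the symmetry class: all equal → C6;
period-2 patterns → C3-like; period-3 patterns → C2-like. Default
domain sizes (30 inner + 45 outer beads per protomer, 450 beads per
hexamer) keep dense diagonalisation interactive while preserving the
ring phenomenology; tests use a 20+30 variant.

Conformer pools stand in for MD snapshots: frames displace the reference
along chosen modes with i.i.d. Gaussian amplitudes, so the ensemble RMS
along mode i equals the requested amplitude. Synthetic measurements
apply relative Gaussian noise with an s-dependent inflation (default 1%
floor, 3× at the top of the s range) and carry the matching σ column, so
χ of truth against simulation calibrates to 1.

What the generator does not emulate: real side-chain packing and
excluded volume, solvent/hydration contrast, anharmonic hinge
energetics, and inter-domain contacts that would couple hinge angles.
Passing the synthetic closure tests therefore demonstrates correctness
of the statistical machinery (profile computation, overlap calibration,
mixture/ensemble recovery), not the physical accuracy of any particular
elastic model for a real protein.

Two identifiability points are deliberate design: (i) the three basis
conformers of the planted ternary mixture use well-separated hinge-angle
patterns, because spherically averaged curves of nearby conformers are
nearly collinear and no solver could attribute fractions between them;
(ii) the planted pair in the ensemble-selection study are distinctive
open states among small-amplitude decoys — with an i.i.d. Gaussian pool
the mean curve of many wrong pairs coincides with the planted mean and
recovery is ill-posed for any optimiser.

## Numerical conventions

- Superposition requires ≥3 non-collinear common beads; collinearity is
  detected by a singular-value ratio of 1e-9.
- PDB coordinates round-trip at 1e-3 Å (format precision); residue
  numbering is author numbering, never renumbered.
- All stochastic steps (noise, null draws, pools, GA) take explicit
  seeds; reports embed a hash of the full configuration.
- Scattering profiles carry their s unit (Å⁻¹ or nm⁻¹) explicitly and
  conversions are explicit; coordinates are always Å.

## Known limitations

- Absolute χ against experimental curves is dominated by the missing
  hydration shell; only orderings are asserted.
- The clash count is a Cα-level proxy; all-atom sterics would shift
  absolute counts (not the toy rankings).
- The IFT's D_max has the usual weak identifiability from above;
  the Occam rule makes the choice deterministic but a ±(2–5)% bias at
  realistic noise is expected.
- `symmetry_rmsd` assumes equal per-protomer bead counts; rings with
  differing gap patterns between protomers are compared on fixed
  pairings after label intersection instead.
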