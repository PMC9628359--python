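# Methods

## Model

A protein of N residues is coarse-grained to its Cα positions X₀ and
modelled as an anisotropic elastic network: every pair (i, j) with
equilibrium separation d_ij ≤ R_c is joined by a Hookean spring, giving the
3N×3N Hessian with off-diagonal blocks

    H_ij = −(γ/d_ij²)·(r_ij ⊗ r_ij),   d_ij ≤ R_c,

and diagonal blocks fixed by translational invariance (block rows sum to
zero). Masses are unit — at one site per residue all sites are identical,
so mass-weighting is the identity. The conformational ensemble is the
Boltzmann distribution of the harmonic energy ½ΔXᵀHΔX, i.e. a zero-mean
Gaussian with covariance k_BT·H⁺ on the internal subspace. The six
zero-eigenvalue modes (rigid translations/rotations) are *counted*, not
assumed: a disconnected contact graph shows up as n_rigid > 6 plus a
warning rather than silently corrupting the analysis.

## Perturbation score (D-value)

A test point at position *a* is treated as a **fixed anchor**: springs of
constant k connect it to every Cα within the attachment cutoff r_p. Each
attachment adds a rank-one term k·(u uᵀ) to that residue's diagonal Hessian
block (u = unit vector residue→point), so the perturbation is ΔH = VVᵀ
with one column per attachment. V is projected onto the internal subspace
before the update — springs to a fixed anchor would otherwise penalise
rigid-body motion, and the unperturbed ensemble is only proper on the
internal subspace, so the two Gaussians are compared where both exist.
With G = ṼᵀH⁺Ṽ (m×m, m = number of attachments) the KL divergence of the
perturbed from the unperturbed ensemble has the closed form

    D = ½[ln det(I + G) − tr(G(I + G)⁻¹)] = ½ Σᵢ [ln(1+gᵢ) − gᵢ/(1+gᵢ)],

each term non-negative, so D ≥ 0 with equality only for a null
perturbation. D is dimensionless and independent of k_BT. Per point the
cost is O(m·N·n_modes + m³) after the one-time O(N³) decomposition; the
test suite verifies the formula to ≤ 10⁻⁸ against a dense oracle that
builds H′ = H + PΔHP explicitly and evaluates
½[ln det(H′H⁺) + tr(HH′⁻¹) − (3N − n_rigid)].

The fixed-anchor convention is the central modelling decision: a mobile
test particle whose coordinates are marginalised would give a different
(though related) divergence. The anchor form has an exact low-rank
solution, preserves the ranking behaviour the method relies on (regions
whose restraint most reshapes the soft-mode ensemble score highest), and
is verified by its own oracle rather than by identity with any other
formulation.

## Layered surface sampling

The solvent-accessible surface of the coarse model is sampled by placing a
deterministic Fibonacci lattice (rotated by a seed-derived random rotation)
on each residue sphere inflated by the probe radius, and keeping the points
that fall outside every other inflated sphere. Layer ℓ+1 re-runs the same
sampler on the body "protein + all previous layers", with previous points
acting as virtual alpha-carbons. With the defaults below each layer
advances by virtual-radius + probe = 3 Å — one probe diameter — which the
suite asserts at 3.0 ± 0.5 Å on a convex body. Points are deterministic
given (inputs, seed). Consequence of the coarse geometry: a groove narrower
than ≈ 9 Å between wall centres admits no test point at all, so fully
buried or very narrow pockets produce no prediction — the known failure
mode of surface-based perturbation analysis, reproduced rather than hidden.

## Screening, clustering, ranking

Within each layer, points with D ≥ mean + z·sd are selected (z = 1.0);
the statistics exclude points with no attachment (D = 0 by construction,
no information), and a zero-spread layer selects nothing. Per-layer
selections are clustered with OPTICS (min_samples = 5, reachability bound
max_eps = 3 Å); extraction is DBSCAN-style at eps = max_eps, because the
screened patches live on shells whose natural linking scale *is* the probe
diameter, and xi-style extraction fragments them; clusters below
min_samples are noise. Per-layer clusters whose closest points lie within
link_distance = 3 Å merge into one pocket (connected components of the
cluster graph), so radially stacked selections become a single pocket
growing outward along the ligand direction. Pockets are ranked by the
arithmetic mean D of their members; ties break to the larger pocket, then
by centroid, making the pipeline fully deterministic. The screening
threshold and clustering radii are the calibration knobs of the method —
the per-layer z-score exists because D magnitudes shrink with distance
from the protein, so a single global threshold would empty the outer
layers.

## Prediction and evaluation

R_P = residues with Cα within 6 Å of any rank-1 pocket point. Against an
annotated set R_L (SITE records, or the flagged 6 Å distance fallback when
a structure has ligands but no SITE records): precision |R_P∩R_L|/|R_P|,
recall |R_P∩R_L|/|R_L|, and the Matthews correlation of the residue-level
confusion matrix (TN = residues in neither set; MCC ≡ 0 when a marginal is
zero). Ligand extension: O_m = pocket points within 3.5 Å of a ligand
atom, S_l = ligand atoms within 3.5 Å of a pocket point; precision
|O_m|/|O_M|, recall |S_l|/|S_L|. The headline report evaluates the rank-1
pocket; per-rank tables and a clearly-labelled best-rank-by-MCC line are
also emitted, since the best cluster is not always rank 1. Reports print
the raw residue sets so any discrepancy between a ratio and its sets is
inspectable.

## Conformer sweep

The lowest internal mode (unit-normalised) generates 12 conformations at
amplitudes A·cos(iπ/12), i = 1..12 — a full vibration cycle; i = 6 is
exactly X₀ and the second half mirrors the first. The pipeline re-runs on
each conformation against the *original* ligand and annotation (the
perturbation is of the protein only). A is in Å·unit-mode units; since an
all-atom dihedral check is meaningless at Cα resolution, the sweep reports
the maximum per-atom displacement of the series instead, and the choice of
a physically sensible A is the user's. On the synthetic clamp, predictions
are stable for sub-Å displacements (A = 0.5 → max displacement ≈ 0.2 Å,
identical predictions across the cycle); larger amplitudes can flip the
rank-1 pocket, reflecting the tight margin between competing pockets on a
small body.

## Defaults

| parameter | default | meaning |
|---|---|---|
| R_c | 12.0 Å | ENM contact cutoff (standard Cα ANM range) |
| γ | 1.0 | spring constant (sets the energy unit; D is γ-independent in rank order) |
| k_perturb | 1.0 | test-spring constant, in units of γ |
| r_p | 8.0 Å | attachment cutoff for test springs |
| probe | 1.5 Å | water-sized probe |
| protein sphere | 3.0 Å | effective residue radius (Cα + side-chain bulk) |
| virtual sphere | 1.5 Å | radius of layer points as pseudo-atoms → 3 Å layer advance |
| samples/sphere | 64 | surface density (runtime vs pocket resolution) |
| n_layers | 3 | accuracy/cost balance; outer layers lose attachment contact |
| z_threshold | 1.0 | per-layer screening |
| min_samples / max_eps | 5 / 3.0 Å | OPTICS density floor and reachability bound |
| link_distance | 3.0 Å | cross-layer merge radius (one probe diameter) |
| LBS cutoff | 6.0 Å | pocket point → residue contact |
| contact cutoff | 3.5 Å | ligand-overlap contact |

With r_p = 8 Å and three layers, layer-3 points sit ≈ 10.5 Å from the
nearest Cα and usually have no attachments; layer 3 then contributes
nothing, which is the expected decay of the perturbation with distance,
not an error.

## Synthetic complexes: what they test, and what they don't

`make_toy_clamp` carves a slot between two prongs of a jittered-lattice
ellipsoid (lattice constant 3.8 Å, jitter σ = 0.2 Å), giving a compact
body whose softest internal mode is the prong-opening hinge and whose only
deep concavity is the groove; a 7-atom pseudo-ligand is strung along the
groove axis at mid-depth, and the ground truth is the residues within 6 Å
of it. An earlier design with two separate lobes joined by a one-atom
strand failed instructively: the strand's transverse wobble dominated the
soft spectrum and attracted all high D-values, so the carved single-body
design was adopted — the fixture must have the *hinge* as its soft mode
for the method's physics to be exercised at all. The default groove width
(10 Å wall-centre separation) keeps the groove accessible to the coarse
surface sampler (see above); widths down to 4 Å are accepted and reproduce
the inaccessible-pocket failure mode.

Problem sizes used throughout (N ≈ 104 residues per clamp, 20 seeds for
recovery rates, a 20-atom cloud for oracle checks, 64 samples/sphere) were
chosen so the whole validation runs in well under a minute per item on one
CPU while leaving the statistics stable across seed ranges.

What passing on the clamp shows: the end-to-end chain — network build,
mode decomposition, low-rank KL scoring, screening, clustering, merging,
ranking, evaluation — concentrates the top-ranked pocket in a genuine
hinge-coupled concavity and recovers its planted residues. What it does
not show: performance on real proteins, whose surfaces are rougher, whose
soft modes are messier, and whose annotated sites reflect chemistry the
Cα model cannot see. Absolute point counts per layer are also not
comparable to any particular molecular-surface program, as they depend on
the sampling density chosen here.

## Numerical choices and degenerate inputs

Rigid modes: eigenvalues below 10⁻⁸·λ_max. Attachments at distance
< 10⁻¹² Å are skipped (undefined direction). G is symmetrised by
construction; its eigenvalues are clipped at 0 before the log terms.
Coincident Cα sites are a hard error at network build. Empty ligands make
extension metrics an error (reported as "no ligand" in the pipeline);
empty pocket lists yield a flagged no-prediction report, exit 0. Altloc:
first-listed kept, alternates logged. PDB coordinate fields are validated
before parsing so malformed input fails with a line number rather than a
silent zero.

## Known limitations

- The fixed-anchor perturbation is one convention; marginalising a mobile
  ligand particle would change absolute D-values (ranking behaviour is
  what the validation pins down).
- Coarse-grained accessibility over-estimates the closure of narrow
  grooves (< 9 Å); all-atom surface programs see pockets this sampler
  cannot.
- Mean-D ranking can prefer a small extreme cluster over a large true
  pocket when the D landscape is flat; min_samples is the only guard.
- No multi-model NMR handling (first model only), no mmCIF writing, no
  all-atom chemistry.
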