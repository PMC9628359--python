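# mdpa — multilayer dynamics perturbation analysis

`mdpa` predicts **ligand-binding regions** on a protein surface — and the
**spatial extension** a ligand occupies inside the pocket — from the
structure alone, with no templates, no training data and no chemistry
beyond a Cα trace.

The premise: ligands bind where external interactions most perturb the
protein's intrinsic conformational dynamics. The protein is modelled as a
Cα elastic network with harmonic energy `U(X) = ½ ΔXᵀ H ΔX`, whose Boltzmann
ensemble `P(X) ∝ exp(−U/k_BT)` is a zero-mean Gaussian over the internal
(non-rigid) normal modes of the Hessian `H`. A *test point* `a` near the
surface attaches springs (constant `k`) to every Cα within a cutoff,
shifting the ensemble to `P⁽ᵃ⁾(X)`. Its score is the Kullback–Leibler
divergence

    D⁽ᵃ⁾ = ∫ dX ln( P⁽ᵃ⁾(X) / P(X) ) P⁽ᵃ⁾(X)
         = ½ Σᵢ [ ln(1 + gᵢ) − gᵢ/(1 + gᵢ) ],

where `gᵢ` are the eigenvalues of the small matrix `G = ṼᵀH⁺Ṽ` built from
the rank-one spring updates (`H⁺` = pseudo-inverse over internal modes).
Points in functional clefts couple to many residues moving in soft,
antiphase modes, so their D-values are large.

Because a single shell of surface points says nothing about how far a
ligand extends *into* a pocket, the analysis is **multilayer**: layer 1 is
sampled one probe radius (1.5 Å) off the coarse protein surface; each
further layer treats the previous points as virtual alpha-carbons and
samples the surface of the combined body, advancing ≈ 3 Å (one probe
diameter) per layer. High-D points of each layer (z-score screening) are
clustered with OPTICS, clusters are merged across layers by spatial
connectivity, and merged pockets are ranked by mean D-value. The rank-1
pocket yields the predicted binding residues (Cα within 6 Å of any pocket
point) and its point cloud is the predicted ligand extension, scored by
3.5 Å mutual-overlap precision/recall against the bound ligand.

## Worked example

The package ships a synthetic-complex generator (`mdpa.synthetic`): a
two-pronged "clamp" — the lysozyme archetype of two domains whose hinge
motion opens and closes a ligand groove — with a pseudo-ligand planted
along the groove and ground-truth binding residues known by construction.

```sh
$ mdpa fixture --out clamp.pdb --seed 7
wrote clamp.pdb: 104 residues, 7 ligand atoms, 12 cleft residues

$ mdpa run clamp.pdb --out clamp_out --seed 7
pockets: 9  rank-1 points: 106
rank-1 site precision=0.261 recall=1.000 MCC=0.406
rank-1 extension precision=0.292 recall=1.000
```

Reading the numbers: of the 12 annotated groove residues, all are recovered
(site recall 1.00); the prediction also includes surrounding residues, so
precision is 0.26 and the Matthews correlation of the residue-level
classification is 0.41. Every planted ligand atom lies within 3.5 Å of the
predicted pocket cloud (extension recall 1.00), while the cloud itself is
larger than the ligand (extension precision 0.29) — the pocket cloud maps
the whole accessible groove volume. `clamp_out/` contains `report.json`
(full provenance: config, seed, input checksum, per-layer counts, ranked
pockets, per-rank metrics), `points.tsv` (every test point with layer,
D-value, cluster and rank), `residues.tsv` (per-residue predicted/annotated
flags) and `clusters.pdb` (pocket clouds as pseudo-atoms, occupancy = layer,
B-factor = D-value, one chain per rank).

`mdpa eval` prints the per-rank metric table; `mdpa conformers -A <amp>`
re-runs the prediction on 12 structures displaced along the lowest normal
mode through a full cosine cycle (amplitudes `A·cos(iπ/12)`), probing the
stability of the prediction under hinge flexing.

The same pipeline runs on real PDB entries (`mdpa run 1abc.pdb --chains A
--out out/`): binding-site annotations are taken from SITE records when
present, otherwise from a flagged 6 Å distance fallback around the bound
hetero-groups (waters and common ions excluded).

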