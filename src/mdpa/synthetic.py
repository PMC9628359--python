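"""Synthetic coarse structures with a known binding cleft.

Real benchmark sets require curated PDB complexes; for development and
validation this module builds Cα-only pseudo-proteins whose pocket geometry
is known by construction.  The main fixture is a two-lobed "clamp" — the
shape of a lysozyme-like enzyme: two globular prongs facing each other
across an open groove, joined through a shared base — with a pseudo-ligand
planted along the groove axis.  The ground-truth binding residues are the
residues within 6 Å of the planted ligand.

The body is a jittered cubic lattice (spacing ≈ 3.8 Å, the Cα virtual-bond
length) rather than a random coil: the lattice guarantees a connected
elastic network and a genuinely concave cleft whose opening/closing hinge is
the softest internal mode, which the locality of the D-value needs.  No
attempt is made to mimic secondary structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enm import build_hessian, decompose
from .structures import CoarseStructure, LigandAtom, LigandSet, ResidueKey

_LATTICE_SPACING = 3.8


@dataclass
class ToyComplex:
    """Synthetic protein–ligand complex with known cleft residues."""

    structure: CoarseStructure
    ligand: LigandSet
    cleft_residues: set[ResidueKey]
    seed: int


def _lobe_points(n: int, rng: np.random.Generator, jitter: float = 0.35) -> np.ndarray:
    """n jittered cubic-lattice points nearest the lobe centre."""
    m = 1
    while (2 * m + 1) ** 3 < 4 * n:
        m += 1
    ax = np.arange(-m, m + 1) * _LATTICE_SPACING
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    pts = pts[order[:n]]
    return pts + rng.normal(scale=jitter, size=pts.shape)


def make_toy_clamp(
    n_per_lobe: int = 30,
    cleft_width: float = 10.0,
    seed: int = 0,
    n_ligand_atoms: int = 7,
    enm_cutoff: float = 12.0,
) -> ToyComplex:
    """Two-pronged clamp with a pseudo-ligand planted in its groove.

    An ellipsoidal lattice body with a slot carved between two prongs at
    ±x; the prong walls are ``cleft_width`` apart (centre-to-centre), the
    groove runs along z, opens at +y, and holds the ligand atoms strung
    along its axis at mid-depth.  ``n_per_lobe`` sets the prong size (the
    body radius scales as its cube root).  Note that at this coarse-grained
    resolution a groove much narrower than ~9 Å cannot host any test point
    (probe 1.5 Å over 3 Å residue spheres), mimicking the buried-cavity
    failure mode of surface-based pocket detection; the default width keeps
    the groove accessible.  Raises if the elastic network is disconnected
    at ``enm_cutoff``.
    """
    if n_per_lobe < 15:
        raise ValueError("n_per_lobe must be ≥ 15")
    if not (4.0 <= cleft_width <= 12.0):
        raise ValueError("cleft_width must be in [4, 12] Å")
    if not (5 <= n_ligand_atoms <= 10):
        raise ValueError("n_ligand_atoms must be in [5, 10]")
    rng = np.random.default_rng(seed)

    # one compact lattice body (ellipsoid) with a slot carved between two
    # prongs: a separate linker strand would dominate the soft-mode spectrum
    # with its own wobble, whereas a clamp carved from one mass has the
    # prong-opening hinge as its genuine low-frequency motion
    radius = (n_per_lobe * _LATTICE_SPACING**3) ** (1.0 / 3.0)
    ax_x, ax_y, ax_z = 1.10 * radius, 1.25 * radius, 0.72 * radius
    m = int(np.ceil(max(ax_x, ax_y, ax_z) / _LATTICE_SPACING)) + 1
    axis = np.arange(-m, m + 1) * _LATTICE_SPACING
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    body = pts[
        (pts[:, 0] / ax_x) ** 2 + (pts[:, 1] / ax_y) ** 2 + (pts[:, 2] / ax_z) ** 2 <= 1.0
    ]
    # carve the central column above the notch line, then set the
    # wall-to-wall separation of the two prongs to cleft_width
    y_notch = -0.45 * ax_y
    in_slot = (np.abs(body[:, 0]) < 2.0) & (body[:, 1] > y_notch)
    body = body[~in_slot]
    shift = (cleft_width - 2.0 * _LATTICE_SPACING) / 2.0
    half = np.abs(body[:, 0]) >= 2.0
    body[half, 0] += np.sign(body[half, 0]) * shift
    body = body + rng.normal(scale=0.20, size=body.shape)

    n = body.shape[0]
    structure = CoarseStructure(
        source_id=f"toyclamp_s{seed}",
        chains=["A"] * n,
        resnums=list(range(1, n + 1)),
        icodes=[""] * n,
        resnames=["GLY"] * n,
        coords=body,
    )

    # pseudo-ligand strung along the groove axis (z) at mid-depth of the slot
    y_top = body[:, 1].max()
    y_lig = y_notch + 0.5 * (y_top - y_notch)
    z_span = 0.40 * ax_z
    zs = np.linspace(-z_span, z_span, n_ligand_atoms)
    lig_atoms = [
        LigandAtom(name=f"C{j+1}", element="C",
                   coord=np.array([0.0, y_lig, z]), parent_het="A/LIG900")
        for j, z in enumerate(zs)
    ]
    ligand = LigandSet(atoms=lig_atoms)

    from .structures import residues_near_ligand

    cleft = residues_near_ligand(structure, ligand, cutoff=6.0).residues

    net = decompose(build_hessian(structure, cutoff=enm_cutoff))
    if net.n_rigid != 6:
        raise ValueError(
            f"toy clamp network not rigidly connected: {net.n_rigid} zero modes "
            f"(components: {net.n_components})"
        )
    return ToyComplex(structure=structure, ligand=ligand, cleft_residues=cleft, seed=seed)


def make_two_particle_system(third_atom: bool = False) -> CoarseStructure:
    """Minimal analytic substrate: two Cα 3.8 Å apart on the x axis.

    The 6×6 ANM Hessian of the pair has a single non-zero eigenvalue 2γ
    (the bond stretch); ``third_atom`` adds an off-axis site for
    connectivity tests.  Note the 2-particle variant bypasses the usual
    N ≥ 3 floor via direct construction.
    """
    coords = [[0.0, 0.0, 0.0], [3.8, 0.0, 0.0]]
    if third_atom:
        coords.append([1.9, 3.3, 0.0])
    n = len(coords)
    cs = CoarseStructure.__new__(CoarseStructure)
    cs.source_id = "two_particle" + ("_plus" if third_atom else "")
    cs.chains = ["A"] * n
    cs.resnums = list(range(1, n + 1))
    cs.icodes = [""] * n
    cs.resnames = ["GLY"] * n
    cs.coords = np.array(coords, dtype=float)
    return cs


def make_convex_blob(n: int = 30, seed: int = 0) -> CoarseStructure:
    """Single jittered-lattice globule (no cleft): a convex control fixture."""
    rng = np.random.default_rng(seed)
    pts = _lobe_points(n, rng)
    return CoarseStructure(
        source_id=f"blob_s{seed}",
        chains=["A"] * n,
        resnums=list(range(1, n + 1)),
        icodes=[""] * n,
        resnames=["GLY"] * n,
        coords=pts,
    )
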