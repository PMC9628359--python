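"""Layered solvent-accessible test-point generation.

Test points probe the space a ligand could occupy.  Layer 1 is a set of
points one probe radius off the coarse protein surface; layer ℓ+1 treats the
points of all previous layers as virtual alpha-carbons and samples the
surface of the combined body, so successive layers advance outward by about
one probe diameter.  Sampling is a deterministic Fibonacci lattice on each
generating sphere, rotated by a seed-derived random rotation; a candidate is
kept only if it lies outside the probe-inflated sphere of every generating
centre (the solvent-accessible criterion at this resolution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structures import CoarseStructure

logger = logging.getLogger(__name__)

_OCCLUSION_SLACK = 1e-6


@dataclass
class SurfaceLayer:
    """One layer of test points with (eventually) their D-values."""

    layer_index: int
    coords: np.ndarray                    # (S, 3)
    probe_radius: float
    sphere_radius_protein: float
    sphere_radius_virtual: float
    samples_per_sphere: int
    seed: int
    d_values: np.ndarray | None = None    # (S,), set by the scoring engine
    n_attachments: np.ndarray | None = None
    selected: np.ndarray | None = None    # bool mask set by screening

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors from the golden-angle lattice."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / phi
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sample_surface(
    centers: np.ndarray,
    radii: np.ndarray | float,
    probe_radius: float,
    samples_per_sphere: int = 64,
    seed: int = 0,
) -> np.ndarray:
    """Solvent-accessible point set of a union of spheres.

    Each centre contributes ``samples_per_sphere`` candidates on its inflated
    sphere (radius + probe); a candidate survives iff it is not inside any
    other centre's inflated sphere.  Deterministic for fixed inputs and seed.

    Returns the kept points as an (M, 3) array.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    if centers.shape[0] == 0:
        raise ValueError("no generating centres")
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (centers.shape[0],))
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if samples_per_sphere < 12:
        raise ValueError("samples_per_sphere < 12 undersamples the sphere")

    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=rng).as_matrix()
    lattice = fibonacci_sphere(samples_per_sphere) @ rot.T

    candidates = centers[:, None, :] + (radii[:, None, None] + probe_radius) * lattice[None, :, :]
    candidates = candidates.reshape(-1, 3)

    # A point on its own inflated sphere sits exactly at the threshold, so no
    # self-exclusion is needed: test distance to the nearest centre of each
    # radius class against that class's inflated radius.
    keep = np.ones(candidates.shape[0], dtype=bool)
    for rad in np.unique(radii):
        cls = centers[radii == rad]
        d, _ = cKDTree(cls).query(candidates, k=1)
        keep &= d >= (rad + probe_radius) - _OCCLUSION_SLACK
    return candidates[keep]


def build_layer(
    structure: CoarseStructure,
    previous_layers: list[SurfaceLayer],
    probe_radius: float = 1.5,
    sphere_radius_protein: float = 3.0,
    sphere_radius_virtual: float = 1.5,
    samples_per_sphere: int = 64,
    seed: int = 0,
) -> SurfaceLayer:
    """Build layer ℓ = len(previous_layers) + 1 of test points.

    Generating body = protein Cα spheres (radius ``sphere_radius_protein``,
    an effective residue size at one site per residue) plus every point of
    the previous layers as virtual atoms of radius ``sphere_radius_virtual``.
    With the defaults (virtual radius = probe radius = 1.5 Å) each layer sits
    ≈ 3 Å — one probe diameter — beyond the last.
    """
    for k, lay in enumerate(previous_layers, start=1):
        if lay.layer_index != k:
            raise ValueError("previous_layers must be layers 1..ℓ−1 in order")
    ell = len(previous_layers) + 1
    centers = [structure.coords]
    radii = [np.full(structure.n_residues, sphere_radius_protein)]
    for lay in previous_layers:
        if lay.n_points:
            centers.append(lay.coords)
            radii.append(np.full(lay.n_points, sphere_radius_virtual))
    pts = sample_surface(
        np.concatenate(centers),
        np.concatenate(radii),
        probe_radius=probe_radius,
        samples_per_sphere=samples_per_sphere,
        seed=seed + ell,  # distinct lattice rotation per layer
    )
    if pts.shape[0] == 0:
        logger.warning("layer %d is empty (fully occluded surface)", ell)
    return SurfaceLayer(
        layer_index=ell,
        coords=pts,
        probe_radius=probe_radius,
        sphere_radius_protein=sphere_radius_protein,
        sphere_radius_virtual=sphere_radius_virtual,
        samples_per_sphere=samples_per_sphere,
        seed=seed,
    )


def mean_layer_spacing(layers: list[SurfaceLayer]) -> list[float]:
    """Mean nearest-previous-layer distance for layers 2..L (diagnostic)."""
    out = []
    for prev, cur in zip(layers, layers[1:]):
        if prev.n_points == 0 or cur.n_points == 0:
            out.append(float("nan"))
            continue
        d, _ = cKDTree(prev.coords).query(cur.coords, k=1)
        out.append(float(d.mean()))
    return out
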