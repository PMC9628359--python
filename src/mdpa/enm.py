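"""Cα elastic network model (anisotropic flavour) and its normal modes.

The protein's conformational ensemble is modelled as a Boltzmann distribution
over a harmonic energy  U(X) = ½ ΔXᵀ H ΔX,  ΔX = X − X₀, built from springs
between Cα sites within a cutoff.  For a contact pair (i, j) at equilibrium
separation d_ij the off-diagonal 3×3 Hessian block is the (negative) scaled
projector onto the bond direction,

    H_ij = −(γ / d_ij²) · (r_ij ⊗ r_ij),

the standard anisotropic network model with uniform spring constant γ and
unit masses (mass-weighting is the identity at one site per residue).
Diagonal blocks follow from translational invariance.  The eigendecomposition
exposes the six rigid-body modes (counted, not assumed) and the internal-mode
subspace over which the perturbation analysis compares conformational
distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structures import CoarseStructure

logger = logging.getLogger(__name__)

#: Eigenvalues below RIGID_TOL · λ_max count as rigid-body (zero) modes.
RIGID_TOL = 1e-8


@dataclass
class ElasticNetwork:
    """ANM Hessian plus (after :func:`decompose`) its normal modes."""

    structure: CoarseStructure
    cutoff: float
    gamma: float
    hessian: np.ndarray
    n_components: int  # connected components of the contact graph
    eigenvalues: np.ndarray | None = None   # ascending, length 3N
    eigenvectors: np.ndarray | None = None  # columns, orthonormal
    n_rigid: int | None = None
    kBT: float = 1.0

    @property
    def n_atoms(self) -> int:
        return self.structure.n_residues

    @property
    def is_decomposed(self) -> bool:
        return self.eigenvalues is not None

    def _require_modes(self) -> None:
        if not self.is_decomposed:
            raise RuntimeError("call decompose() first")

    @property
    def internal_values(self) -> np.ndarray:
        """Eigenvalues of the internal (non-rigid) modes, ascending."""
        self._require_modes()
        return self.eigenvalues[self.n_rigid :]

    @property
    def internal_vectors(self) -> np.ndarray:
        """Orthonormal internal-mode matrix, shape (3N, 3N − n_rigid)."""
        self._require_modes()
        return self.eigenvectors[:, self.n_rigid :]

    @property
    def rigid_vectors(self) -> np.ndarray:
        self._require_modes()
        return self.eigenvectors[:, : self.n_rigid]


@dataclass
class ConformerSeries:
    """Structures displaced along one normal mode through a full cosine cycle.

    Conformation i (i = 1..12) is X₀ + A·cos(iπ/12)·v with v the unit-norm
    mode; conformation 6 coincides with X₀ (cos(π/2) = 0) and the second half
    of the cycle mirrors the first (cos((12−i)π/12) = −cos(iπ/12)).
    """

    mode_index: int          # 0-based index into the ascending spectrum
    amplitude_A: float
    mode_vector: np.ndarray  # (3N,), unit norm
    conformations: list[CoarseStructure] = field(default_factory=list)

    @property
    def max_atom_displacement(self) -> float:
        per_atom = np.linalg.norm(self.mode_vector.reshape(-1, 3), axis=1)
        return abs(self.amplitude_A) * float(per_atom.max())


def build_hessian(
    structure: CoarseStructure, cutoff: float = 12.0, gamma: float = 1.0
) -> ElasticNetwork:
    """Assemble the anisotropic-network Hessian for Cα contacts within cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    X = structure.coords
    n = X.shape[0]
    tree = cKDTree(X)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")

    H = np.zeros((3 * n, 3 * n))
    adj = np.zeros((n, n), dtype=bool)
    for i, j in pairs:
        r = X[j] - X[i]
        d2 = float(r @ r)
        if d2 == 0.0:
            raise ValueError(f"coincident Cα sites {i} and {j}")
        block = (gamma / d2) * np.outer(r, r)
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[sl_i, sl_j] -= block
        H[sl_j, sl_i] -= block
        H[sl_i, sl_i] += block
        H[sl_j, sl_j] += block
        adj[i, j] = adj[j, i] = True

    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        logger.warning(
            "contact graph has %d components at cutoff %.1f Å; more than 6 rigid modes expected",
            n_comp, cutoff,
        )
    return ElasticNetwork(
        structure=structure, cutoff=cutoff, gamma=gamma, hessian=H, n_components=n_comp
    )


def decompose(network: ElasticNetwork) -> ElasticNetwork:
    """Full symmetric eigendecomposition of the Hessian (in place).

    Sets ascending eigenvalues, orthonormal eigenvector columns and the
    counted number of near-zero (rigid-body) modes.
    """
    H = network.hessian
    try:
        w, v = scipy.linalg.eigh(H)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise RuntimeError(f"eigensolver failed: {exc}") from exc
    lam_max = float(w[-1]) if w.size else 0.0
    tol = RIGID_TOL * max(lam_max, 1.0e-300)
    network.eigenvalues = w
    network.eigenvectors = v
    network.n_rigid = int(np.count_nonzero(w < tol))
    if network.n_rigid != 6:
        logger.info("counted %d rigid modes (6 expected for a connected 3-D network)", network.n_rigid)
    return network


def make_conformer_series(network: ElasticNetwork, amplitude_A: float) -> ConformerSeries:
    """Displace the structure along its lowest internal mode.

    Twelve conformations at amplitudes A·cos(iπ/12), i = 1..12, spanning a
    full vibration cycle of the lowest-frequency non-rigid normal mode (the
    hinge motion, for a two-lobed protein).  The mode vector is normalised to
    unit Euclidean length before scaling, so A is in Å · unit-mode units.
    """
    network._require_modes()
    if not np.isfinite(amplitude_A):
        raise ValueError("amplitude must be finite")
    if network.n_rigid >= 3 * network.n_atoms:
        raise ValueError("no internal modes available")
    mode = network.eigenvectors[:, network.n_rigid].copy()
    mode /= np.linalg.norm(mode)
    X0 = network.structure.coords
    confs = []
    for i in range(1, 13):
        # cos(iπ/12) evaluated so that c₆ = 0 and c₁₂₋ᵢ = −cᵢ hold exactly
        if i == 6:
            cos_i = 0.0
        elif i < 6:
            cos_i = np.cos(i * np.pi / 12.0)
        else:
            cos_i = -np.cos((12 - i) * np.pi / 12.0)
        c = amplitude_A * cos_i
        coords = X0 + c * mode.reshape(-1, 3)
        confs.append(
            network.structure.with_coords(coords, source_id=f"{network.structure.source_id}_m{i:02d}")
        )
    return ConformerSeries(
        mode_index=network.n_rigid,
        amplitude_A=float(amplitude_A),
        mode_vector=mode,
        conformations=confs,
    )
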