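"""Dynamics perturbation scoring: the allosteric potential D-value.

A test interaction at surface position *a* attaches springs (constant k)
between the test point, treated as a fixed anchor, and every Cα within an
attachment cutoff.  The perturbed harmonic ensemble P⁽ᵃ⁾(X) differs from the
unperturbed P(X), and the D-value is their Kullback–Leibler divergence

    D⁽ᵃ⁾ = ∫ dX ln(P⁽ᵃ⁾(X)/P(X)) P⁽ᵃ⁾(X),

evaluated in closed form over the internal-mode subspace.  Because each
attachment adds a rank-one term k·(u uᵀ) to one diagonal Hessian block, the
perturbation is ΔH = V Vᵀ with at most m = #attachments columns, and with
G = ṼᵀH⁺Ṽ (Ṽ the projection of V onto the internal subspace, H⁺ the
pseudo-inverse over internal modes):

    D = ½ [ ln det(I + G) − tr( G (I + G)⁻¹ ) ]
      = ½ Σᵢ [ ln(1 + gᵢ) − gᵢ/(1 + gᵢ) ],      gᵢ = eigenvalues of G ≥ 0.

Each term is non-negative, so D ≥ 0, vanishing only for a null perturbation.
Per-point cost is O(m·N·n_modes + m³) after the one-time decomposition;
large D marks surface regions whose perturbation most reshapes the protein's
internal conformational distribution — the binding-prone regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree

from .enm import ElasticNetwork
from .structures import CoarseStructure
from .surface import SurfaceLayer

logger = logging.getLogger(__name__)


@dataclass
class PerturbationModel:
    """Test-interaction parameters.

    k_perturb : spring constant of the test springs (units of γ).
    attach_cutoff_rp : Å; Cα within this distance of the test point get a spring.
    min_attachments : points with fewer attachments score D = 0.
    """

    k_perturb: float = 1.0
    attach_cutoff_rp: float = 8.0
    min_attachments: int = 1

    def __post_init__(self) -> None:
        if self.k_perturb < 0:
            raise ValueError("k_perturb must be non-negative")
        if self.attach_cutoff_rp <= 0:
            raise ValueError("attach_cutoff_rp must be positive")


def attachments(
    point: np.ndarray, structure: CoarseStructure, model: PerturbationModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cα sites coupled to the test point.

    Returns (atom indices, unit vectors atom→point, distances); all empty if
    no Cα lies within the attachment cutoff.
    """
    p = np.asarray(point, dtype=float).reshape(3)
    diff = p[None, :] - structure.coords
    d = np.linalg.norm(diff, axis=1)
    mask = (d <= model.attach_cutoff_rp) & (d > 1e-12)
    idx = np.nonzero(mask)[0]
    units = diff[idx] / d[idx, None]
    return idx, units, d[idx]


def _d_from_g_eigvals(g: np.ndarray) -> float:
    g = np.clip(g, 0.0, None)
    return float(0.5 * np.sum(np.log1p(g) - g / (1.0 + g)))


def _d_value_from_attachments(
    network: ElasticNetwork, idx: np.ndarray, units: np.ndarray, k_perturb: float
) -> float:
    if idx.size == 0 or k_perturb == 0.0:
        return 0.0
    U = network.internal_vectors
    lam = network.internal_values
    # B[:, j] = U[3i:3i+3, :]ᵀ · (√k u_j)  — the internal-basis image of column j of V.
    m = idx.size
    B = np.empty((U.shape[1], m))
    sqk = np.sqrt(k_perturb)
    for j in range(m):
        a = idx[j]
        B[:, j] = U[3 * a : 3 * a + 3, :].T @ (sqk * units[j])
    G = (B / lam[:, None]).T @ B
    g = scipy.linalg.eigvalsh(G)
    d = _d_from_g_eigvals(g)
    if not np.isfinite(d):
        raise RuntimeError("non-finite D-value: broken eigendecomposition?")
    return d


def d_value(
    network: ElasticNetwork, point: np.ndarray, model: PerturbationModel
) -> float:
    """KL divergence between perturbed and unperturbed ensembles for one point."""
    network._require_modes()
    idx, units, _ = attachments(point, network.structure, model)
    if idx.size < model.min_attachments:
        return 0.0
    return _d_value_from_attachments(network, idx, units, model.k_perturb)


def score_layer(
    network: ElasticNetwork, layer: SurfaceLayer, model: PerturbationModel
) -> SurfaceLayer:
    """Fill the layer's D-values (and attachment counts) in place."""
    network._require_modes()
    S = layer.n_points
    d_vals = np.zeros(S)
    n_att = np.zeros(S, dtype=int)
    if S:
        tree = cKDTree(network.structure.coords)
        neigh = tree.query_ball_point(layer.coords, model.attach_cutoff_rp)
        X = network.structure.coords
        for p in range(S):
            idx = np.asarray(neigh[p], dtype=int)
            if idx.size == 0:
                continue
            diff = layer.coords[p][None, :] - X[idx]
            d = np.linalg.norm(diff, axis=1)
            ok = d > 1e-12
            idx, diff, d = idx[ok], diff[ok], d[ok]
            n_att[p] = idx.size
            if idx.size < model.min_attachments:
                continue
            d_vals[p] = _d_value_from_attachments(
                network, idx, diff / d[:, None], model.k_perturb
            )
    layer.d_values = d_vals
    layer.n_attachments = n_att
    if S:
        logger.info(
            "layer %d: %d points, D mean %.4g sd %.4g max %.4g",
            layer.layer_index, S, d_vals.mean(), d_vals.std(), d_vals.max(),
        )
    return layer
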