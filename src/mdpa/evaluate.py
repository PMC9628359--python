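"""Binding-site prediction from the ranked pockets, and its evaluation.

The predicted ligand-binding site R_P is the set of residues whose Cα lies
within 6 Å of any point of the evaluated pocket.  Against the annotated set
R_L this gives precision |R_P∩R_L|/|R_P|, recall |R_P∩R_L|/|R_L| and the
Matthews correlation coefficient of the residue-level confusion matrix.
The ligand's spatial extension is scored by 3.5 Å mutual overlap: O_m is the
subset of pocket points within 3.5 Å of a ligand atom (precision |O_m|/|O_M|)
and S_l the subset of ligand atoms within 3.5 Å of a pocket point (recall
|S_l|/|S_L|).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .pockets import PocketCluster
from .structures import CoarseStructure, LigandSet, ResidueKey, SiteAnnotation


@dataclass
class EvaluationReport:
    """Site and ligand-extension metrics for one evaluated pocket rank."""

    pocket_rank_evaluated: int
    no_prediction: bool = False
    # site metrics
    site_precision: float = 0.0
    site_recall: float = 0.0
    site_mcc: float = 0.0
    r_p_size: int = 0
    r_l_size: int = 0
    r_intersection_size: int = 0
    annotation_origin: str = "site_records"
    # extension metrics (None when no ligand is present)
    ext_precision: float | None = None
    ext_recall: float | None = None
    o_M_size: int = 0
    o_m_size: int = 0
    s_L_size: int = 0
    s_l_size: int = 0
    predicted_residues: list[ResidueKey] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "pocket_rank_evaluated": self.pocket_rank_evaluated,
            "no_prediction": self.no_prediction,
            "site_precision": self.site_precision,
            "site_recall": self.site_recall,
            "site_mcc": self.site_mcc,
            "r_p_size": self.r_p_size,
            "r_l_size": self.r_l_size,
            "r_intersection_size": self.r_intersection_size,
            "annotation_origin": self.annotation_origin,
            "ext_precision": self.ext_precision,
            "ext_recall": self.ext_recall,
            "o_M_size": self.o_M_size,
            "o_m_size": self.o_m_size,
            "s_L_size": self.s_L_size,
            "s_l_size": self.s_l_size,
            "predicted_residues": [list(k) for k in sorted(self.predicted_residues)],
        }
        return d


def predict_lbs(
    pocket: PocketCluster, structure: CoarseStructure, cutoff: float = 6.0
) -> set[ResidueKey]:
    """Residues whose Cα is within ``cutoff`` Å of any pocket point (R_P)."""
    if pocket.n_points == 0:
        raise ValueError("empty pocket")
    d, _ = cKDTree(pocket.coords).query(structure.coords, k=1)
    keys = structure.residue_keys()
    return {keys[i] for i in np.nonzero(d <= cutoff)[0]}


def site_metrics(
    r_p: set[ResidueKey], r_l: set[ResidueKey], n_total: int
) -> tuple[float, float, float]:
    """Precision, recall and MCC of the predicted residue set.

    Precision = |R_P∩R_L| / |R_P|, Recall = |R_P∩R_L| / |R_L| (0 on empty
    denominators); MCC from the residue-level confusion matrix over the
    ``n_total`` residues, with the 0/0 convention MCC = 0.
    """
    if n_total < len(r_p | r_l):
        raise ValueError("n_total smaller than |R_P ∪ R_L|")
    tp = len(r_p & r_l)
    fp = len(r_p - r_l)
    fn = len(r_l - r_p)
    tn = n_total - len(r_p | r_l)
    precision = tp / len(r_p) if r_p else 0.0
    recall = tp / len(r_l) if r_l else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return precision, recall, mcc


def extension_metrics(
    pocket: PocketCluster, ligand: LigandSet, contact_cutoff: float = 3.5
) -> tuple[float, float, int, int, int, int]:
    """Mutual-overlap precision/recall between pocket cloud and ligand atoms.

    Returns (precision, recall, |O_M|, |O_m|, |S_L|, |S_l|).
    """
    if len(ligand) == 0:
        raise ValueError("empty ligand: extension metrics undefined")
    if pocket.n_points == 0:
        raise ValueError("empty pocket")
    lig = ligand.coords
    d_pocket, _ = cKDTree(lig).query(pocket.coords, k=1)
    d_lig, _ = cKDTree(pocket.coords).query(lig, k=1)
    o_M = pocket.n_points
    o_m = int(np.count_nonzero(d_pocket <= contact_cutoff))
    s_L = lig.shape[0]
    s_l = int(np.count_nonzero(d_lig <= contact_cutoff))
    return o_m / o_M, s_l / s_L, o_M, o_m, s_L, s_l


def evaluate_structure(
    pockets: list[PocketCluster],
    structure: CoarseStructure,
    annotation: SiteAnnotation | None,
    ligand: LigandSet | None,
    lbs_cutoff: float = 6.0,
    contact_cutoff: float = 3.5,
    max_ranks: int | None = None,
) -> list[EvaluationReport]:
    """Per-rank evaluation reports; the rank-1 report is the headline.

    A run without pockets (e.g. a binding region buried in the protein core,
    which surface test points cannot reach) yields a single report flagged
    ``no_prediction``.
    """
    if not pockets:
        return [EvaluationReport(pocket_rank_evaluated=0, no_prediction=True)]
    reports = []
    ordered = sorted(pockets, key=lambda c: c.rank)
    if max_ranks is not None:
        ordered = ordered[:max_ranks]
    for pocket in ordered:
        rep = EvaluationReport(pocket_rank_evaluated=pocket.rank)
        r_p = predict_lbs(pocket, structure, cutoff=lbs_cutoff)
        rep.predicted_residues = sorted(r_p)
        rep.r_p_size = len(r_p)
        if annotation is not None and len(annotation):
            r_l = annotation.residues
            rep.annotation_origin = annotation.origin
            rep.r_l_size = len(r_l)
            rep.r_intersection_size = len(r_p & r_l)
            rep.site_precision, rep.site_recall, rep.site_mcc = site_metrics(
                r_p, r_l, structure.n_residues
            )
        if ligand is not None and len(ligand):
            (rep.ext_precision, rep.ext_recall,
             rep.o_M_size, rep.o_m_size, rep.s_L_size, rep.s_l_size) = extension_metrics(
                pocket, ligand, contact_cutoff=contact_cutoff
            )
        reports.append(rep)
    return reports
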