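"""Run configuration: every tunable of the pipeline in one provenance record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass
class RunConfig:
    """Pipeline parameters (lengths in Å, energies in γ·Å² model units).

    The geometric constants tie together: the 1.5 Å probe sets layer spacing
    at one probe diameter (3 Å), which is also the OPTICS reachability bound
    and the cross-layer link distance; 6 Å is the Cα contact distance that
    turns a pocket into predicted residues; 3.5 Å is the ligand-overlap
    contact distance.
    """

    chains: list[str] | None = None
    n_layers: int = 3
    probe_radius: float = 1.5
    sphere_radius_protein: float = 3.0
    sphere_radius_virtual: float = 1.5
    samples_per_sphere: int = 64
    enm_cutoff: float = 12.0
    gamma: float = 1.0
    k_perturb: float = 1.0
    attach_cutoff_rp: float = 8.0
    z_threshold: float = 1.0
    optics_min_samples: int = 5
    optics_max_eps: float = 3.0
    link_distance: float = 3.0
    lbs_cutoff: float = 6.0
    contact_cutoff: float = 3.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("probe_radius", "sphere_radius_protein", "sphere_radius_virtual",
                     "enm_cutoff", "attach_cutoff_rp", "optics_max_eps",
                     "link_distance", "lbs_cutoff", "contact_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_layers < 1:
            raise ValueError("n_layers must be ≥ 1")

    def to_dict(self) -> dict:
        return asdict(self)
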