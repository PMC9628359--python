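"""Coarse-grained structure model and PDB input/output.

The pipeline works at one site per residue (the Cα position), the resolution
at which the elastic network model is defined.  This module reads PDB files
into that coarse representation, extracts bound hetero-groups as candidate
ligands, and collects the binding-site residue annotations from SITE records
so predictions can be scored against them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]

#: Hetero-group codes never treated as candidate ligands: water and the
#: common crystallization ions/additives.  Configurable per call.
DEFAULT_EXCLUDED_HET = frozenset(
    {"HOH", "DOD", "WAT", "NA", "CL", "MG", "ZN", "CA", "K", "SO4", "PO4"}
)


@dataclass
class CoarseStructure:
    """Cα-level protein model: one site per residue, at the Cα position."""

    source_id: str
    chains: list[str]
    resnums: list[int]
    icodes: list[str]
    resnames: list[str]
    coords: np.ndarray  # (N, 3) float64, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if not (len(self.chains) == len(self.resnums) == len(self.icodes) == len(self.resnames) == n):
            raise ValueError("residue annotation lists and coordinates disagree in length")
        if n < 3:
            raise ValueError(f"coarse structure needs at least 3 residues, got {n}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite Cα coordinate")
        keys = self.residue_keys()
        if len(set(keys)) != n:
            raise ValueError("duplicate (chain, resnum, icode) residue key")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def residue_keys(self) -> list[ResidueKey]:
        return list(zip(self.chains, self.resnums, self.icodes))

    def key_index(self) -> dict[ResidueKey, int]:
        return {k: i for i, k in enumerate(self.residue_keys())}

    def with_coords(self, coords: np.ndarray, source_id: str | None = None) -> "CoarseStructure":
        """Copy of this structure with replaced Cα coordinates."""
        return CoarseStructure(
            source_id=source_id or self.source_id,
            chains=list(self.chains),
            resnums=list(self.resnums),
            icodes=list(self.icodes),
            resnames=list(self.resnames),
            coords=np.array(coords, dtype=float),
        )

    def label(self, i: int) -> str:
        ic = self.icodes[i].strip()
        return f"{self.chains[i]}/{self.resnames[i]}{self.resnums[i]}{ic}"


@dataclass
class LigandAtom:
    name: str
    element: str
    coord: np.ndarray
    parent_het: str


@dataclass
class LigandSet:
    """Heavy atoms of the bound hetero-groups (candidate ligands)."""

    atoms: list[LigandAtom] = field(default_factory=list)
    excluded_het_codes: frozenset[str] = DEFAULT_EXCLUDED_HET

    def __post_init__(self) -> None:
        for a in self.atoms:
            a.coord = np.asarray(a.coord, dtype=float).reshape(3)
            if not np.all(np.isfinite(a.coord)):
                raise ValueError(f"non-finite ligand atom coordinate in {a.parent_het}")
            if a.element.upper() == "H":
                raise ValueError("LigandSet holds heavy atoms only")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.coord for a in self.atoms])

    def group_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.parent_het, None)
        return list(seen)

    def subset(self, parent_het: str) -> "LigandSet":
        return LigandSet(
            atoms=[a for a in self.atoms if a.parent_het == parent_het],
            excluded_het_codes=self.excluded_het_codes,
        )


@dataclass
class SiteAnnotation:
    """Annotated binding-site residues (the reference set R_L)."""

    residues: set[ResidueKey] = field(default_factory=set)
    origin: str = "site_records"  # or "distance_fallback"

    def __post_init__(self) -> None:
        if self.origin not in ("site_records", "distance_fallback"):
            raise ValueError(f"unknown annotation origin {self.origin!r}")

    def __len__(self) -> int:
        return len(self.residues)


def _parse_site_records(path: Path) -> list[tuple[str, str, int, str]]:
    """Collect (resname, chain, resnum, icode) entries from PDB SITE records.

    SITE is a fixed-column record with up to four residue slots of 11 columns
    each starting at column 19 (1-based).
    """
    entries: list[tuple[str, str, int, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("SITE"):
                continue
            for start in (18, 29, 40, 51):
                fieldtxt = line[start : start + 10]
                if len(fieldtxt.strip()) == 0:
                    continue
                resname = line[start : start + 3].strip()
                chain = line[start + 4 : start + 5].strip()
                seq = line[start + 5 : start + 9].strip()
                icode = line[start + 9 : start + 10].strip()
                if not resname or not seq:
                    continue
                try:
                    resnum = int(seq)
                except ValueError:
                    logger.warning("unparseable SITE residue field %r in %s", fieldtxt, path)
                    continue
                entries.append((resname, chain, resnum, icode))
    return entries


def read_pdb_coarse(
    path: str | Path,
    chains: Iterable[str] | None = None,
    excluded_het_codes: Iterable[str] | None = None,
) -> tuple[CoarseStructure, LigandSet, SiteAnnotation]:
    """Read a PDB file into the coarse model.

    Parameters
    ----------
    path:
        PDB-format file with ATOM records (and optionally HETATM / SITE).
    chains:
        Chain ids to keep; ``None`` keeps every chain.  Multi-chain biological
        units are modelled by passing several ids — all selected chains form
        one elastic network.
    excluded_het_codes:
        Hetero-group codes to ignore as ligands (default: water and common
        ions, :data:`DEFAULT_EXCLUDED_HET`).

    Returns
    -------
    (CoarseStructure, LigandSet, SiteAnnotation)
        One Cα entry per residue (first-listed altloc kept), heavy atoms of
        the retained hetero-groups, and the SITE-record residue set restricted
        to residues present in the coarse structure.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    excluded = frozenset(
        c.upper() for c in (excluded_het_codes if excluded_het_codes is not None else DEFAULT_EXCLUDED_HET)
    )
    chain_filter = set(chains) if chains is not None else None

    # gemmi is lenient about unparseable coordinate fields; fail loudly instead
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise ValueError(
                            f"malformed coordinate field {line[lo:hi].strip()!r} "
                            f"at line {ln} of {path}"
                        ) from None

    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path} contains no models")
    model = st[0]

    chains_seen: list[str] = []
    cs_chains: list[str] = []
    cs_resnums: list[int] = []
    cs_icodes: list[str] = []
    cs_resnames: list[str] = []
    cs_coords: list[list[float]] = []
    lig_atoms: list[LigandAtom] = []
    n_altloc_dropped = 0

    for chain in model:
        chains_seen.append(chain.name)
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            het = res.het_flag == "H"
            if het:
                if res.name.upper() in excluded:
                    continue
                parent = f"{chain.name}/{res.name}{res.seqid.num}"
                for atom in res:
                    if atom.element.name.upper() == "H" or atom.element.name.upper() == "D":
                        continue
                    lig_atoms.append(
                        LigandAtom(
                            name=atom.name,
                            element=atom.element.name,
                            coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            parent_het=parent,
                        )
                    )
            else:
                ca = None
                for atom in res:
                    if atom.name == "CA":
                        if ca is None:
                            ca = atom
                        else:
                            n_altloc_dropped += 1
                if ca is None:
                    continue
                cs_chains.append(chain.name)
                cs_resnums.append(res.seqid.num)
                cs_icodes.append((res.seqid.icode or "").strip())
                cs_resnames.append(res.name)
                cs_coords.append([ca.pos.x, ca.pos.y, ca.pos.z])

    if n_altloc_dropped:
        logger.warning("%s: dropped %d alternate-location CA atoms (kept first-listed)", path, n_altloc_dropped)
    if not cs_coords:
        raise ValueError(
            f"no CA atoms found in selected chains of {path}; chains present: {sorted(set(chains_seen))}"
        )

    structure = CoarseStructure(
        source_id=path.stem,
        chains=cs_chains,
        resnums=cs_resnums,
        icodes=cs_icodes,
        resnames=cs_resnames,
        coords=np.array(cs_coords),
    )
    ligand = LigandSet(atoms=lig_atoms, excluded_het_codes=excluded)

    idx = structure.key_index()
    site_res: set[ResidueKey] = set()
    raw = _parse_site_records(path)
    for resname, chain, resnum, icode in raw:
        key = (chain, resnum, icode)
        if key in idx:
            site_res.add(key)
        elif chain_filter is None or chain in chain_filter:
            logger.warning("SITE residue %s %s%d%s not resolvable in coarse structure; dropped",
                           resname, chain, resnum, icode)
    if not raw:
        warnings.warn(f"{path.name}: no SITE records; site annotation is empty", stacklevel=2)
    annotation = SiteAnnotation(residues=site_res, origin="site_records")
    return structure, ligand, annotation


def residues_near_ligand(
    structure: CoarseStructure, ligand: LigandSet, cutoff: float = 6.0
) -> SiteAnnotation:
    """Distance fallback for the binding-site annotation.

    Residues whose Cα lies within ``cutoff`` Å of any ligand heavy atom.
    Used when the PDB entry carries no SITE records; flagged through
    ``origin="distance_fallback"``.
    """
    if len(ligand) == 0:
        raise ValueError("cannot derive a distance-fallback annotation from an empty ligand")
    from scipy.spatial import cKDTree

    tree = cKDTree(ligand.coords)
    d, _ = tree.query(structure.coords, k=1)
    keys = structure.residue_keys()
    members = {keys[i] for i in np.nonzero(d <= cutoff)[0]}
    return SiteAnnotation(residues=members, origin="distance_fallback")


def _fmt_float6(x: float) -> str:
    """Fit a non-negative value into the 6-character occupancy/B column."""
    for dec in (4, 3, 2, 1, 0):
        s = f"{x:6.{dec}f}"
        if len(s) == 6:
            return s
    return "999999"


def write_cluster_pdb(clusters: Sequence, path: str | Path) -> None:
    """Write pocket clusters as a PDB pseudo-atom point cloud.

    Each test point becomes a HETATM pseudo-atom; the occupancy column holds
    the layer index and the B-factor column the point's D-value, so standard
    viewers can colour the cloud by either.  One chain per cluster rank.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("no clusters to write")
    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
    lines = []
    serial = 1
    for ci, cl in enumerate(sorted(clusters, key=lambda c: c.rank)):
        chain = chain_ids[min(ci, len(chain_ids) - 1)]
        for coord, layer, d in zip(cl.coords, cl.layers, cl.d_values):
            x, y, z = coord
            lines.append(
                f"HETATM{serial % 100000:5d}  C   PNT {chain}{(serial - 1) % 9999 + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{float(layer):6.0f}{_fmt_float6(float(d))}"
                f"           C"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_coarse_pdb(
    structure: CoarseStructure,
    path: str | Path,
    ligand: LigandSet | None = None,
    site: SiteAnnotation | None = None,
) -> None:
    """Write a coarse structure (and optional ligand / SITE records) as PDB."""
    lines = []
    if site is not None and len(site):
        keyset = sorted(site.residues)
        idx = structure.key_index()
        per_rec = 4
        recs = [keyset[i : i + per_rec] for i in range(0, len(keyset), per_rec)]
        for ri, rec in enumerate(recs, start=1):
            body = ""
            for key in rec:
                i = idx.get(key)
                resname = structure.resnames[i] if i is not None else "UNK"
                ch, num, ic = key
                body += f"{resname:>3s} {ch:1s}{num:4d}{(ic or ' '):1s} "
            lines.append(f"SITE   {ri:3d} AC1 {len(keyset):2d} {body}".rstrip())
    serial = 1
    for i in range(structure.n_residues):
        x, y, z = structure.coords[i]
        lines.append(
            f"ATOM  {serial:5d}  CA  {structure.resnames[i]:>3s} {structure.chains[i]:1s}"
            f"{structure.resnums[i]:4d}{(structure.icodes[i] or ' '):1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C"
        )
        serial += 1
    if ligand is not None:
        lig_seq = 900
        last_parent = None
        for a in ligand.atoms:
            if a.parent_het != last_parent:
                lig_seq += 1
                last_parent = a.parent_het
            x, y, z = a.coord
            lines.append(
                f"HETATM{serial:5d} {a.name:>4s} LIG L{lig_seq % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"           {a.element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
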