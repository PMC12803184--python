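"""Structural context of acetyl sites: pLDDT and solvent accessibility.

Predicted-structure PDB files are parsed with a fixed-column reader
(PDB v3.3 ATOM records); per-residue model confidence (pLDDT, 0-100) is
read from the B-factor field, as AlphaFold writes it.  Solvent-accessible
surface area is computed with the Shrake-Rupley point-sampling algorithm:
a deterministic golden-section spiral of points on each atom's
probe-expanded sphere, a point counting as accessible when it lies
strictly outside every neighboring atom's expanded sphere.  Residue SASA
is the sum over member atoms.  Structural context is then joined to
acetyl sites by residue index (predicted models number residues by
sequence position).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import PipelineConfig
from .ingest import SiteRecord

logger = logging.getLogger(__name__)

# Bondi-style van der Waals radii, Angstrom
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}
DEFAULT_VDW = 1.70

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class PDBParseError(ValueError):
    """Malformed fixed-column ATOM record."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_index: int            # 1-based
    residue_name: str
    coords: tuple[float, float, float]
    b_factor: float
    is_hetero: bool = False

    @property
    def vdw_radius(self) -> float:
        return VDW_RADII.get(self.element, DEFAULT_VDW)


@dataclass
class ResidueStructure:
    protein_id: str
    residue_index: int
    amino_acid: str               # one-letter code
    plddt: float                  # 0-100 model confidence
    sasa: float                   # Angstrom^2


def _infer_element(name_field: str, element_field: str) -> str:
    element = element_field.strip()
    if element:
        return element.capitalize()
    # fall back to the atom-name convention: first letter, skipping digits
    stripped = name_field.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def parse_pdb(path: str | Path, include_hetero: bool = True) -> list[AtomRecord]:
    """Read fixed-column ATOM (and optionally HETATM) records.

    Only the first MODEL of a multi-model file is read, with a warning.
    Malformed coordinate/B-factor fields raise with the offending line
    number.
    """
    atoms: list[AtomRecord] = []
    in_first_model = True
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tag = line[:6]
            if tag.startswith("MODEL"):
                if saw_model:
                    warnings.warn(
                        f"{path}: multi-model file; using the first model"
                    )
                    break
                saw_model = True
                continue
            if tag.startswith("ENDMDL"):
                in_first_model = False
                continue
            if not in_first_model:
                continue
            is_hetero = tag == "HETATM"
            if tag != "ATOM  " and not is_hetero:
                continue
            if is_hetero and not include_hetero:
                continue
            try:
                atoms.append(
                    AtomRecord(
                        serial=int(line[6:11]),
                        name=line[12:16].strip(),
                        element=_infer_element(line[12:16], line[76:78]),
                        residue_index=int(line[22:26]),
                        residue_name=line[17:20].strip(),
                        coords=(
                            float(line[30:38]),
                            float(line[38:46]),
                            float(line[46:54]),
                        ),
                        b_factor=float(line[60:66]),
                        is_hetero=is_hetero,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise PDBParseError(
                    f"{path}: malformed ATOM record at line {lineno}: {exc}"
                ) from exc
    if not any(not a.is_hetero for a in atoms):
        warnings.warn(f"{path}: no ATOM records found")
    return atoms


def plddt_per_residue(atoms: list[AtomRecord]) -> dict[int, float]:
    """Per-residue pLDDT from B-factors (ATOM records only).

    Predicted models carry one pLDDT per residue replicated on each atom;
    if atoms of a residue disagree, their mean is used with a warning.
    """
    by_res: dict[int, list[float]] = {}
    for atom in atoms:
        if not atom.is_hetero:
            by_res.setdefault(atom.residue_index, []).append(atom.b_factor)
    out: dict[int, float] = {}
    disagree = 0
    for res, values in by_res.items():
        if max(values) - min(values) > 1e-9:
            disagree += 1
        out[res] = float(np.mean(values))
    if disagree:
        warnings.warn(
            f"{disagree} residue(s) had unequal atom B-factors; using the mean"
        )
    return out


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points via the golden-section spiral."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


def shrake_rupley(
    atoms: list[AtomRecord],
    probe: float = 1.4,
    n_points: int = 100,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Angstrom^2.

    For each atom, ``n_points`` spiral points are placed on its sphere of
    radius r_i + probe; a point is accessible iff it lies strictly outside
    every other atom's expanded sphere (a point exactly on a neighbor's
    sphere counts as accessible, for determinism with coincident atoms).
    SASA_i = 4*pi*(r_i+probe)^2 * accessible fraction.  Neighbor search is
    restricted to atoms within r_i + r_j + 2*probe.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    n = len(atoms)
    if n == 0:
        return np.zeros(0)
    coords = np.array([a.coords for a in atoms], dtype=float)
    radii = np.array([a.vdw_radius for a in atoms], dtype=float)
    expanded = radii + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = expanded.max()
    sasa = np.zeros(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        # any atom that can occlude lies within expanded_i + expanded_j of i
        neighbors = tree.query_ball_point(coords[i], expanded[i] + max_reach)
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d2 = np.einsum(
                "ij,ij->i", pts - coords[j], pts - coords[j]
            )
            accessible &= d2 >= expanded[j] ** 2   # boundary counts accessible
        sasa[i] = 4.0 * math.pi * expanded[i] ** 2 * accessible.mean()
    return sasa


def residue_sasa(
    atoms: list[AtomRecord], atom_sasa: np.ndarray
) -> dict[int, float]:
    """Sum member-atom SASA per residue (ATOM records only)."""
    out: dict[int, float] = {}
    for atom, s in zip(atoms, atom_sasa):
        if not atom.is_hetero:
            out[atom.residue_index] = out.get(atom.residue_index, 0.0) + float(s)
    return out


def residue_structure_table(
    protein_id: str,
    atoms: list[AtomRecord],
    cfg: PipelineConfig | None = None,
) -> list[ResidueStructure]:
    """pLDDT + SASA per residue for one parsed structure."""
    cfg = cfg or PipelineConfig()
    kept = [
        a for a in atoms
        if (not a.is_hetero or cfg.sasa_include_hetero)
        and (a.element != "H" or cfg.sasa_include_hydrogens)
    ]
    sasa = shrake_rupley(kept, cfg.sasa_probe_radius, cfg.sasa_n_points)
    per_res_sasa = residue_sasa(kept, sasa)
    plddt = plddt_per_residue(atoms)
    names = {
        a.residue_index: THREE_TO_ONE.get(a.residue_name, "X")
        for a in atoms if not a.is_hetero
    }
    return [
        ResidueStructure(
            protein_id=protein_id,
            residue_index=res,
            amino_acid=names[res],
            plddt=plddt[res],
            sasa=per_res_sasa.get(res, 0.0),
        )
        for res in sorted(names)
    ]


def filter_sites_by_term(
    sites: list[SiteRecord],
    closed_annotations: dict[str, set[str]],
    term: str,
) -> list[SiteRecord]:
    """Sites on proteins annotated (after closure) to a compartment term.

    A protein annotated to several compartments contributes its sites to
    each of them.
    """
    return [
        s for s in sites if term in closed_annotations.get(s.protein_id, set())
    ]


def join_site_structure(
    sites: list[SiteRecord],
    structures: dict[str, list[ResidueStructure]],
) -> pd.DataFrame:
    """Attach pLDDT and SASA to each acetyl site by residue index.

    Sites whose protein has no structure are dropped (logged); sites whose
    structural residue is not lysine are flagged ``mismatch`` and excluded
    from downstream distributions.
    """
    rows = []
    n_missing = 0
    for site in sites:
        residues = structures.get(site.protein_id)
        if residues is None:
            n_missing += 1
            continue
        by_index = {r.residue_index: r for r in residues}
        res = by_index.get(site.position)
        if res is None:
            n_missing += 1
            continue
        rows.append(
            {
                "collapse_key": site.collapse_key,
                "protein_id": site.protein_id,
                "position": site.position,
                "amino_acid": res.amino_acid,
                "plddt": res.plddt,
                "sasa": res.sasa,
                "mismatch": res.amino_acid != "K",
            }
        )
    if n_missing:
        logger.info("join_site_structure: %d site(s) without structure", n_missing)
    return pd.DataFrame(
        rows,
        columns=[
            "collapse_key", "protein_id", "position",
            "amino_acid", "plddt", "sasa", "mismatch",
        ],
    )
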