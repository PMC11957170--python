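"""Structural disease-density covariate from residue coordinates.

Each residue of the protein gets a "disease density": the evidence-weighted
fraction of affected heterozygotes among all heterozygotes carried by
variants whose residues lie within a 3D neighborhood (Calpha-Calpha
distance) of it.  High density marks regions of the structure enriched for
penetrant variants.  The density at a variant's own residue can be computed
leaving that variant out, so it can serve as a covariate for the variant
without self-leakage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as _cif_structure

from .variant_data import VariantTable

__all__ = [
    "ResidueCoordinates",
    "DensityProfile",
    "read_structure",
    "compute_density",
    "density_covariate",
    "export_structure_colors",
    "write_ca_pdb",
]


@dataclass(frozen=True)
class ResidueCoordinates:
    """One resolved residue: position (1-based), chain and Calpha position (Å)."""

    position: int
    chain_id: str
    ca_xyz: tuple[float, float, float]


@dataclass
class DensityProfile:
    """Per-residue density values; ``None`` marks an undefined residue.

    ``coverage`` lists, per variant key, whether its residue was resolved in
    the structure (unresolved variants contribute nothing to the sums).
    """

    values: dict[int, Optional[float]]
    coverage: dict[tuple[int, str, str], bool]

    def __getitem__(self, position: int) -> Optional[float]:
        return self.values[position]


def _load_atoms(path) -> struc.AtomArray:
    p = Path(path)
    if p.suffix.lower() in (".cif", ".mmcif", ".pdbx"):
        cif = CIFFile.read(str(p))
        atoms = _cif_structure(cif, model=1, altloc="occupancy",
                               extra_fields=["b_factor", "occupancy"])
    else:
        pdb = PDBFile.read(str(p))
        atoms = pdb.get_structure(model=1, altloc="occupancy",
                                  extra_fields=["b_factor", "occupancy"])
    return atoms


def read_structure(path, chain: str = "A") -> list[ResidueCoordinates]:
    """Read Calpha coordinates of one chain from a PDB/mmCIF file.

    Alternate locations are resolved to the highest-occupancy conformer.
    """
    atoms = _load_atoms(path)
    chains = sorted(set(atoms.chain_id))
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} not present in {path}; available chains: "
            f"{chains}")
    ca = atoms[(atoms.chain_id == chain) & (atoms.atom_name == "CA")
               & struc.filter_amino_acids(atoms)]
    if ca.array_length() == 0:
        raise ValueError(f"no Calpha atoms found for chain {chain!r} in {path}")
    out = []
    seen = set()
    for i in range(ca.array_length()):
        pos = int(ca.res_id[i])
        if pos in seen:  # duplicate CA (should not survive altloc filtering)
            continue
        seen.add(pos)
        out.append(ResidueCoordinates(pos, chain, tuple(float(x)
                                                        for x in ca.coord[i])))
    return out


def _kernel_weights(dists: np.ndarray, radius: float, kernel: str,
                    length_scale: Optional[float]) -> np.ndarray:
    if kernel == "uniform":
        return (dists <= radius).astype(float)
    if kernel == "exponential":
        ls = length_scale if length_scale is not None else radius / 3.0
        return np.exp(-dists / ls)
    raise ValueError(f"unknown kernel {kernel!r}")


def compute_density(residues: Sequence[ResidueCoordinates],
                    variants: VariantTable,
                    radius: float = 15.0,
                    leave_out: Optional[tuple[int, str, str]] = None,
                    kernel: str = "uniform",
                    length_scale: Optional[float] = None) -> DensityProfile:
    """Disease density at every resolved residue.

    density(r) = sum_v w_v * affected_v * k(d(r, res(v)))
               / sum_v w_v * total_v    * k(d(r, res(v)))

    with k the uniform cutoff at ``radius`` (default) or an exponential
    decay, d the Calpha-Calpha Euclidean distance, and the residue's own
    variants included.  A residue whose neighborhood carries no heterozygote
    mass has undefined (``None``) density.  ``leave_out`` removes one
    variant from both sums (used when the value serves as that variant's own
    covariate).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    res_pos = np.array([r.position for r in residues])
    res_xyz = np.array([r.ca_xyz for r in residues], dtype=float)
    pos_index = {p: i for i, p in enumerate(res_pos)}

    coverage: dict[tuple[int, str, str], bool] = {}
    v_idx, v_num, v_den = [], [], []
    for rec in variants:
        resolved = rec.position in pos_index
        coverage[rec.key] = resolved
        if not resolved or rec.key == leave_out:
            continue
        w = rec.weight if rec.weight is not None else 1.0
        v_idx.append(pos_index[rec.position])
        v_num.append(w * rec.counts.affected)
        v_den.append(w * rec.counts.total)

    values: dict[int, Optional[float]] = {}
    if not v_idx:
        values = {int(p): None for p in res_pos}
        return DensityProfile(values, coverage)

    var_xyz = res_xyz[np.array(v_idx)]
    k = _kernel_weights(cdist(res_xyz, var_xyz), radius, kernel, length_scale)
    num = k @ np.array(v_num)
    den = k @ np.array(v_den)
    for i, p in enumerate(res_pos):
        values[int(p)] = float(num[i] / den[i]) if den[i] > 0 else None
    return DensityProfile(values, coverage)


def density_covariate(residues: Sequence[ResidueCoordinates],
                      variants: VariantTable,
                      radius: float = 15.0,
                      leave_one_out: bool = True,
                      kernel: str = "uniform",
                      length_scale: Optional[float] = None
                      ) -> dict[tuple[int, str, str], Optional[float]]:
    """Per-variant density covariate (value at the variant's own residue).

    With ``leave_one_out`` (default) each variant's own counts are removed
    from the sums at its residue, avoiding self-leakage when the density is
    regressed against that variant's outcome.  Computed incrementally from
    the all-variant sums, so cost stays linear in the number of variants.
    """
    profile = compute_density(residues, variants, radius=radius,
                              kernel=kernel, length_scale=length_scale)
    res_pos = np.array([r.position for r in residues])
    res_xyz = np.array([r.ca_xyz for r in residues], dtype=float)
    pos_index = {int(p): i for i, p in enumerate(res_pos)}

    # re-derive raw sums at variant-bearing residues to allow own-term removal
    v_keys, v_idx, v_num, v_den = [], [], [], []
    for rec in variants:
        if rec.position not in pos_index:
            continue
        w = rec.weight if rec.weight is not None else 1.0
        v_keys.append(rec.key)
        v_idx.append(pos_index[rec.position])
        v_num.append(w * rec.counts.affected)
        v_den.append(w * rec.counts.total)

    out: dict[tuple[int, str, str], Optional[float]] = {}
    if not v_keys:
        return {rec.key: None for rec in variants}
    var_xyz = res_xyz[np.array(v_idx)]
    k = _kernel_weights(cdist(var_xyz, var_xyz), radius, kernel, length_scale)
    num = k @ np.array(v_num)
    den = k @ np.array(v_den)
    for j, key in enumerate(v_keys):
        n, d = num[j], den[j]
        if leave_one_out:
            n -= k[j, j] * v_num[j]
            d -= k[j, j] * v_den[j]
        out[key] = float(n / d) if d > 0 else None
    for rec in variants:
        out.setdefault(rec.key, None)
    return out


def export_structure_colors(values: Mapping[int, float], structure_path,
                            out_path, chain: Optional[str] = None) -> None:
    """Write a PDB copy with per-residue values in the B-factor column.

    Residues absent from ``values`` (or mapped to ``None``) receive the
    sentinel B-factor -1.0 so external renderers can mask them.
    """
    atoms = _load_atoms(structure_path)
    b = np.full(atoms.array_length(), -1.0)
    for i in range(atoms.array_length()):
        if chain is not None and atoms.chain_id[i] != chain:
            continue
        v = values.get(int(atoms.res_id[i]))
        if v is not None:
            b[i] = v
    atoms.set_annotation("b_factor", b)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(out_path))


_AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def write_ca_pdb(residues: Sequence[ResidueCoordinates], path,
                 res_names: Optional[Sequence[str]] = None) -> None:
    """Write a Calpha-only PDB for a residue chain (e.g. a toy structure)."""
    n = len(residues)
    atoms = struc.AtomArray(n)
    for i, r in enumerate(residues):
        atoms.coord[i] = r.ca_xyz
        atoms.chain_id[i] = r.chain_id
        atoms.res_id[i] = r.position
        atoms.res_name[i] = (_AA1_TO_3.get(res_names[i], "ALA")
                             if res_names is not None else "ALA")
        atoms.atom_name[i] = "CA"
        atoms.element[i] = "C"
    atoms.set_annotation("b_factor", np.zeros(n))
    atoms.set_annotation("occupancy", np.ones(n))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))
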