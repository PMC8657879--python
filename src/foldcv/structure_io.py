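"""PDB parsing, backbone extraction and backbone dihedral angles.

A protein backbone is reduced to the ordered N, CA, C atom triplets of each
residue.  Dihedrals follow the IUPAC sign convention and are reported in
degrees on (-180, 180]:

* ``psi_k``   from (N_k, CA_k, C_k, N_{k+1})
* ``omega_k`` from (CA_k, C_k, N_{k+1}, CA_{k+1})
* ``phi_k``   from (C_{k-1}, N_k, CA_k, C_k)

Angles across a chain break (C-N distance above ~2.5 A) or involving an
incomplete residue are undefined and stored as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from foldcv.constants import CHAIN_BREAK_CN
from foldcv.errors import StructureError

__all__ = [
    "Residue",
    "BackboneChain",
    "DihedralRecord",
    "parse_structure",
    "parse_trajectory",
    "compute_dihedrals",
    "dihedral_angle",
    "write_dihedral_tsv",
]


@dataclass
class Residue:
    """One residue's backbone: residue number, name and N/CA/C coordinates."""

    resnum: int
    resname: str
    n: np.ndarray | None
    ca: np.ndarray | None
    c: np.ndarray | None
    icode: str = " "

    @property
    def complete(self) -> bool:
        return self.n is not None and self.ca is not None and self.c is not None


@dataclass
class BackboneChain:
    """Ordered backbone residues of one chain."""

    chain_id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)


@dataclass
class DihedralRecord:
    """Backbone dihedrals of residue ``index`` (1-based within its chain).

    ``omega_prev`` is the peptide-bond torsion preceding the residue
    (omega_{k-1}), ``omega_next`` the one following it (omega_k).  Undefined
    angles are NaN.
    """

    index: int
    resnum: int
    resname: str
    phi: float = math.nan
    psi: float = math.nan
    omega_prev: float = math.nan
    omega_next: float = math.nan


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees on (-180, 180], IUPAC sign."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def _pick_atom(residue, name: str) -> np.ndarray | None:
    """Select an atom, resolving altlocs to highest occupancy (ties: 'A')."""
    if not residue.has_id(name):
        return None
    atom = residue[name]
    if atom.is_disordered():
        alts = atom.disordered_get_list()
        alts = sorted(
            alts,
            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
        )
        atom = alts[0]
    return np.asarray(atom.get_coord(), dtype=float)


def _chains_from_model(model) -> list[BackboneChain]:
    chains: list[BackboneChain] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag != " ":  # skip HETATM / waters
                continue
            residues.append(
                Residue(
                    resnum=resseq,
                    resname=res.get_resname(),
                    n=_pick_atom(res, "N"),
                    ca=_pick_atom(res, "CA"),
                    c=_pick_atom(res, "C"),
                    icode=icode,
                )
            )
        residues.sort(key=lambda r: (r.resnum, r.icode))
        if residues:
            chains.append(BackboneChain(chain_id=chain.id, residues=residues))
    return chains


def parse_structure(path, model_index: int = 1) -> list[BackboneChain]:
    """Parse one model of a PDB file into backbone chains.

    Parameters
    ----------
    path : str or Path
        PDB-format file.
    model_index : int
        1-based model number (order of appearance in the file).

    Returns
    -------
    list of BackboneChain
        One entry per chain containing at least one ATOM-record residue.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    if model_index < 1:
        raise StructureError("model_index is 1-based and must be >= 1")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if model_index > len(models):
        raise StructureError(
            f"model_index {model_index} beyond model count {len(models)}"
        )
    chains = _chains_from_model(models[model_index - 1])
    if not chains:
        raise StructureError(f"no protein chains found in {path}")
    return chains


def parse_trajectory(path) -> list[list[BackboneChain]]:
    """Parse every model of a (multi-model) PDB file, in file order."""
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    frames = [_chains_from_model(m) for m in structure]
    frames = [f for f in frames if f]
    if not frames:
        raise StructureError(f"no protein chains found in {path}")
    return frames


def contiguous_stretches(chain: BackboneChain) -> list[list[int]]:
    """Indices of residues grouped into covalently contiguous stretches.

    A residue extends the current stretch when both it and its predecessor
    are complete and the C(prev)-N(this) distance does not exceed the
    chain-break cutoff.  Incomplete residues form singleton stretches.
    """
    stretches: list[list[int]] = []
    current: list[int] = []
    for i, res in enumerate(chain.residues):
        if current:
            prev = chain.residues[current[-1]]
            linked = (
                prev.complete
                and res.complete
                and float(np.linalg.norm(res.n - prev.c)) <= CHAIN_BREAK_CN
            )
            if linked:
                current.append(i)
                continue
            stretches.append(current)
        current = [i]
    if current:
        stretches.append(current)
    return stretches


def compute_dihedrals(chain: BackboneChain) -> list[DihedralRecord]:
    """Backbone dihedrals for every residue of a chain.

    Returns one record per residue (NaN for undefined angles).  Dihedrals are
    never computed across a chain break.
    """
    if len(chain) < 2:
        raise StructureError("chain has fewer than 2 residues")
    if not any(r.complete for r in chain.residues):
        raise StructureError("no residue has a complete N/CA/C backbone")
    records = [
        DihedralRecord(index=i + 1, resnum=r.resnum, resname=r.resname)
        for i, r in enumerate(chain.residues)
    ]
    for stretch in contiguous_stretches(chain):
        res = [chain.residues[i] for i in stretch]
        for j in range(len(res) - 1):
            a, b = res[j], res[j + 1]
            psi = dihedral_angle(a.n, a.ca, a.c, b.n)
            omega = dihedral_angle(a.ca, a.c, b.n, b.ca)
            phi = dihedral_angle(a.c, b.n, b.ca, b.c)
            records[stretch[j]].psi = psi
            records[stretch[j]].omega_next = omega
            records[stretch[j + 1]].omega_prev = omega
            records[stretch[j + 1]].phi = phi
    return records


def dihedral_table(chains: Iterable[BackboneChain]) -> pd.DataFrame:
    """Tidy per-residue dihedral table over one or more chains."""
    rows = []
    for chain in chains:
        for rec in compute_dihedrals(chain):
            rows.append(
                {
                    "chain": chain.chain_id,
                    "resnum": rec.resnum,
                    "resname": rec.resname,
                    "phi": rec.phi,
                    "psi": rec.psi,
                    "omega_prev": rec.omega_prev,
                    "omega_next": rec.omega_next,
                }
            )
    return pd.DataFrame(rows)


def write_dihedral_tsv(chains: Sequence[BackboneChain], path) -> None:
    """Write the dihedral table as TSV, with "NA" for undefined angles."""
    dihedral_table(chains).to_csv(path, sep="\t", index=False, na_rep="NA")
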