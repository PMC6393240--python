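"""Synthetic Bio.PDB structures for accessibility and restraint tests.

All structures here are built from idealised internal coordinates or plain
point clouds; they stand in for experimental coordinate files and are
labelled synthetic throughout.
"""

from __future__ import annotations

import numpy as np
from Bio.PDB.Atom import Atom
from Bio.PDB.Chain import Chain
from Bio.PDB.Model import Model
from Bio.PDB.Residue import Residue
from Bio.PDB.Structure import Structure

# idealised backbone geometry (lengths in A, angles in degrees)
_B = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.521}
_A = {"C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2, "CA-C-O": 120.8,
      "N-CA-CB": 110.4}


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates."""
    ang, tor = np.deg2rad(angle), np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang),
         bond * np.sin(ang) * np.cos(tor),
         bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def extended_peptide_atoms(sequence: list[str]) -> list[tuple[str, str, int, np.ndarray]]:
    """Backbone (+CB) atoms of a fully extended (phi = psi = 180) peptide.

    Returns (atom_name, residue_name, residue_number, coord) tuples.
    """
    atoms = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(_A["N-CA-C"])
    c = ca + _B["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i, resname in enumerate(sequence, start=1):
        atoms.append(("N", resname, i, n))
        atoms.append(("CA", resname, i, ca))
        atoms.append(("C", resname, i, c))
        if resname != "GLY":
            cb = nerf(c, n, ca, _B["CA-CB"], _A["N-CA-CB"], 123.0)
            atoms.append(("CB", resname, i, cb))
        if i < len(sequence):
            n_next = nerf(n, ca, c, _B["C-N"], _A["CA-C-N"], 180.0)  # psi
            o = nerf(n, ca, c, _B["C-O"], _A["CA-C-O"], 0.0)
            atoms.append(("O", resname, i, o))
            ca_next = nerf(ca, c, n_next, _B["N-CA"], _A["C-N-CA"], 180.0)  # omega
            c_next = nerf(c, n_next, ca_next, _B["CA-C"], _A["N-CA-C"], 180.0)  # phi
            n, ca, c = n_next, ca_next, c_next
        else:
            o = nerf(n, ca, c, _B["C-O"], _A["CA-C-O"], 0.0)
            atoms.append(("O", resname, i, o))
            oxt = nerf(n, ca, c, _B["C-O"], _A["CA-C-O"], 180.0)
            atoms.append(("OXT", resname, i, oxt))
    return atoms


def build_structure(atom_records, chain_id: str = "A") -> Structure:
    """Assemble a Bio.PDB Structure from (name, resname, resnum, xyz) records."""
    structure = Structure("synthetic")
    model = Model(0)
    structure.add(model)
    chains: dict[str, Chain] = {}
    residues: dict[tuple[str, int], Residue] = {}
    serial = 1
    for rec in atom_records:
        if len(rec) == 4:
            name, resname, resnum, xyz = rec
            cid = chain_id
        else:
            name, resname, resnum, xyz, cid = rec
        if cid not in chains:
            chains[cid] = Chain(cid)
            model.add(chains[cid])
        key = (cid, resnum)
        if key not in residues:
            residues[key] = Residue((" ", resnum, " "), resname, "")
            chains[cid].add(residues[key])
        element = name[0] if name[0] != "O" or name == "O" or name == "OXT" else "O"
        element = {"N": "N", "C": "C", "O": "O", "S": "S"}[name[0]]
        atom = Atom(name, np.asarray(xyz, dtype=float), 0.0, 1.0, " ", name, serial,
                    element=element)
        residues[key].add(atom)
        serial += 1
    return structure


def extended_gxg(x_resname: str = "ALA") -> Structure:
    """Fully extended Gly-X-Gly tripeptide (the normalisation anchor)."""
    return build_structure(extended_peptide_atoms(["GLY", x_resname, "GLY"]))


def ca_sphere_cluster(n_shell: int = 60, radius: float = 5.0) -> Structure:
    """A central ALA CA atom enclosed by a shell of GLY CA atoms.

    The central residue (number 1) is almost fully occluded.
    """
    records = [("CA", "ALA", 1, np.zeros(3))]
    # Fibonacci sphere shell
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i in range(n_shell):
        z = 1 - 2 * (i + 0.5) / n_shell
        r = np.sqrt(1 - z * z)
        th = golden * i
        xyz = radius * np.array([r * np.cos(th), r * np.sin(th), z])
        records.append(("CA", "GLY", i + 2, xyz))
    return build_structure(records)


def ca_grid_structure(positions: dict[int, np.ndarray],
                      resname: str = "GLY", chain_id: str = "A") -> Structure:
    """One CA pseudo-atom per residue at the given coordinates: a minimal
    synthetic structure where every residue is fully accessible and
    inter-residue distances are exactly the CA-CA distances."""
    records = [("CA", resname, num, xyz, chain_id) for num, xyz in positions.items()]
    return build_structure(records)
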