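"""Read and write single-chain backbone PDB files (ATOM records only).

Backed by biotite's PDB parser/writer; restricted to the backbone atoms
N, CA, C, O (CB optional) of one chain, with monotonically increasing
serial and residue numbers.
"""

from __future__ import annotations

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

from .geometry import BackboneChain, GeometryError

_BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")


class PDBError(IOError):
    """Unreadable or structurally unusable PDB input."""


def write_backbone_pdb(chain: BackboneChain, path, res_name: str = "ALA") -> None:
    """Write a chain as standard 80-column ATOM records, chain ID ``A``."""
    names = chain.atom_names
    n_res = chain.n_residues
    n_atoms = n_res * len(names)
    arr = AtomArray(n_atoms)
    arr.coord = chain.all_coords()
    arr.chain_id = np.full(n_atoms, "A")
    arr.res_id = chain.atom_residue_index() + 1
    arr.res_name = np.full(n_atoms, "GLY" if res_name == "GLY" else res_name)
    arr.atom_name = np.tile(np.array(names), n_res)
    arr.element = np.array([nm[0] for nm in arr.atom_name])
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_backbone_pdb(path) -> tuple[BackboneChain, str]:
    """Read backbone atoms of the first chain; returns (chain, sequence).

    The sequence is one-letter (X for non-standard residues).  Residues
    missing any of N, CA, C are rejected; a missing O is tolerated on the
    final residue only.
    """
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # pragma: no cover - biotite error classes vary
        raise PDBError(f"cannot parse PDB file {path}: {exc}") from exc
    arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise PDBError(f"{path}: no ATOM records")
    first_chain = arr.chain_id[0]
    arr = arr[arr.chain_id == first_chain]
    res_ids = np.unique(arr.res_id)
    res_ids.sort()
    n_res = len(res_ids)
    coords = {nm: np.full((n_res, 3), np.nan) for nm in _BACKBONE_ATOMS}
    seq = []
    for k, rid in enumerate(res_ids):
        sub = arr[arr.res_id == rid]
        seq.append(_three_to_one(sub.res_name[0]))
        for nm in _BACKBONE_ATOMS:
            hit = sub[sub.atom_name == nm]
            if hit.array_length() > 0:
                coords[nm][k] = hit.coord[0]
    for nm in ("N", "CA", "C"):
        if np.any(~np.isfinite(coords[nm])):
            raise PDBError(f"{path}: missing backbone atom {nm}")
    cb = coords["CB"] if np.all(np.isfinite(coords["CB"])) else None
    if np.any(~np.isfinite(coords["O"][:-1])):
        raise PDBError(f"{path}: missing carbonyl O atoms")
    if np.any(~np.isfinite(coords["O"][-1])):
        # rebuild an ideal terminal carbonyl O so downstream geometry works
        from .geometry import ANGLE_CA_C_O, BOND_C_O, place_atom
        coords["O"][-1] = place_atom(coords["N"][-1], coords["CA"][-1],
                                     coords["C"][-1], BOND_C_O, ANGLE_CA_C_O, 135.0)
    chain = BackboneChain(n=coords["N"], ca=coords["CA"], c=coords["C"],
                          o=coords["O"], cb=cb)
    return chain, "".join(seq)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _three_to_one(name: str) -> str:
    return _THREE_TO_ONE.get(name, "X")
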