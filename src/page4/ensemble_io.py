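"""Reading and writing Cα ensembles: multi-model XYZ and PDB.

The XYZ flavor is the plain multi-frame convention (atom count line,
comment line, then ``CA x y z`` records, one block per conformer). PDB
files are Cα-only multi-MODEL files handled through biotite.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .ensemble_metrics import Ensemble, EnsembleError

__all__ = ["write_xyz", "read_xyz", "write_pdb", "read_pdb"]


def write_xyz(ensemble: Ensemble, path, comment: str = "model") -> None:
    L = ensemble.chain_length
    with open(path, "w") as fh:
        for m, conf in enumerate(ensemble.coords, start=1):
            fh.write(f"{L}\n{comment} {m}\n")
            for x, y, z in conf:
                fh.write(f"CA {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> Ensemble:
    frames = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise EnsembleError(f"bad atom-count line {i + 1}") from exc
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise EnsembleError("truncated XYZ frame")
        xyz = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(xyz)
        i += 2 + n
    if not frames:
        raise EnsembleError("no frames in XYZ file")
    return Ensemble(coords=np.stack(frames))


def _to_atom_stack(ensemble: Ensemble) -> struc.AtomArrayStack:
    n, L = ensemble.n_conformers, ensemble.chain_length
    stack = struc.AtomArrayStack(n, L)
    stack.coord = ensemble.coords.astype(np.float32)
    stack.chain_id = np.full(L, "A")
    stack.res_id = np.arange(1, L + 1)
    stack.res_name = np.full(L, "GLY")
    stack.atom_name = np.full(L, "CA")
    stack.element = np.full(L, "C")
    stack.hetero = np.full(L, False)
    return stack


def write_pdb(ensemble: Ensemble, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(_to_atom_stack(ensemble))
    pdb.write(path)


def read_pdb(path) -> Ensemble:
    pdb = PDBFile.read(path)
    stack = pdb.get_structure(model=None)
    ca = stack[:, stack.atom_name == "CA"]
    return Ensemble(coords=np.asarray(ca.coord, dtype=float))
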