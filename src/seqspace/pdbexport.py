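"""Export factor scores as a PDB file for molecular-graphics viewers.

Each sequence becomes one pseudo-CA HETATM whose x/y/z are its scores on
three chosen components, scaled into the fixed-width PDB coordinate field;
cluster labels are encoded as chain identifiers so viewers can color by
cluster.  The scale factor is recorded in a REMARK for reversibility.
"""

from __future__ import annotations

import string

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

_CHAINS = string.ascii_uppercase + string.digits


def choose_scale(coords: np.ndarray) -> float:
    """Power of ten putting the largest |coordinate| in [10, 100)."""
    peak = np.abs(coords).max()
    if peak == 0:
        return 1.0
    return float(10.0 ** (1 - np.floor(np.log10(peak))))


def export_pdb(
    scores: np.ndarray,
    path,
    components: tuple[int, int, int] = (0, 1, 2),
    cluster_labels: np.ndarray | None = None,
    scale: float | None = None,
) -> float:
    """Write one HETATM per sequence at its scaled component coordinates.

    Returns the scale factor used (chosen automatically unless given).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 3:
        raise ValueError("need at least 3 retained components to export")
    n = scores.shape[0]
    if n > 99999:
        raise ValueError("PDB serial field cannot hold more than 99999 points")
    coords = scores[:, list(components)]
    if scale is None:
        scale = choose_scale(coords)
    xyz = coords * scale
    if np.abs(xyz).max() >= 10000:
        raise ValueError("scaled coordinates overflow the 8.3 PDB field")

    if cluster_labels is None:
        chains = np.full(n, "A")
    else:
        labels = np.asarray(cluster_labels)
        uniq = list(dict.fromkeys(labels.tolist()))
        if len(uniq) > len(_CHAINS):
            raise ValueError("more clusters than available chain identifiers")
        lut = {lab: _CHAINS[i] for i, lab in enumerate(uniq)}
        chains = np.array([lut[lab] for lab in labels])

    atoms = struc.AtomArray(n)
    atoms.coord = xyz
    atoms.atom_name[:] = "CA"
    atoms.res_name[:] = "GLY"
    atoms.element[:] = "C"
    atoms.hetero[:] = True
    atoms.chain_id = chains
    atoms.res_id = np.arange(1, n + 1)

    pdbf = PDBFile()
    pdbf.set_structure(atoms)
    pdbf.lines = [f"REMARK 250 SEQSPACE COORDINATE SCALE {scale:g}"] + pdbf.lines
    pdbf.write(str(path))
    return scale


def read_pdb_coordinates(path) -> np.ndarray:
    """Scaled-back coordinates of an exported file (inverse of export)."""
    pdbf = PDBFile.read(str(path))
    scale = 1.0
    for line in pdbf.lines:
        if line.startswith("REMARK 250 SEQSPACE COORDINATE SCALE"):
            scale = float(line.split()[-1])
    atoms = pdbf.get_structure(model=1)
    return atoms.coord / scale
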