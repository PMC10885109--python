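"""Per-residue solvent accessibility and mutation-profile mapping on structures.

Absolute SASA is computed with the Shrake-Rupley rolling-probe algorithm
(probe 1.4 Å, Fibonacci point meshes) and summed per residue; relative SASA
divides by the residue type's theoretical maximum accessibility in a
Gly-X-Gly tripeptide (Tien et al. 2013, theoretical column).  Relative
values are reported uncapped — exposed termini and isolated residues can
legitimately exceed 1 because the Gly-X-Gly reference includes neighbour
occlusion.

Mutation frequencies from an SHM profile can be written onto residues of a
chain (through an explicit Chothia-label → residue-number map) and exported
in the temperature-factor column for visualisation.
"""

from __future__ import annotations

import logging
from typing import Mapping

import biotite.structure as struc
import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile

from .errors import ParameterError
from .shm import MutationProfile

logger = logging.getLogger(__name__)

#: Theoretical maximum accessibility (Å²) per residue type in Gly-X-Gly
#: (Tien et al. 2013).
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Expected heavy-atom counts per residue type, used to flag partial residues.
_HEAVY_ATOMS = {
    "ALA": 5, "ARG": 11, "ASN": 8, "ASP": 8, "CYS": 6, "GLN": 9, "GLU": 9,
    "GLY": 4, "HIS": 10, "ILE": 8, "LEU": 8, "LYS": 9, "MET": 8, "PHE": 11,
    "PRO": 7, "SER": 6, "THR": 7, "TRP": 14, "TYR": 12, "VAL": 7,
}


def load_structure(path, model: int = 1) -> struc.AtomArray:
    """Read a PDB file into an AtomArray (protein atoms of one model)."""
    pdb = PDBFile.read(str(path))
    array = pdb.get_structure(model=model, extra_fields=["b_factor"])
    array = array[struc.filter_amino_acids(array)]
    if array.array_length() == 0:
        raise ParameterError(f"{path}: no protein chain found")
    return array


def compute_sasa(
    structure,
    probe_radius: float = 1.4,
    n_points: int = 1000,
    chains: list[str] | None = None,
) -> pd.DataFrame:
    """Per-residue absolute and relative SASA.

    ``structure`` is a PDB path or an AtomArray.  ``chains`` optionally
    restricts the computation (the retained chains still occlude each other
    when several are given).  Residues of non-standard type or with missing
    heavy atoms are flagged ``partial`` and get NaN relative SASA when no
    reference maximum exists.
    """
    if not isinstance(structure, struc.AtomArray):
        structure = load_structure(structure)
    array = structure
    if chains is not None:
        mask = np.isin(array.chain_id, chains)
        if not mask.any():
            raise ParameterError(
                f"chain(s) {chains} not found; available: {sorted(set(array.chain_id))}"
            )
        array = array[mask]
    array = array[array.element != "H"]

    atom_sasa = struc.sasa(array, probe_radius=probe_radius, point_number=n_points)
    atom_sasa = np.nan_to_num(atom_sasa)

    rows = []
    starts = struc.get_residue_starts(array, add_exclusive_stop=True)
    for begin, end in zip(starts[:-1], starts[1:]):
        res_name = str(array.res_name[begin])
        n_atoms = int(end - begin)
        absolute = float(atom_sasa[begin:end].sum())
        max_asa = MAX_ASA.get(res_name)
        partial = max_asa is None or n_atoms < _HEAVY_ATOMS.get(res_name, 0)
        rows.append({
            "chain_id": str(array.chain_id[begin]),
            "res_id": int(array.res_id[begin]),
            "ins_code": str(array.ins_code[begin]) if hasattr(array, "ins_code") else "",
            "res_name": res_name,
            "n_atoms": n_atoms,
            "sasa": absolute,
            "rel_sasa": absolute / max_asa if max_asa else np.nan,
            "partial": bool(partial),
        })
    return pd.DataFrame(rows)


def rsasa_at_positions(
    table: pd.DataFrame,
    chain: str,
    numbering_map: Mapping[str, int],
    labels: list[str],
) -> dict[str, float]:
    """Relative SASA at the requested Chothia labels of one chain.

    ``numbering_map`` sends Chothia labels to PDB residue numbers for the
    chain of interest (supplied explicitly; no numbering engine is applied).
    """
    sub = table[table["chain_id"] == chain].set_index("res_id")
    missing = [lab for lab in labels if numbering_map.get(lab) not in sub.index]
    if missing:
        raise ParameterError(
            f"label(s) not resolvable on chain {chain!r}: {', '.join(missing)}"
        )
    return {lab: float(sub.loc[numbering_map[lab], "rel_sasa"]) for lab in labels}


def map_profile_to_structure(
    prof: MutationProfile,
    structure,
    chain: str,
    numbering_map: Mapping[str, int],
) -> tuple[pd.DataFrame, struc.AtomArray]:
    """Annotate residues of ``chain`` with per-position mutation frequencies.

    Returns a per-residue annotation table and a copy of the structure with
    the frequency written into the temperature-factor column (0 elsewhere),
    ready for cartoon-putty style visualisation.  Labels that do not resolve
    onto the chain are reported in ``table.attrs["unresolved"]``.
    """
    if not isinstance(structure, struc.AtomArray):
        structure = load_structure(structure)
    array = structure.copy()
    array.set_annotation("b_factor", np.zeros(array.array_length()))

    resolved, unresolved = [], []
    chain_res = set(array.res_id[array.chain_id == chain].tolist())
    for lab in prof.labels:
        res_id = numbering_map.get(lab)
        if res_id is None or res_id not in chain_res:
            unresolved.append(lab)
            continue
        freq = prof.per_position_freq[lab]
        mask = (array.chain_id == chain) & (array.res_id == res_id)
        array.b_factor[mask] = freq
        resolved.append({"label": lab, "res_id": res_id, "freq": freq})
    if not resolved:
        raise ParameterError("no profile label resolves onto the requested chain")
    if unresolved:
        logger.info("unresolved labels: %s", unresolved)
    table = pd.DataFrame(resolved)
    table.attrs["unresolved"] = unresolved
    return table, array


def write_annotated_pdb(array: struc.AtomArray, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(array)
    pdb.write(str(path))
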