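"""Shared chemical reference data: vdW radii and residue connectivity.

Connectivity templates cover the protein backbone (and the ALA/GLY side
chains the synthetic systems use); side-chain atoms without a template bond
are connected by the < 1.9 Å heavy-atom distance heuristic, which is also
the fallback for nonstandard residues.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .structures import StructureModel

# standard element vdW radii (Å); unknown elements default to carbon's
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.20, "D": 1.20, "SE": 1.90, "F": 1.47, "CL": 1.75,
    "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.70

# intra-residue bonds by atom name; backbone entries apply to every residue
_BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT"),
                   ("CA", "CB")]
_DISTANCE_BOND_CUTOFF = 1.9  # Å, heavy-atom fallback

_TEMPLATED_RESIDUES = {"ALA", "GLY"}  # fully covered by the backbone template


def vdw_radius(element: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        warnings.warn(f"unknown element {element!r}: using default vdW radius",
                      stacklevel=3)
        return DEFAULT_VDW
    return r


def bonded_pairs(model: StructureModel) -> list[tuple[int, int]]:
    """Covalent heavy-atom bonds as (i, j) atom-index pairs, i < j.

    Backbone bonds come from the name template, the peptide bond links
    C(i)–N(i+1) between consecutive residues of a chain, and any heavy atoms
    left unbonded by the template are connected by the distance heuristic.
    """
    heavy = model.heavy_mask & ~model.hetero_flags
    # index atoms by (residue_key, name)
    by_res: dict[tuple, dict[str, int]] = {}
    res_order: list[tuple] = []
    for i in np.flatnonzero(heavy):
        key = model.residue_key(i)
        if key not in by_res:
            by_res[key] = {}
            res_order.append(key)
        by_res[key][model.names[i]] = i

    bonds: set[tuple[int, int]] = set()

    def add(i: int, j: int) -> None:
        bonds.add((i, j) if i < j else (j, i))

    for key in res_order:
        atoms = by_res[key]
        for a, b in _BACKBONE_BONDS:
            if a in atoms and b in atoms:
                add(atoms[a], atoms[b])

    # peptide bonds between consecutive residues within a chain
    for k in range(len(res_order) - 1):
        key_a, key_b = res_order[k], res_order[k + 1]
        if key_a[0] != key_b[0]:
            continue
        a, b = by_res[key_a], by_res[key_b]
        if "C" in a and "N" in b:
            ci, nj = a["C"], b["N"]
            # guard against chain breaks: only bond if geometrically bonded
            if np.linalg.norm(model.positions[ci] - model.positions[nj]) < _DISTANCE_BOND_CUTOFF:
                add(ci, nj)

    # distance heuristic for atoms the template does not cover
    untempl = sorted(i for i in np.flatnonzero(heavy)
                     if model.names[i] not in ("N", "CA", "C", "O", "OXT", "CB"))
    if untempl:
        pos_all = model.positions
        tree = cKDTree(pos_all[heavy])
        heavy_idx = np.flatnonzero(heavy)
        for i in untempl:
            for local_j in tree.query_ball_point(pos_all[i], _DISTANCE_BOND_CUTOFF):
                j = heavy_idx[local_j]
                if j != i:
                    add(i, j)
    return sorted(bonds)


def bond_graph_exclusions(model: StructureModel, max_separation: int = 2) -> set[tuple[int, int]]:
    """Atom pairs within ``max_separation`` bonds (1-2 and 1-3 neighbours)."""
    bonds = bonded_pairs(model)
    adj: dict[int, set[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    excl: set[tuple[int, int]] = set()
    for i, j in bonds:
        excl.add((i, j))
    if max_separation >= 2:
        for center, nbrs in adj.items():
            nb = sorted(nbrs)
            for a in range(len(nb)):
                for b in range(a + 1, len(nb)):
                    excl.add((nb[a], nb[b]))
    return excl
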