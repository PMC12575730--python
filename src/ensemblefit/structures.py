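"""Protein structure and trajectory containers with PDB/mmCIF I/O.

The in-memory model is deliberately flat: a :class:`StructureModel` stores
parallel arrays (one entry per atom), which keeps coordinate-heavy stages
(refinement, map simulation) fast while individual :class:`Atom` records
remain available as lightweight views.

Conventions
-----------
* Coordinates are always in Å, right-handed, exactly as stored in the file.
* Author residue numbering is preserved; residue identity is the key
  ``(chain_id, residue_index, insertion_code)``.
* Alternate locations are collapsed to the highest-occupancy conformer
  (first wins on ties) so every model is a deterministic single conformer.
* Hydrogens are passed through on read/write but flagged, and excluded from
  clash and RMSD computations downstream.
* HETATM records are kept but flagged non-protein and excluded from Cα
  operations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "Ensemble",
    "Trajectory",
    "ParseError",
    "TopologyError",
    "CoordinateOverflowError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "ca_coordinates",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# PDB fixed columns hold coordinates in %8.3f: |x| < 10000 after rounding.
_PDB_COORD_LIMIT = 9999.9995


class ParseError(ValueError):
    """A structure or map file could not be parsed."""


class TopologyError(ValueError):
    """Residue/atom topology violates an invariant (e.g. a chain without CA)."""


class CoordinateOverflowError(ValueError):
    """Coordinates do not fit the fixed-width fields of the output format."""


@dataclass(frozen=True)
class Atom:
    """One atom record (a read-only view into a :class:`StructureModel`)."""

    element: str
    name: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    insertion_code: str = ""
    is_hetero: bool = False
    occupancy: float = 1.0


class StructureModel:
    """A single-conformer protein model stored as parallel per-atom arrays."""

    def __init__(
        self,
        names: Sequence[str],
        elements: Sequence[str],
        residue_indices: Sequence[int],
        residue_names: Sequence[str],
        chain_ids: Sequence[str],
        positions: np.ndarray,
        insertion_codes: Sequence[str] | None = None,
        hetero_flags: Sequence[bool] | None = None,
        occupancies: Sequence[float] | None = None,
    ):
        n = len(names)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=np.int64)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.positions = np.asarray(positions, dtype=np.float64).reshape(n, 3)
        self.insertion_codes = (
            np.asarray(insertion_codes, dtype=object)
            if insertion_codes is not None
            else np.asarray([""] * n, dtype=object)
        )
        self.hetero_flags = (
            np.asarray(hetero_flags, dtype=bool)
            if hetero_flags is not None
            else np.zeros(n, dtype=bool)
        )
        self.occupancies = (
            np.asarray(occupancies, dtype=np.float64)
            if occupancies is not None
            else np.ones(n, dtype=np.float64)
        )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("atom positions must be finite")
        if any(not e for e in self.elements):
            raise ValueError("every atom needs a non-empty element symbol")
        self._validate_topology()

    # ---- invariants -----------------------------------------------------

    def _validate_topology(self) -> None:
        backbone = {"N", "CA", "C", "O", "OXT"}
        seen: dict[tuple, dict] = {}
        for i in range(self.n_atoms):
            if self.hetero_flags[i]:
                continue
            key = self.residue_key(i)
            rec = seen.setdefault(key, {"bb": False, "ca": 0})
            if self.names[i] in backbone:
                rec["bb"] = True
            if self.names[i] == "CA" and self.elements[i] != "Ca":
                rec["ca"] += 1
        for key, rec in seen.items():
            if rec["bb"] and rec["ca"] != 1:
                raise TopologyError(
                    f"residue {key} has {rec['ca']} CA atoms (expected exactly 1)"
                )
        if seen and not any(rec["ca"] for rec in seen.values()):
            raise TopologyError("no CA atoms found in any protein residue")

    # ---- basic accessors ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def residue_key(self, atom_index: int) -> tuple[str, int, str]:
        return (
            self.chain_ids[atom_index],
            int(self.residue_indices[atom_index]),
            self.insertion_codes[atom_index],
        )

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.array([e in ("H", "D") for e in self.elements], dtype=bool)

    @property
    def heavy_mask(self) -> np.ndarray:
        return ~self.is_hydrogen

    @property
    def ca_mask(self) -> np.ndarray:
        return np.array(
            [
                (n == "CA" and e != "Ca" and not h)
                for n, e, h in zip(self.names, self.elements, self.hetero_flags)
            ],
            dtype=bool,
        )

    @property
    def n_residues(self) -> int:
        """Number of protein residues carrying a CA atom."""
        return int(self.ca_mask.sum())

    def residue_keys_ca(self) -> list[tuple[str, int, str]]:
        """Residue keys in CA order (one per residue, file order)."""
        return [self.residue_key(i) for i in np.flatnonzero(self.ca_mask)]

    @property
    def sequence(self) -> dict[str, str]:
        """One-letter sequence per chain, from residues with a CA atom."""
        seqs: dict[str, list[str]] = {}
        for i in np.flatnonzero(self.ca_mask):
            one = _THREE_TO_ONE.get(self.residue_names[i], "X")
            seqs.setdefault(self.chain_ids[i], []).append(one)
        return {c: "".join(s) for c, s in seqs.items()}

    def atoms(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield Atom(
                element=self.elements[i],
                name=self.names[i],
                residue_index=int(self.residue_indices[i]),
                residue_name=self.residue_names[i],
                chain_id=self.chain_ids[i],
                position=self.positions[i].copy(),
                insertion_code=self.insertion_codes[i],
                is_hetero=bool(self.hetero_flags[i]),
                occupancy=float(self.occupancies[i]),
            )

    def topology_signature(self) -> tuple:
        """Hashable per-atom identity used for topology equality checks."""
        return tuple(
            (self.chain_ids[i], int(self.residue_indices[i]),
             self.insertion_codes[i], self.names[i])
            for i in range(self.n_atoms)
        )

    def with_positions(self, positions: np.ndarray) -> "StructureModel":
        """Copy of this model with replaced coordinates (same topology)."""
        out = StructureModel.__new__(StructureModel)
        out.names = self.names
        out.elements = self.elements
        out.residue_indices = self.residue_indices
        out.residue_names = self.residue_names
        out.chain_ids = self.chain_ids
        out.insertion_codes = self.insertion_codes
        out.hetero_flags = self.hetero_flags
        out.occupancies = self.occupancies
        pos = np.asarray(positions, dtype=np.float64).reshape(self.n_atoms, 3)
        if not np.all(np.isfinite(pos)):
            raise ValueError("atom positions must be finite")
        out.positions = pos.copy()
        return out

    def copy(self) -> "StructureModel":
        return self.with_positions(self.positions)


@dataclass
class Ensemble:
    """Ordered collection of topology-identical models."""

    models: list[StructureModel]
    source_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.models) < 1:
            raise ValueError("an ensemble needs at least one model")
        sig = self.models[0].topology_signature()
        for i, m in enumerate(self.models[1:], start=1):
            if m.topology_signature() != sig:
                raise TopologyError(f"model {i} topology differs from model 0")
        if self.source_labels is not None and len(self.source_labels) != len(self.models):
            raise ValueError("source_labels length must match models")

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, i: int) -> StructureModel:
        return self.models[i]

    def labels(self) -> list[str]:
        if self.source_labels is not None:
            return list(self.source_labels)
        return [f"model_{i:04d}" for i in range(len(self.models))]


@dataclass
class Trajectory:
    """Ordered frames from one refinement run (all topologically identical)."""

    frames: list[StructureModel]
    frame_interval: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a trajectory needs at least one frame")
        sig = self.frames[0].topology_signature()
        for i, f in enumerate(self.frames[1:], start=1):
            if f.topology_signature() != sig:
                raise TopologyError(f"frame {i} topology differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# gemmi conversion


def _from_gemmi_model(gmodel: gemmi.Model) -> StructureModel:
    names, elements, ridx, rnames, chains, icodes, het, occ = ([] for _ in range(8))
    pos = []
    for chain in gmodel:
        for res in chain:
            # collapse altlocs: highest occupancy wins, first on tie
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                if atom.name not in best:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > best[atom.name].occ:
                    best[atom.name] = atom
            for name in order:
                atom = best[name]
                names.append(atom.name)
                elements.append(atom.element.name or "X")
                ridx.append(res.seqid.num)
                rnames.append(res.name)
                chains.append(chain.name)
                icodes.append(res.seqid.icode.strip())
                het.append(res.het_flag == "H")
                occ.append(atom.occ)
                pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not names:
        raise ParseError("file contains no atoms")
    return StructureModel(
        names, elements, ridx, rnames, chains,
        np.array(pos, dtype=np.float64),
        insertion_codes=icodes, hetero_flags=het, occupancies=occ,
    )


def _to_gemmi_structure(models: Sequence[StructureModel], name: str = "model") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for mi, model in enumerate(models, start=1):
        if np.any(np.abs(model.positions) > _PDB_COORD_LIMIT):
            raise CoordinateOverflowError(
                "coordinates exceed the ±9999.999 Å range of fixed-width PDB fields"
            )
        gm = gemmi.Model(mi)
        chain_map: dict[str, gemmi.Chain] = {}
        res_ref: dict[tuple, gemmi.Residue] = {}
        for i in range(model.n_atoms):
            cid = model.chain_ids[i]
            if cid not in chain_map:
                chain_map[cid] = gemmi.Chain(cid)
                gm.add_chain(chain_map[cid])
                chain_map[cid] = gm[len(list(gm)) - 1]
            key = model.residue_key(i)
            if key not in res_ref:
                res = gemmi.Residue()
                res.name = model.residue_names[i]
                res.seqid = gemmi.SeqId(int(model.residue_indices[i]),
                                        model.insertion_codes[i] or " ")
                res.het_flag = "H" if model.hetero_flags[i] else "A"
                chain_map[cid].add_residue(res)
                res_ref[key] = chain_map[cid][len(chain_map[cid]) - 1]
            atom = gemmi.Atom()
            atom.name = model.names[i]
            atom.element = gemmi.Element(model.elements[i])
            atom.occ = float(model.occupancies[i])
            x, y, z = model.positions[i]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            res_ref[key].add_atom(atom)
        st.add_model(gm)
    st.setup_entities()
    return st


# ---------------------------------------------------------------------------
# public I/O


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("pdb", "mmcif", "cif"):
            raise ValueError(f"unsupported structure format: {fmt}")
        return "mmcif" if fmt == "cif" else fmt
    ext = os.path.splitext(str(path))[1].lower()
    return "mmcif" if ext in (".cif", ".mmcif") else "pdb"


def _read_gemmi(path: str, fmt: str) -> gemmi.Structure:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        if fmt == "pdb":
            return gemmi.read_pdb(str(path))
        return gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path!s}: {exc}") from exc


def read_structure(path: str, format: str | None = None) -> StructureModel:
    """Read a single-model structure from PDB or mmCIF.

    Hydrogens are retained; altlocs collapse to the highest-occupancy
    conformer; author residue numbering is preserved.
    """
    fmt = _detect_format(path, format)
    st = _read_gemmi(path, fmt)
    if len(st) == 0:
        raise ParseError(f"{path!s}: no models in file")
    return _from_gemmi_model(st[0])


def write_structure(model: StructureModel, path: str, format: str | None = None) -> None:
    """Write a model to PDB or mmCIF (coordinates at format precision)."""
    fmt = _detect_format(path, format)
    st = _to_gemmi_structure([model])
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def read_trajectory(paths: str | Sequence[str], format: str | None = None) -> Trajectory:
    """Read a trajectory from a multi-model PDB or an ordered list of files.

    This is the import channel for externally produced density-guided
    simulation output (frames exported as PDB models).
    """
    if isinstance(paths, (str, os.PathLike)):
        fmt = _detect_format(paths, format)
        st = _read_gemmi(str(paths), fmt)
        if len(st) == 0:
            raise ParseError(f"{paths!s}: no models in file")
        frames = [_from_gemmi_model(m) for m in st]
    else:
        frames = [read_structure(p, format) for p in paths]
    return Trajectory(frames=frames)


def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write trajectory frames as a multi-model PDB (MODEL/ENDMDL records)."""
    st = _to_gemmi_structure(traj.frames, name="trajectory")
    st.write_pdb(str(path))


def ca_coordinates(model: StructureModel) -> np.ndarray:
    """Cα coordinates, one row per protein residue, in residue order (Å)."""
    return model.positions[model.ca_mask].copy()
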