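"""Residue-level (Cα) I/O for antibody–antigen complex structures.

Complexes are represented at one point per residue: the Cα coordinate,
the amino-acid type, and the author residue numbering with insertion
codes. Chain roles (heavy / light / antigen) come from an explicit
mapping supplied by the caller — typically from a curated summary file —
and are never inferred from sequence.

Parsing and writing go through biotite; only ``ATOM`` records with atom
name ``CA`` are consumed, keeping the first altloc encountered.
Non-canonical residues map to the ``UNKNOWN`` symbol ``X`` and are never
treated as designable.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AA_ALPHABET",
    "AA_TO_INDEX",
    "UNKNOWN_AA",
    "ResidueRecord",
    "ChainRecord",
    "ComplexRecord",
    "read_complex",
    "check_cdr_completeness",
    "write_chain_pdb",
    "read_role_manifest",
]

#: The 20 canonical amino acids, one-letter codes, alphabetical.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_AA = "X"
AA_TO_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE[UNKNOWN_AA] = "UNK"

ROLES = ("heavy", "light", "antigen")


class StructureFormatError(ValueError):
    """Raised when a structure source cannot be parsed."""


class EmptyChainError(ValueError):
    """Raised when a kept chain contributes no Cα atoms."""


class ChainNotFoundError(KeyError):
    """Raised when an operation references a chain absent from a complex."""


@dataclass(frozen=True)
class ResidueRecord:
    chain_id: str
    res_number: int
    insertion_code: str  # single char or ""
    amino_acid: str      # one-letter code or UNKNOWN_AA
    ca_coord: np.ndarray  # (3,) Å

    def __post_init__(self):
        coord = np.asarray(self.ca_coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError("ca_coord must be a finite 3-vector")
        object.__setattr__(self, "ca_coord", coord)
        if self.amino_acid not in AA_TO_INDEX and self.amino_acid != UNKNOWN_AA:
            raise ValueError(f"unknown amino acid symbol {self.amino_acid!r}")


@dataclass
class ChainRecord:
    chain_id: str
    role: str  # heavy | light | antigen
    residues: list[ResidueRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        keys = [(r.res_number, r.insertion_code) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate (res_number, icode) in chain {self.chain_id}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_antibody(self) -> bool:
        return self.role in ("heavy", "light")

    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.array([r.ca_coord for r in self.residues], dtype=float)


@dataclass
class ComplexRecord:
    complex_id: str
    chains: list[ChainRecord]
    pairing: dict[str, str] = field(default_factory=dict)  # heavy id -> light id

    def __post_init__(self):
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError("chain_ids must be unique")

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ChainNotFoundError(chain_id)

    def partner_of(self, chain_id: str) -> str | None:
        """Antibody partner chain id (heavy↔light), if paired."""
        if chain_id in self.pairing:
            return self.pairing[chain_id]
        for h, l in self.pairing.items():
            if l == chain_id:
                return h
        return None


def _structure_from_source(pdb_source) -> struc.AtomArray:
    try:
        if isinstance(pdb_source, (str, Path)) and os.path.exists(str(pdb_source)):
            pdb = PDBFile.read(str(pdb_source))
        else:
            pdb = PDBFile.read(io.StringIO(str(pdb_source)))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises various types on malformed input
        raise StructureFormatError(f"cannot parse PDB source: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureFormatError("PDB source contains no atoms")
    return atoms


def read_complex(
    pdb_source,
    chain_roles: dict[str, str],
    complex_id: str = "complex",
    pairing: dict[str, str] | None = None,
) -> ComplexRecord:
    """Parse a PDB file or text into a Cα-level :class:`ComplexRecord`.

    Parameters
    ----------
    pdb_source
        Path to a PDB file, or PDB-format text.
    chain_roles
        Mapping chain id → role (``heavy``/``light``/``antigen``). Chains
        not in the mapping are dropped.
    pairing
        Optional heavy→light chain pairing; inferred as the single
        heavy/light pair when exactly one of each is present.
    """
    atoms = _structure_from_source(pdb_source)
    ca = atoms[(atoms.atom_name == "CA") & struc.filter_amino_acids(atoms)]

    chains: list[ChainRecord] = []
    for chain_id, role in chain_roles.items():
        sel = ca[ca.chain_id == chain_id]
        residues: list[ResidueRecord] = []
        seen: set[tuple[int, str]] = set()
        for i in range(sel.array_length()):
            key = (int(sel.res_id[i]), str(sel.ins_code[i]).strip())
            if key in seen:  # altloc duplicates: keep first
                continue
            seen.add(key)
            residues.append(
                ResidueRecord(
                    chain_id=chain_id,
                    res_number=key[0],
                    insertion_code=key[1],
                    amino_acid=_THREE_TO_ONE.get(str(sel.res_name[i]), UNKNOWN_AA),
                    ca_coord=np.array(sel.coord[i], dtype=float),
                )
            )
        if not residues:
            raise EmptyChainError(f"chain {chain_id!r} has no Cα atoms")
        chains.append(ChainRecord(chain_id=chain_id, role=role, residues=residues))

    if pairing is None:
        heavies = [c.chain_id for c in chains if c.role == "heavy"]
        lights = [c.chain_id for c in chains if c.role == "light"]
        pairing = {heavies[0]: lights[0]} if len(heavies) == 1 and len(lights) == 1 else {}
    return ComplexRecord(complex_id=complex_id, chains=chains, pairing=pairing)


def check_cdr_completeness(complex_record: ComplexRecord, cdr) -> bool:
    """True iff every CDR residue exists with a Cα and a canonical amino acid.

    ``cdr`` is a :class:`~cdrdesign.cdr_schemes.CdrSpec`; completeness is
    judged on the sequential index range ``start_idx..end_idx``.
    """
    chain = complex_record.chain(cdr.chain_id)
    if cdr.start_idx < 0 or cdr.end_idx >= len(chain):
        return False
    return all(
        chain.residues[i].amino_acid in AA_TO_INDEX
        for i in range(cdr.start_idx, cdr.end_idx + 1)
    )


def _chain_to_atom_array(chain: ChainRecord) -> struc.AtomArray:
    n = len(chain)
    arr = struc.AtomArray(n)
    arr.coord = chain.coords()
    arr.chain_id = np.full(n, chain.chain_id)
    arr.res_id = np.array([r.res_number for r in chain.residues])
    arr.ins_code = np.array([r.insertion_code for r in chain.residues])
    arr.res_name = np.array([_ONE_TO_THREE[r.amino_acid] for r in chain.residues])
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.full(n, False)
    return arr


def write_chain_pdb(complex_record: ComplexRecord, chain_id: str, out) -> Path:
    """Write one chain as a CA-only PDB file; round-trips through read_complex."""
    chain = complex_record.chain(chain_id)
    out = Path(out)
    if not out.parent.exists():
        raise IOError(f"output directory {out.parent} does not exist")
    pdb = PDBFile()
    pdb.set_structure(_chain_to_atom_array(chain))
    pdb.write(str(out))
    return out


def write_complex_pdb(complex_record: ComplexRecord, out) -> Path:
    """Write all chains of a complex as a CA-only PDB file."""
    out = Path(out)
    if not out.parent.exists():
        raise IOError(f"output directory {out.parent} does not exist")
    arrays = [_chain_to_atom_array(c) for c in complex_record.chains]
    merged = arrays[0]
    for a in arrays[1:]:
        merged += a
    pdb = PDBFile()
    pdb.set_structure(merged)
    pdb.write(str(out))
    return out


def read_role_manifest(path) -> dict[str, dict[str, str]]:
    """Read a tab-separated chain-role manifest: complex_id, chain_id, role."""
    roles: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            complex_id, chain_id, role = line.split("\t")
            roles.setdefault(complex_id, {})[chain_id] = role
    return roles
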