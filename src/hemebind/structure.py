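"""Parsing of PDB structures into chains of residues plus heme groups.

Only heavy atoms are retained (the depth/protrusion descriptor literature
is defined on heavy atoms, and deposited heme-protein structures rarely
resolve hydrogens consistently).  Waters and HET groups other than ``HEM``
are discarded.  Alternate locations are resolved to the highest-occupancy
conformer, ties broken alphabetically by altloc identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueUnit",
    "HemeGroup",
    "ChainModel",
    "StructureError",
    "parse_structure",
    "chain_sequence",
    "write_structure",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Modified residues mapped to the nearest standard parent type.
NONSTANDARD_TO_STANDARD = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "MLY": "LYS", "M3L": "LYS", "KCX": "LYS", "CME": "CYS",
    "CSD": "CYS", "OCS": "CYS", "FME": "MET", "PCA": "GLU",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

HEME_CODE = "HEM"
_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class StructureError(ValueError):
    """Raised for unparseable or degenerate structure input."""


@dataclass
class AtomRecord:
    """A single heavy atom."""

    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    is_sidechain: bool = False
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name}: empty element")


@dataclass
class ResidueUnit:
    """One polymer residue with its resolved heavy atoms."""

    chain_id: str
    seq_position: str  # author residue number + insertion code
    aa_type: str       # three-letter standard code or "UNK"
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def has_ca(self) -> bool:
        return any(a.name == "CA" for a in self.atoms)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.aa_type, "X")

    def ca_coord(self) -> np.ndarray:
        for a in self.atoms:
            if a.name == "CA":
                return a.coord
        raise StructureError(f"residue {self.seq_position} has no CA atom")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class HemeGroup:
    """A heme (HET code HEM) with its heavy atoms."""

    het_code: str
    atoms: list[AtomRecord]
    parent_structure_id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("heme group with no atoms")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class ChainModel:
    """An ordered chain of polymer residues."""

    chain_id: str
    residues: list[ResidueUnit]

    @property
    def sequence(self) -> str:
        return chain_sequence(self)

    def __len__(self) -> int:
        return len(self.residues)

    def all_atom_coords(self) -> np.ndarray:
        return np.vstack([r.coords() for r in self.residues])

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates, NaN rows for residues without a Cα."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, r in enumerate(self.residues):
            for a in r.atoms:
                if a.name == "CA":
                    out[i] = a.coord
                    break
        return out


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc id."""
    by_name: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = a
            order.append(a.name)
        else:
            b = by_name[a.name]
            if (a.occupancy, _altloc_rank(a.altloc)) > (b.occupancy, _altloc_rank(b.altloc)):
                by_name[a.name] = a
    return [by_name[n] for n in order]


def _altloc_rank(altloc: str) -> int:
    # Higher rank wins; alphabetically earlier altloc ids win ties.
    return -ord(altloc) if altloc else 0


def parse_structure(pdb_text: str) -> tuple[list[ChainModel], list[HemeGroup]]:
    """Parse PDB text into polymer chains and heme groups.

    ATOM records (plus HETATM records of mappable modified residues) form
    :class:`ChainModel` objects; HETATM residues named ``HEM`` form
    :class:`HemeGroup` objects; waters and other HET groups are dropped.
    Hydrogens are discarded everywhere.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"unparseable PDB input: {exc}") from exc
    if len(st) == 0:
        raise StructureError("no models in PDB input")
    st.setup_entities()
    model = st[0]

    chains: list[ChainModel] = []
    hemes: list[HemeGroup] = []
    for ch in model:
        residues: list[ResidueUnit] = []
        for res in ch:
            name = res.name.strip().upper()
            atoms = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                atoms.append(
                    AtomRecord(
                        name=at.name,
                        element=at.element.name,
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_sidechain=at.name not in BACKBONE_ATOMS,
                        occupancy=at.occ,
                        altloc=at.altloc,
                    )
                )
            if not atoms:
                continue
            atoms = _resolve_altlocs(atoms)
            if name == HEME_CODE:
                hemes.append(HemeGroup(het_code=name, atoms=atoms, parent_structure_id=st.name))
                continue
            if name in _WATER_NAMES:
                continue
            std = name if name in THREE_TO_ONE else NONSTANDARD_TO_STANDARD.get(name)
            if std is None:
                if res.het_flag == "H":
                    continue  # unrecognized ligand
                std = "UNK"
            seqid = f"{res.seqid.num}{res.seqid.icode}".strip()
            residues.append(
                ResidueUnit(chain_id=ch.name, seq_position=seqid, aa_type=std, atoms=atoms)
            )
        if residues:
            chains.append(ChainModel(chain_id=ch.name, residues=residues))

    if not chains:
        raise StructureError("no polymer residues found in PDB input")
    return chains, hemes


def chain_sequence(chain: ChainModel) -> str:
    """One-letter sequence of a chain; ``X`` for UNK residues."""
    if not chain.residues:
        raise StructureError("empty chain")
    return "".join(r.one_letter for r in chain.residues)


def write_structure(chains: list[ChainModel], hemes: list[HemeGroup] | None = None) -> str:
    """Serialize chains and hemes back to PDB text (inverse of parse_structure)."""
    st = gemmi.Structure()
    st.name = "hemebind"
    model = gemmi.Model("1")
    heme_chain_ids = set()
    for cm in chains:
        ch = gemmi.Chain(cm.chain_id)
        for res in cm.residues:
            r = gemmi.Residue()
            r.name = res.aa_type if res.aa_type in THREE_TO_ONE else res.aa_type
            num = res.seq_position
            icode = ""
            if num and not num.lstrip("-").isdigit():
                num, icode = num[:-1], num[-1]
            r.seqid = gemmi.SeqId(int(num), icode or " ")
            for a in res.atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.coord)
                at.occ = a.occupancy
                r.add_atom(at)
            ch.add_residue(r)
        model.add_chain(ch)
        heme_chain_ids.add(cm.chain_id)
    if hemes:
        hc = gemmi.Chain(_free_chain_id(heme_chain_ids))
        for i, heme in enumerate(hemes, start=1):
            r = gemmi.Residue()
            r.name = heme.het_code
            r.seqid = gemmi.SeqId(i, " ")
            r.het_flag = "H"
            for a in heme.atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.coord)
                at.occ = a.occupancy
                r.add_atom(at)
            hc.add_residue(r)
        model.add_chain(hc)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def _free_chain_id(used: set[str]) -> str:
    for c in "ZYXWVUTSRQPONMLKJIHGFEDCBA":
        if c not in used:
            return c
    return "z"
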