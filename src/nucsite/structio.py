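"""Protein structure I/O and ligand decomposition.

Parses PDB-format text into a light-weight in-memory model (polymer
chains kept apart from hetero ligands), derives the two-pseudo-atom
residue representation used for structural matching (Cα plus the
geometric centre of the side chain), and splits bound nucleotide
ligands into their module fragments — nucleobase, carbohydrate and
phosphate — according to a declarative atom-name table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import gemmi
import numpy as np
import yaml

NUCLEOBASE = "nucleobase"
CARBOHYDRATE = "carbohydrate"
PHOSPHATE = "phosphate"
MODULE_TYPES = (NUCLEOBASE, CARBOHYDRATE, PHOSPHATE)

LETTER_TO_TYPE = {"N": NUCLEOBASE, "C": CARBOHYDRATE, "P": PHOSPHATE}
TYPE_TO_LETTER = {v: k for k, v in LETTER_TO_TYPE.items()}

#: three-letter -> one-letter amino-acid codes
AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: PDB residue names written for predicted fragments, keyed by subtype
SUBTYPE_RESNAME = {
    "adenine": "ADE", "guanine": "GUN", "cytosine": "CYT",
    "thymine": "THY", "uracil": "URA", "nicotinamide": "NCA",
    "flavin": "FLN", "ribose_closed": "RIB", "ribose_open": "RBO",
    "deoxyribose": "DRB", "phosphate": "PO4",
}


class StructureError(ValueError):
    """Base class for structure-handling errors."""


class FormatError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


class MissingChainError(StructureError, KeyError):
    pass


class UnknownLigandError(StructureError, KeyError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) Å

    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    name: str          # 3-letter code
    seqnum: int
    icode: str
    atoms: list[Atom] = field(default_factory=list)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Ligand:
    component_id: str
    chain_id: str
    seqnum: int
    icode: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> str:
        return f"{self.component_id}_{self.chain_id}{self.seqnum}{self.icode}".strip()


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    ligands: list[Ligand] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise MissingChainError(f"no chain {chain_id!r} in structure {self.id!r}")


@dataclass
class ResidueDescriptor:
    """A residue reduced to Cα + side-chain geometric centre."""
    residue_ref: tuple[str, int, str]  # (chain_id, seqnum, icode)
    aa: str
    ca: np.ndarray
    sc_center: np.ndarray

    def points(self) -> np.ndarray:
        """The (2, 3) pseudo-atom coordinate block used in superposition."""
        return np.vstack([self.ca, self.sc_center])


@dataclass
class ModuleFragment:
    module_type: str
    subtype: str
    atoms: list[Atom]
    centroid: np.ndarray
    provenance: str = "predicted"
    arch_index: int = 0        # position in the source architecture
    branch: bool = False       # hangs off the linear architecture (NADP 2'-P)
    complete: bool = True

    @staticmethod
    def from_atoms(module_type, subtype, atoms, provenance="predicted",
                   arch_index=0, branch=False, complete=True) -> "ModuleFragment":
        heavy = [a for a in atoms if not a.is_hydrogen()]
        if not heavy:
            raise ValueError("fragment has no heavy atoms")
        centroid = np.mean([a.pos for a in heavy], axis=0)
        return ModuleFragment(module_type, subtype, list(atoms), centroid,
                              provenance, arch_index, branch, complete)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms if not a.is_hydrogen()])


@dataclass
class FragmentSpec:
    module_type: str
    subtype: str
    atom_names: list[str]
    branch: bool = False


@dataclass
class FragmentDefinition:
    component_id: str
    fragments: list[FragmentSpec]

    @property
    def architecture(self) -> str:
        """Module-type letters of the linear (non-branch) fragments."""
        return "".join(TYPE_TO_LETTER[f.module_type]
                       for f in self.fragments if not f.branch)


def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def load_fragment_definitions(path=None) -> dict[str, FragmentDefinition]:
    """Load the component -> fragment atom-name table (YAML)."""
    if path is None:
        ref = importlib.resources.files("nucsite") / "data" / "fragment_definitions.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    defs = {}
    for comp_id, entry in raw["components"].items():
        frags = []
        for f in entry["fragments"]:
            if f["type"] not in MODULE_TYPES:
                raise FormatError(f"{comp_id}: unknown module type {f['type']!r}")
            frags.append(FragmentSpec(f["type"], f["subtype"],
                                      [str(a) for a in f["atoms"]],
                                      bool(f.get("branch", False))))
        all_names = [a for fr in frags for a in fr.atom_names]
        if len(all_names) != len(set(all_names)):
            raise FormatError(f"{comp_id}: atom assigned to more than one fragment")
        defs[comp_id] = FragmentDefinition(comp_id, frags)
    return defs


def _norm_atom_name(name: str) -> str:
    # old-style PDB files use * instead of ' in sugar atom names
    return name.strip().replace("*", "'").upper()


def _resolve_altlocs(gres) -> list:
    """Pick one atom per name: highest occupancy, first in file on ties."""
    best: dict[str, tuple[float, int]] = {}
    chosen: dict[str, object] = {}
    for idx, atom in enumerate(gres):
        key = atom.name
        occ = atom.occ if atom.altloc else max(atom.occ, 1.0)
        if key not in best or occ > best[key][0]:
            best[key] = (occ, idx)
            chosen[key] = atom
    order = sorted(chosen, key=lambda k: best[k][1])
    return [chosen[k] for k in order]


def parse_structure(pdb_text: str, structure_id: str = "struct") -> Structure:
    """Parse PDB-format text (first model only).

    Polymer residues and hetero ligands are separated by record type;
    waters are dropped; alternate locations collapse to the highest
    occupancy conformer (ties: first in file).
    """
    if not pdb_text.strip():
        raise EmptyStructureError("empty input")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(str(exc)) from exc
    if len(st) == 0:
        raise EmptyStructureError("no model in input")
    model = st[0]

    out = Structure(id=structure_id or st.name or "struct")
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        seen_keys = set()
        for gres in gchain:
            if gres.is_water():
                continue
            atoms = []
            for ga in _resolve_altlocs(gres):
                pos = np.array([ga.pos.x, ga.pos.y, ga.pos.z], dtype=float)
                if not np.all(np.isfinite(pos)):
                    raise FormatError(
                        f"non-finite coordinates in {gchain.name}/{gres.seqid.num}")
                elem = ga.element.name.upper() if ga.element else ""
                atoms.append(Atom(ga.name, elem or _element_from_name(ga.name), pos))
            icode = gres.seqid.icode.strip()
            if gres.het_flag == "H":
                out.ligands.append(Ligand(gres.name, gchain.name,
                                          gres.seqid.num, icode, atoms))
            else:
                key = (gchain.name, gres.seqid.num, icode)
                if key in seen_keys:
                    raise FormatError(f"duplicate residue identity {key}")
                seen_keys.add(key)
                chain.residues.append(Residue(gres.name, gres.seqid.num,
                                              icode, atoms))
        if chain.residues:
            out.chains.append(chain)
    if not out.chains:
        if out.ligands:
            raise EmptyStructureError("no polymer residues (HETATM records only)")
        raise EmptyStructureError("no ATOM records parsed")
    return out


def residue_descriptors(structure: Structure, chain_id: str) -> list[ResidueDescriptor]:
    """One descriptor per residue with a resolved Cα.

    The side-chain centre is the geometric mean of the heavy side-chain
    atoms (backbone N, CA, C, O, OXT excluded); glycine — or any residue
    with no resolved side-chain heavy atom — reuses the Cα position.
    """
    chain = structure.chain(chain_id)
    out = []
    for res in chain.residues:
        ca = res.get_atom("CA")
        if ca is None:
            continue
        if res.name == "GLY":
            side = []
        else:
            side = [a.pos for a in res.atoms
                    if a.name not in BACKBONE_ATOMS and not a.is_hydrogen()]
        sc = np.mean(side, axis=0) if side else ca.pos.copy()
        out.append(ResidueDescriptor(
            residue_ref=(chain_id, res.seqnum, res.icode),
            aa=AA_3TO1.get(res.name, "X"),
            ca=ca.pos.copy(),
            sc_center=sc,
        ))
    return out


def chain_sequence(structure: Structure, chain_id: str) -> str:
    """One-letter sequence of residues that carry a Cα, in chain order."""
    return "".join(d.aa for d in residue_descriptors(structure, chain_id))


def decompose_ligand(ligand: Ligand,
                     defs: dict[str, FragmentDefinition],
                     include_incomplete: bool = False) -> list[ModuleFragment]:
    """Split a ligand into module fragments by atom name.

    Fragments missing more than half of their defined heavy atoms are
    flagged incomplete and excluded unless ``include_incomplete``.
    """
    if ligand.component_id not in defs:
        raise UnknownLigandError(f"no fragment definition for {ligand.component_id!r}")
    definition = defs[ligand.component_id]
    by_name = {_norm_atom_name(a.name): a for a in ligand.atoms
               if not a.is_hydrogen()}
    out = []
    for idx, spec in enumerate(definition.fragments):
        atoms = [by_name[_norm_atom_name(n)] for n in spec.atom_names
                 if _norm_atom_name(n) in by_name]
        if not atoms:
            continue
        complete = len(atoms) >= 0.5 * len(spec.atom_names)
        if not complete and not include_incomplete:
            continue
        out.append(ModuleFragment.from_atoms(
            spec.module_type, spec.subtype, atoms,
            provenance=f"ligand:{ligand.key}", arch_index=idx,
            branch=spec.branch, complete=complete))
    return out


def _pdb_atom_line(record: str, serial: int, name: str, resname: str,
                   chain_id: str, seqnum: int, icode: str,
                   pos: np.ndarray, occ: float, b: float, element: str) -> str:
    aname = name if len(name) >= 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:5d} {aname:<4.4s} {resname:<3s} "
            f"{chain_id:1s}{seqnum:4d}{icode or ' ':1s}   "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2s}")


def write_structure_pdb(structure: Structure, remarks: list[str] = ()) -> str:
    """Render a Structure (polymer + ligands) as PDB text."""
    lines = [f"REMARK 999 {r}" for r in remarks]
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                lines.append(_pdb_atom_line(
                    "ATOM", serial, atom.name, res.name, chain.chain_id,
                    res.seqnum, res.icode, atom.pos, 1.0, 0.0, atom.element))
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    for lig in structure.ligands:
        for atom in lig.atoms:
            lines.append(_pdb_atom_line(
                "HETATM", serial, atom.name, lig.component_id, lig.chain_id,
                lig.seqnum, lig.icode, atom.pos, 1.0, 0.0, atom.element))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_fragments_pdb(fragments: list[ModuleFragment],
                        bfactors: list[float] | None = None) -> str:
    """Render fragments as PDB HETATM blocks (B-factor column optional)."""
    lines = []
    serial = 1
    for i, frag in enumerate(fragments):
        resname = SUBTYPE_RESNAME.get(frag.subtype, "UNK")
        b = 0.0 if bfactors is None else float(bfactors[i])
        for atom in frag.atoms:
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"HETATM{serial:5d} {name:<4.4s} {resname:<3s} F{(i + 1) % 10000:4d}    "
                f"{atom.pos[0]:8.3f}{atom.pos[1]:8.3f}{atom.pos[2]:8.3f}"
                f"{1.00:6.2f}{b:6.2f}          {atom.element:>2s}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
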