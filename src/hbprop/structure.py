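"""Protein backbone structure model.

Reads PDB files into a light-weight backbone representation (N, CA, C, O
plus side-chain heavy atoms per residue), reconstructs missing amide
hydrogens geometrically, applies in-silico alanine truncation, and writes
multi-model PDB files for trajectory fixtures.

Coordinates are in Angstrom throughout.  Residues are identified by the
author (chain, residue number, insertion code) triple; no renumbering is
ever applied.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

import warnings

__all__ = [
    "STANDARD_AA",
    "BACKBONE_ATOMS",
    "ResidueRef",
    "AtomRecord",
    "Residue",
    "BackboneStructure",
    "StructureError",
    "parse_pdb_backbone",
    "place_amide_hydrogens",
    "truncate_to_alanine",
    "write_multimodel_pdb",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: amide N-H bond length used when reconstructing hydrogens, Angstrom
NH_BOND_LENGTH = 1.01


class StructureError(ValueError):
    """Raised for malformed or unusable structural input."""


@dataclass(frozen=True)
class ResidueRef:
    """Author-numbering identity of a residue.

    Equality and hashing use only (chain_id, seq_number, insertion_code);
    ``res_name`` is an annotation so that bond keys built from bare
    residue-number tables compare equal to keys built from full structures.
    """

    chain_id: str
    seq_number: int
    insertion_code: str = ""
    res_name: str = "UNK"

    def __eq__(self, other):
        if not isinstance(other, ResidueRef):
            return NotImplemented
        return (self.chain_id, self.seq_number, self.insertion_code) == (
            other.chain_id, other.seq_number, other.insertion_code)

    def __hash__(self):
        return hash((self.chain_id, self.seq_number, self.insertion_code))

    def __lt__(self, other: "ResidueRef"):
        return (self.chain_id, self.seq_number, self.insertion_code) < (
            other.chain_id, other.seq_number, other.insertion_code)

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AA

    def __str__(self) -> str:
        ic = self.insertion_code or ""
        return f"{self.res_name} {self.chain_id}{self.seq_number}{ic}"


@dataclass(frozen=True)
class AtomRecord:
    """A named atom with element and position (Angstrom)."""

    name: str
    element: str
    position: tuple[float, float, float]

    def __post_init__(self):
        if not all(np.isfinite(self.position)):
            raise StructureError(f"non-finite position for atom {self.name}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class Residue:
    """One residue: identity plus atom-name -> coordinate map."""

    ref: ResidueRef
    atoms: dict[str, np.ndarray]
    #: False for prolines and chain-initial residues (no amide H available)
    donor_capable: bool = True

    def has(self, name: str) -> bool:
        return name in self.atoms

    def coord(self, name: str) -> np.ndarray:
        try:
            return self.atoms[name]
        except KeyError:
            raise StructureError(
                f"residue {self.ref} has no atom {name!r}") from None

    @property
    def sidechain_atom_names(self) -> list[str]:
        skip = set(BACKBONE_ATOMS) | {"H", "OXT"}
        return [n for n in self.atoms if n not in skip]


@dataclass
class BackboneStructure:
    """Ordered residues of one PDB model, plus a partner-atom pool.

    ``partner_atoms`` holds heavy atoms of heteroatom groups (ligands,
    non-water HETATM records) that were excluded from the residue list;
    they serve as the binding-partner pool for interface selection.
    """

    residues: list[Residue]
    model_index: int = 1
    source_label: str = ""
    partner_atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self):
        for res in self.residues:
            for name in BACKBONE_ATOMS:
                if name not in res.atoms:
                    raise StructureError(
                        f"residue {res.ref} is missing backbone atom {name!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, ref: ResidueRef) -> Residue:
        try:
            return self._index[ref]
        except AttributeError:
            self._index = {r.ref: r for r in self.residues}
            return self._index[ref]
        except KeyError:
            raise StructureError(f"residue {ref} not in structure") from None

    def copy(self) -> "BackboneStructure":
        st = BackboneStructure(
            residues=[Residue(r.ref, {k: v.copy() for k, v in r.atoms.items()},
                              r.donor_capable) for r in self.residues],
            model_index=self.model_index,
            source_label=self.source_label,
            partner_atoms=list(self.partner_atoms),
        )
        return st


def _pick_altloc(atom):
    """Resolve a possibly-disordered Bio.PDB atom.

    Highest occupancy wins; occupancy ties are broken by altloc identifier
    ('A' before 'B'), which makes parsing deterministic.
    """
    if not atom.is_disordered():
        return atom
    children = atom.disordered_get_list()
    return sorted(children, key=lambda a: (-(a.get_occupancy() or 0.0),
                                           a.get_altloc()))[0]


def parse_pdb_backbone(pdb_text: str, model_index: int = 1,
                       source_label: str = "") -> BackboneStructure:
    """Parse one MODEL of a PDB file into a :class:`BackboneStructure`.

    Parameters
    ----------
    pdb_text : str
        Full text of a PDB file (single-model X-ray or multi-model NMR).
    model_index : int
        1-based index of the MODEL block to read.  Single-model files have
        exactly one model, index 1.

    Waters are discarded; non-water HETATM groups contribute their heavy
    atoms to ``partner_atoms``.  Alternate locations are resolved to the
    highest-occupancy conformer (ties -> altloc 'A').  A residue missing
    any of N, CA, C, O raises :class:`StructureError` naming the residue.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        bio_struct = parser.get_structure("s", io.StringIO(pdb_text))
    models = list(bio_struct.get_models())
    if not models:
        raise StructureError("no MODEL found in PDB text")
    if not (1 <= model_index <= len(models)):
        raise StructureError(
            f"model_index {model_index} out of range (file has {len(models)})")
    model = models[model_index - 1]

    residues: list[Residue] = []
    partners: list[AtomRecord] = []
    prev_chain = None
    for chain in model:
        for bio_res in chain:
            hetflag, seq, icode = bio_res.get_id()
            atoms = {}
            for atom in bio_res:
                sel = _pick_altloc(atom)
                atoms[atom.get_id()] = (sel.get_coord().astype(float),
                                        (sel.element or "").strip() or "X")
            if hetflag.strip():           # HETATM group
                if hetflag == "W":
                    continue              # waters excluded entirely
                for name, (xyz, elem) in atoms.items():
                    if elem.upper() != "H":
                        partners.append(AtomRecord(name, elem, tuple(xyz)))
                continue
            ref = ResidueRef(chain.id, seq, icode.strip(),
                             bio_res.get_resname().strip())
            for bname in BACKBONE_ATOMS:
                if bname not in atoms:
                    raise StructureError(
                        f"residue {ref} is missing backbone atom {bname!r}")
            # keep heavy atoms and the amide H only; other hydrogens are
            # irrelevant to the backbone criterion
            coords = {n: xyz for n, (xyz, elem) in atoms.items()
                      if elem.upper() != "H" or n == "H"}
            is_chain_start = chain.id != prev_chain
            prev_chain = chain.id
            donor = (ref.res_name != "PRO") and not is_chain_start
            residues.append(Residue(ref, coords, donor_capable=donor))
    if not residues:
        raise StructureError("no amino-acid residues found in PDB text")
    return BackboneStructure(residues, model_index=model_index,
                             source_label=source_label,
                             partner_atoms=partners)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise StructureError("zero-length vector in hydrogen placement")
    return v / n


def place_amide_hydrogens(structure: BackboneStructure) -> BackboneStructure:
    """Reconstruct missing backbone amide hydrogens.

    For residue i > 1 (within its chain) that is not proline and has no H,
    the hydrogen is placed 1.01 Angstrom from N along the in-plane bisector
    pointing away from the two heavy neighbours::

        H = N + 1.01 * unit( unit(N - C_prev) + unit(N - CA) )

    Existing hydrogens are left untouched.  Chain-initial residues and
    prolines receive no hydrogen and are flagged non-donor.  Returns a new
    structure; the input is not modified.
    """
    out = structure.copy()
    for i, res in enumerate(out.residues):
        first_of_chain = (i == 0 or
                          out.residues[i - 1].ref.chain_id != res.ref.chain_id)
        if first_of_chain or res.ref.res_name == "PRO":
            res.donor_capable = False
            continue
        res.donor_capable = True
        if res.has("H"):
            continue
        c_prev = out.residues[i - 1].coord("C")
        n = res.coord("N")
        ca = res.coord("CA")
        bisector = _unit(n - c_prev) + _unit(n - ca)
        norm = np.linalg.norm(bisector)
        if norm < 1e-6:
            raise StructureError(
                f"degenerate amide geometry at residue {res.ref}")
        res.atoms["H"] = n + NH_BOND_LENGTH * bisector / norm
    return out


def truncate_to_alanine(structure: BackboneStructure,
                        target: ResidueRef) -> BackboneStructure:
    """Replace the side chain of ``target`` by a methyl group (-> ALA).

    All side-chain atoms beyond CB are removed; CB keeps its original
    coordinates; the residue is renamed ALA.  Every other residue is
    untouched.  Glycine has no CB and cannot be truncated.
    """
    out = structure.copy()
    res = out.residue(target)
    if res.ref.res_name == "GLY":
        raise StructureError(
            f"cannot truncate {res.ref}: glycine has no CB atom")
    if res.ref.res_name != "ALA" and not res.has("CB"):
        raise StructureError(f"residue {res.ref} has no CB atom")
    keep = set(BACKBONE_ATOMS) | {"CB", "H", "OXT"}
    res.atoms = {n: xyz for n, xyz in res.atoms.items() if n in keep}
    res.ref = replace(res.ref, res_name="ALA")
    # invalidate any cached ref index on the copy
    out.residues = list(out.residues)
    if hasattr(out, "_index"):
        del out._index
    return out


_PDB_ATOM = ("{rec:<6}{serial:>5} {name:<4}{alt:1}{res:<3} {chain:1}"
             "{seq:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}"
             "{occ:>6.2f}{b:>6.2f}          {elem:>2}\n")


def _atom_line(serial, name, res, chain, seq, icode, xyz, elem):
    pdb_name = name if len(name) >= 4 else f" {name:<3}"
    return _PDB_ATOM.format(rec="ATOM", serial=serial, name=pdb_name, alt=" ",
                            res=res, chain=chain, seq=seq, icode=icode or " ",
                            x=xyz[0], y=xyz[1], z=xyz[2], occ=1.00, b=0.00,
                            elem=elem)


def write_multimodel_pdb(frames: list[BackboneStructure]) -> str:
    """Serialize structures as a multi-model PDB string (wwPDB v3.3 layout).

    All frames must share residue topology; each becomes one MODEL block.
    Coordinates survive a round trip through :func:`parse_pdb_backbone`
    within the 1e-3 Angstrom precision of the PDB fixed-width format.
    """
    if not frames:
        raise StructureError("cannot write a PDB with zero frames")
    ref_refs = [r.ref for r in frames[0].residues]
    lines: list[str] = []
    for m, frame in enumerate(frames, start=1):
        if [r.ref for r in frame.residues] != ref_refs:
            raise StructureError("frames do not share residue topology")
        lines.append(f"MODEL     {m:>4}\n")
        serial = 0
        for res in frame.residues:
            order = [n for n in ("N", "H", "CA", "C", "O") if res.has(n)]
            order += sorted(res.sidechain_atom_names)
            for name in order:
                serial += 1
                elem = "H" if name == "H" else name[0]
                lines.append(_atom_line(serial, name, res.ref.res_name,
                                        res.ref.chain_id, res.ref.seq_number,
                                        res.ref.insertion_code,
                                        res.coord(name), elem))
        lines.append("ENDMDL\n")
    lines.append("END\n")
    return "".join(lines)
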