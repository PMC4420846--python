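"""Readers for receptor conformations and docked ligand poses.

Receptors arrive as single-model PDB files (one file per conformation of a
fixed-sequence receptor); poses arrive as SDF (V2000) or MOL2 files with
explicit bonds. Both are mapped onto a small internal model — :class:`Atom`,
:class:`Residue`, :class:`ReceptorConformation`, :class:`LigandPose` — that
carries exactly the annotation the interaction-fingerprint predicates need:
main-chain/side-chain role, polarity, hydrophobicity, hydrogen-bond
donor/acceptor capability, aromaticity and formal charge.

Hydrogens are accepted when present but nothing downstream requires them:
donor capability is inferred from heavy-atom identity (receptor) or implicit
valence (ligand) so that poses stripped of hydrogens remain usable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ReceptorConformation",
    "LigandPose",
    "read_receptor",
    "read_pose",
    "read_pose_manifest",
    "assemble_ensemble",
    "validate_ensemble",
    "write_receptor_pdb",
    "write_pose_sdf",
]


class ComplexIOError(ValueError):
    """Raised for unreadable or structurally invalid receptor/pose input."""


# ---------------------------------------------------------------------------
# internal data model
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) float, ångströms
    is_main_chain: bool = False
    is_polar: bool = False
    is_hydrophobic: bool = False
    is_donor: bool = False
    is_acceptor: bool = False
    is_aromatic: bool = False
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ComplexIOError(f"atom {self.name!r}: coords must be a 3-vector")
        if self.is_donor and self.element not in {"N", "O", "S"}:
            raise ComplexIOError(f"atom {self.name!r}: donors must be N/O/S")
        if self.is_acceptor and self.element not in {"N", "O", "S", "F"}:
            raise ComplexIOError(f"atom {self.name!r}: acceptors must be N/O/S/F")


@dataclass
class Residue:
    chain: str
    resnum: int
    resname: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.resname)

    @property
    def label(self) -> str:
        return f"{self.chain}{self.resnum}"

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]


@dataclass
class ReceptorConformation:
    conformation_id: str
    residues: list[Residue]
    source_path: str = ""

    def residue_keys(self) -> tuple[tuple[str, int, str], ...]:
        return tuple(r.key for r in self.residues)

    @property
    def n_residues(self) -> int:
        return len(self.residues)


@dataclass
class LigandPose:
    compound_id: str
    conformation_id: str
    atoms: list[Atom]
    ring_systems: list[frozenset[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not any(a.element != "H" for a in self.atoms):
            raise ComplexIOError(
                f"pose {self.compound_id}/{self.conformation_id}: no heavy atoms"
            )
        for ring in self.ring_systems:
            if not all(self.atoms[i].is_aromatic for i in ring):
                raise ComplexIOError("ring_systems may only contain aromatic atoms")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]


# ---------------------------------------------------------------------------
# receptor-side chemistry tables (standard amino-acid topology)
# ---------------------------------------------------------------------------

MAIN_CHAIN_ATOMS = {"N", "CA", "C", "O", "OXT"}
_MAIN_CHAIN_H = {"H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT"}

# side-chain H-bond donors / acceptors by (resname, atom name); the backbone
# amide N donates and the carbonyl O accepts for every residue type.
_SIDE_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("TRP", "NE1"), ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
}
_SIDE_ACCEPTORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}
# physiological-pH formal charges on side-chain termini
_SIDE_CHARGES = {
    ("ASP", "OD2"): -1, ("GLU", "OE2"): -1,
    ("LYS", "NZ"): +1, ("ARG", "NH2"): +1,
}
# aromatic ring atoms per residue type; TRP carries two fused rings
RESIDUE_AROMATIC_RINGS: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
}
# carbons covalently bonded to N or O in the standard topology: excluded from
# the hydrophobic class ("C or S with no bonded N/O"). CA and carbonyl C are
# excluded for every residue.
_POLAR_BONDED_CARBONS = {
    ("SER", "CB"), ("THR", "CB"),
    ("ASN", "CG"), ("ASP", "CG"),
    ("GLN", "CD"), ("GLU", "CD"),
    ("ARG", "CD"), ("ARG", "CZ"), ("LYS", "CE"), ("PRO", "CD"),
    ("HIS", "CG"), ("HIS", "CD2"), ("HIS", "CE1"),
    ("TRP", "CD1"), ("TRP", "CE2"), ("TYR", "CZ"),
}

_STANDARD_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _annotate_receptor_atom(resname: str, name: str, element: str,
                            coords: np.ndarray) -> Atom:
    element = element.capitalize() if len(element) > 1 else element.upper()
    is_mc = name in MAIN_CHAIN_ATOMS or name in _MAIN_CHAIN_H
    is_polar = element in {"N", "O", "S"}
    is_aromatic = any(
        name in ring for ring in RESIDUE_AROMATIC_RINGS.get(resname, [])
    )
    is_donor = (name == "N" and resname != "PRO") or (resname, name) in _SIDE_DONORS
    is_acceptor = name in {"O", "OXT"} or (resname, name) in _SIDE_ACCEPTORS
    if element == "C":
        is_hydrophobic = name not in {"C", "CA"} and \
            (resname, name) not in _POLAR_BONDED_CARBONS
    elif element == "S":
        is_hydrophobic = True  # SG/SD: bonded to C only
    else:
        is_hydrophobic = False
    return Atom(
        name=name, element=element, coords=coords,
        is_main_chain=is_mc, is_polar=is_polar,
        is_hydrophobic=is_hydrophobic,
        is_donor=is_donor and element in {"N", "O", "S"},
        is_acceptor=is_acceptor,
        is_aromatic=is_aromatic,
        formal_charge=_SIDE_CHARGES.get((resname, name), 0),
    )


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_receptor(path: str | Path) -> ReceptorConformation:
    """Read one receptor conformation from a single-model PDB file.

    Waters and hetero groups are excluded; residues are ordered by
    (chain, resnum); alternate locations resolve to the highest-occupancy
    conformer (ties to altloc 'A'); insertion codes are rejected.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure(path.stem, str(path))
        except Exception as exc:  # unreadable / malformed
            raise ComplexIOError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise ComplexIOError(f"{path}: no models in file")
    model = models[0]

    residues: list[Residue] = []
    seen: dict[tuple[str, int], str] = {}
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag != " ":
                continue  # waters and HETATM ligands
            if icode.strip():
                raise ComplexIOError(
                    f"{path}: insertion code {icode!r} at {chain.id}{resseq} unsupported"
                )
            key = (chain.id, resseq)
            if key in seen and seen[key] != res.resname:
                raise ComplexIOError(
                    f"{path}: duplicate residue {chain.id}{resseq} with "
                    f"conflicting names {seen[key]}/{res.resname}"
                )
            seen[key] = res.resname
            atoms = _collect_atoms(res)
            residues.append(Residue(chain.id, resseq, res.resname, atoms))

    if not residues:
        raise ComplexIOError(f"{path}: no protein residues (zero ATOM records?)")

    residues.sort(key=lambda r: (r.chain, r.resnum))
    return ReceptorConformation(
        conformation_id=path.stem, residues=residues, source_path=str(path)
    )


def _collect_atoms(res) -> list[Atom]:
    atoms = []
    for atom in res:
        if atom.is_disordered():
            children = sorted(
                atom.disordered_get_list(),
                key=lambda a: (-a.get_occupancy(), a.get_altloc()),
            )
            atom = children[0]
        element = (atom.element or atom.get_name()[0]).strip()
        atoms.append(
            _annotate_receptor_atom(
                res.resname, atom.get_name(), element, np.asarray(atom.coord)
            )
        )
    return atoms


def write_receptor_pdb(conf: ReceptorConformation, path: str | Path) -> None:
    """Write a conformation back to PDB (ATOM records only)."""
    lines = []
    serial = 1
    for res in conf.residues:
        for a in res.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {name:<4.4s} {res.resname:<3.3s} "
                f"{res.chain:1.1s}{res.resnum:>4d}    "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ligand pose reading (RDKit)
# ---------------------------------------------------------------------------

def _annotate_ligand(mol, compound_id: str, conformation_id: str) -> LigandPose:
    from rdkit import Chem

    if mol.GetNumConformers() == 0:
        raise ComplexIOError(f"pose {compound_id}: no 3D coordinates")
    conf = mol.GetConformer()
    atoms: list[Atom] = []
    for rd_atom in mol.GetAtoms():
        idx = rd_atom.GetIdx()
        pos = conf.GetAtomPosition(idx)
        element = rd_atom.GetSymbol()
        charge = rd_atom.GetFormalCharge()
        nbr_elems = {n.GetSymbol() for n in rd_atom.GetNeighbors()}
        polar = element in {"N", "O", "S"}
        hydrophobic = element in {"C", "S"} and not ({"N", "O"} & nbr_elems)
        n_h = rd_atom.GetTotalNumHs(includeNeighbors=True)
        donor = polar and n_h >= 1 and charge >= 0
        if element == "O":
            acceptor = charge <= 0
        elif element == "N":
            # pyrrole-type aromatic N-H has no available lone pair
            acceptor = charge <= 0 and not (rd_atom.GetIsAromatic() and n_h > 0)
        elif element == "S":
            acceptor = charge <= 0 and rd_atom.GetDegree() <= 2
        elif element == "F":
            acceptor = True
        else:
            acceptor = False
        atoms.append(
            Atom(
                name=f"{element}{idx + 1}", element=element,
                coords=np.array([pos.x, pos.y, pos.z]),
                is_main_chain=False, is_polar=polar,
                is_hydrophobic=hydrophobic,
                is_donor=donor and element in {"N", "O", "S"},
                is_acceptor=acceptor and element in {"N", "O", "S", "F"},
                is_aromatic=rd_atom.GetIsAromatic(),
                formal_charge=charge,
            )
        )
    rings = []
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            rings.append(frozenset(ring))
    return LigandPose(compound_id, conformation_id, atoms, rings)


def read_pose(path: str | Path, compound_id: str,
              conformation_id: str) -> LigandPose:
    """Read one docked pose from an SDF (V2000) or MOL2 file."""
    from rdkit import Chem

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".sdf", ".sd", ".mol"}:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        mol = next(iter(supplier), None)
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=True)
    else:
        raise ComplexIOError(f"unsupported pose format: {path.suffix}")
    if mol is None or mol.GetNumAtoms() == 0:
        raise ComplexIOError(f"cannot parse pose file {path}")
    return _annotate_ligand(mol, compound_id, conformation_id)


def read_pose_manifest(path: str | Path) -> list[LigandPose]:
    """Read poses listed in a manifest TSV with columns
    ``compound_id  conformation_id  path`` (paths relative to the manifest)."""
    import csv

    path = Path(path)
    poses = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"compound_id", "conformation_id", "path"}
        if not required <= set(reader.fieldnames or []):
            raise ComplexIOError(f"manifest {path} must have columns {sorted(required)}")
        for row in reader:
            pose_path = Path(row["path"])
            if not pose_path.is_absolute():
                pose_path = path.parent / pose_path
            poses.append(
                read_pose(pose_path, row["compound_id"], row["conformation_id"])
            )
    return poses


def write_pose_sdf(pose: LigandPose, path: str | Path) -> None:
    """Write a toy pose as minimal V2000 SDF.

    Only ring bonds are emitted (kekulized alternation for even rings); other
    atoms are written unbonded. Intended for synthetic complexes — re-reading
    infers chemistry from this file, not from the original flags.
    """
    lines = [pose.compound_id, "  ensift", ""]
    bonds: list[tuple[int, int, int]] = []
    for ring in pose.ring_systems:
        members = sorted(ring)
        m = len(members)
        for j in range(m):
            a, b = members[j], members[(j + 1) % m]
            order = 2 if j % 2 == 0 and m % 2 == 0 else 1
            bonds.append((a + 1, b + 1, order))
    lines.append(f"{len(pose.atoms):>3d}{len(bonds):>3d}  0  0  0  0  0  0  0  0999 V2000")
    for a in pose.atoms:
        x, y, z = a.coords
        lines.append(f"{x:>10.4f}{y:>10.4f}{z:>10.4f} {a.element:<3.3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, order in bonds:
        lines.append(f"{i:>3d}{j:>3d}{order:>3d}  0  0  0  0")
    charged = [(i + 1, a.formal_charge) for i, a in enumerate(pose.atoms)
               if a.formal_charge != 0]
    for i, chg in charged:
        lines.append(f"M  CHG  1{i:>4d}{chg:>4d}")
    lines.append("M  END")
    lines.append("$$$$")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def validate_ensemble(
    conformations: Sequence[ReceptorConformation],
) -> list[ReceptorConformation]:
    """Check that all conformations share one (chain, resnum, resname) sequence."""
    if not conformations:
        raise ComplexIOError("empty ensemble")
    reference = conformations[0].residue_keys()
    for conf in conformations[1:]:
        if conf.residue_keys() != reference:
            raise ComplexIOError(
                f"conformation {conf.conformation_id!r} residue sequence differs "
                f"from {conformations[0].conformation_id!r}"
            )
    return list(conformations)


def assemble_ensemble(paths: Iterable[str | Path]) -> list[ReceptorConformation]:
    """Read receptor conformations and verify they form a valid ensemble.

    The input order is preserved: it defines the one-by-one addition order
    used by the ensemble-size sweep.
    """
    paths = list(paths)
    if not paths:
        raise ComplexIOError("assemble_ensemble requires at least one path")
    return validate_ensemble([read_receptor(p) for p in paths])
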