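"""Structural Interaction Fingerprints (SIFt).

A SIFt encodes one ligand pose against one receptor conformation as a binary
string of nine bits per residue, in residue order:

    any, main_chain, side_chain, polar, hydrophobic,
    hb_acceptor, hb_donor, aromatic, charged

``hb_donor`` means the *residue* donates the hydrogen bond and
``hb_acceptor`` that the residue accepts — the convention of the original
interaction-fingerprint literature. The source describing the nine classes
names no geometric cutoffs; the defaults in :class:`GeometryConfig` follow
common interaction-fingerprint practice and are this implementation's
documented choice (see docs/methods.md). All are configurable.

Semantics: each interaction class fires on heavy-atom geometry alone (with
an optional donor-H angle term when explicit hydrogens are present). The
``any`` bit is the OR over every detected interaction, and ``main_chain`` /
``side_chain`` partition the residue atoms contributing to any detected
interaction, so the chunk invariants (any = OR; any ⇒ main ∨ side;
hb ⇒ polar) hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from .complex_io import (
    Atom,
    LigandPose,
    ReceptorConformation,
    Residue,
    RESIDUE_AROMATIC_RINGS,
)

__all__ = [
    "BIT_NAMES",
    "BITS_PER_RESIDUE",
    "GeometryConfig",
    "InteractionBits",
    "Sift",
    "residue_bits",
    "compute_sift",
    "write_sifts",
    "read_sifts",
    "rle_encode",
    "rle_decode",
]

BIT_NAMES = (
    "any", "main_chain", "side_chain", "polar", "hydrophobic",
    "hb_acceptor", "hb_donor", "aromatic", "charged",
)
BITS_PER_RESIDUE = 9

_COVALENT_H_CUTOFF = 1.3  # Å: hydrogen belongs to the nearest heavy atom


@dataclass(frozen=True)
class GeometryConfig:
    """Distance/angle cutoffs for the nine interaction classes (ångströms,
    degrees)."""

    contact_cutoff: float = 4.5
    hbond_dist: float = 3.5
    hbond_angle_min: float = 120.0
    hydrophobic_cutoff: float = 4.5
    aromatic_centroid_cutoff: float = 5.0
    charged_cutoff: float = 4.0
    polar_cutoff: float = 3.5

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if self.hbond_dist > self.contact_cutoff:
            raise ValueError("hbond_dist must not exceed contact_cutoff")

    @classmethod
    def from_file(cls, path: str | Path) -> "GeometryConfig":
        """Load from a flat ``key = value`` config file ('#' comments)."""
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in valid:
                raise ValueError(f"unknown geometry key {key!r}")
            kwargs[key] = float(value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{f.name} = {getattr(self, f.name)}\n" for f in fields(self))
        )


@dataclass
class InteractionBits:
    """One residue's nine-bit interaction chunk."""

    any: bool = False
    main_chain: bool = False
    side_chain: bool = False
    polar: bool = False
    hydrophobic: bool = False
    hb_acceptor: bool = False
    hb_donor: bool = False
    aromatic: bool = False
    charged: bool = False

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in BIT_NAMES], dtype=np.uint8)

    @classmethod
    def from_array(cls, bits: np.ndarray) -> "InteractionBits":
        if len(bits) != BITS_PER_RESIDUE:
            raise ValueError("chunk must have exactly 9 bits")
        return cls(**{n: bool(b) for n, b in zip(BIT_NAMES, bits)})


@dataclass
class Sift:
    """Binary interaction string for one (compound, conformation) pair."""

    compound_id: str
    conformation_id: str
    bits: np.ndarray  # uint8, length 9 × n_residues, residue-major

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1 or len(self.bits) % BITS_PER_RESIDUE:
            raise ValueError("SIFt length must be a multiple of 9")

    @property
    def n_residues(self) -> int:
        return len(self.bits) // BITS_PER_RESIDUE

    def chunk(self, residue_index: int) -> InteractionBits:
        lo = residue_index * BITS_PER_RESIDUE
        return InteractionBits.from_array(self.bits[lo:lo + BITS_PER_RESIDUE])


# ---------------------------------------------------------------------------
# geometric predicates
# ---------------------------------------------------------------------------

def _hydrogens_on(atoms: list[Atom], donor: Atom) -> list[Atom]:
    out = []
    for a in atoms:
        if a.element == "H" and np.linalg.norm(a.coords - donor.coords) <= _COVALENT_H_CUTOFF:
            out.append(a)
    return out


def _hbond_geometry_ok(donor: Atom, acceptor: Atom, donor_hs: list[Atom],
                       cfg: GeometryConfig) -> bool:
    """Distance is checked by the caller; here: optional D–H…A angle term.

    Without explicit hydrogens on the donor the check is distance-only.
    """
    if not donor_hs:
        return True
    for h in donor_hs:
        dh = donor.coords - h.coords
        ah = acceptor.coords - h.coords
        denom = np.linalg.norm(dh) * np.linalg.norm(ah)
        if denom == 0:
            continue
        angle = np.degrees(np.arccos(np.clip(np.dot(dh, ah) / denom, -1.0, 1.0)))
        if angle >= cfg.hbond_angle_min:
            return True
    return False


def _residue_rings(residue: Residue) -> list[np.ndarray]:
    """Centroids of the residue's aromatic rings, when all ring atoms exist."""
    centroids = []
    by_name = {a.name: a for a in residue.atoms}
    for ring in RESIDUE_AROMATIC_RINGS.get(residue.resname, []):
        if all(name in by_name for name in ring):
            centroids.append(
                np.mean([by_name[n].coords for n in ring], axis=0)
            )
    return centroids


def residue_bits(residue: Residue, ligand: LigandPose,
                 cfg: GeometryConfig | None = None) -> InteractionBits:
    """Evaluate the nine interaction classes for one residue vs. one pose."""
    cfg = cfg or GeometryConfig()
    r_atoms = residue.heavy_atoms()
    l_atoms = ligand.heavy_atoms()
    if not r_atoms or not l_atoms:
        return InteractionBits()

    r_xyz = np.array([a.coords for a in r_atoms])
    l_xyz = np.array([a.coords for a in l_atoms])
    dist = np.linalg.norm(r_xyz[:, None, :] - l_xyz[None, :, :], axis=-1)

    bits = InteractionBits()
    contributors: set[int] = set()  # indices into r_atoms

    contact_pairs = np.argwhere(dist <= cfg.contact_cutoff)
    contributors.update(int(i) for i, _ in contact_pairs)

    for i, j in np.argwhere(dist <= cfg.polar_cutoff):
        if r_atoms[i].is_polar and l_atoms[j].is_polar:
            bits.polar = True
            contributors.add(int(i))

    for i, j in np.argwhere(dist <= cfg.hydrophobic_cutoff):
        if r_atoms[i].is_hydrophobic and l_atoms[j].is_hydrophobic:
            bits.hydrophobic = True
            contributors.add(int(i))

    for i, j in np.argwhere(dist <= cfg.hbond_dist):
        ra, la = r_atoms[i], l_atoms[j]
        if ra.is_donor and la.is_acceptor and _hbond_geometry_ok(
            ra, la, _hydrogens_on(residue.atoms, ra), cfg
        ):
            bits.hb_donor = True
            bits.polar = True  # an H-bond is a polar interaction by definition
            contributors.add(int(i))
        if ra.is_acceptor and la.is_donor and _hbond_geometry_ok(
            la, ra, _hydrogens_on(ligand.atoms, la), cfg
        ):
            bits.hb_acceptor = True
            bits.polar = True
            contributors.add(int(i))

    for i, j in np.argwhere(dist <= cfg.charged_cutoff):
        if r_atoms[i].formal_charge * l_atoms[j].formal_charge < 0:
            bits.charged = True
            contributors.add(int(i))

    ring_names = {
        name for ring in RESIDUE_AROMATIC_RINGS.get(residue.resname, [])
        for name in ring
    }
    for r_centroid in _residue_rings(residue):
        for ring in ligand.ring_systems:
            l_centroid = np.mean([ligand.atoms[k].coords for k in ring], axis=0)
            if np.linalg.norm(r_centroid - l_centroid) <= cfg.aromatic_centroid_cutoff:
                bits.aromatic = True
                contributors.update(
                    i for i, a in enumerate(r_atoms) if a.name in ring_names
                )

    # every detected interaction registered its residue atoms above, so the
    # "any" bit is exactly "some residue atom contributed"
    bits.any = bool(contributors)
    if bits.any:
        bits.main_chain = any(r_atoms[i].is_main_chain for i in contributors)
        bits.side_chain = any(not r_atoms[i].is_main_chain for i in contributors)
    return bits


def compute_sift(receptor: ReceptorConformation, pose: LigandPose,
                 cfg: GeometryConfig | None = None) -> Sift:
    """Concatenate per-residue nine-bit chunks in receptor residue order."""
    cfg = cfg or GeometryConfig()
    chunks = [residue_bits(res, pose, cfg).to_array() for res in receptor.residues]
    return Sift(
        compound_id=pose.compound_id,
        conformation_id=pose.conformation_id,
        bits=np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.uint8),
    )


# ---------------------------------------------------------------------------
# fingerprint I/O
# ---------------------------------------------------------------------------

def bit_column_names(residue_labels: list[str]) -> list[str]:
    return [f"{lab}_{bit}" for lab in residue_labels for bit in BIT_NAMES]


def _default_labels(n_residues: int) -> list[str]:
    return [f"R{i + 1}" for i in range(n_residues)]


def write_sifts(sifts: list[Sift], path: str | Path,
                residue_labels: list[str] | None = None) -> None:
    """Write fingerprints as TSV: compound_id, conformation_id, one 0/1
    column per bit headed ``<residue>_<bitname>``."""
    import pandas as pd

    if not sifts:
        raise ValueError("no fingerprints to write")
    n_res = sifts[0].n_residues
    labels = residue_labels or _default_labels(n_res)
    if len(labels) != n_res:
        raise ValueError("residue_labels length mismatch")
    frame = pd.DataFrame(
        np.stack([s.bits for s in sifts]), columns=bit_column_names(labels)
    )
    frame.insert(0, "conformation_id", [s.conformation_id for s in sifts])
    frame.insert(0, "compound_id", [s.compound_id for s in sifts])
    frame.to_csv(path, sep="\t", index=False)


def read_sifts(path: str | Path) -> list[Sift]:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype={"compound_id": str,
                                               "conformation_id": str})
    bit_cols = [c for c in frame.columns if c not in ("compound_id", "conformation_id")]
    return [
        Sift(row["compound_id"], row["conformation_id"],
             row[bit_cols].to_numpy(dtype=np.uint8))
        for _, row in frame.iterrows()
    ]


def rle_encode(bits: np.ndarray) -> str:
    """Compact run-length text form, e.g. ``0x24,1x3,0x9`` for sparse SIFts."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size == 0:
        return ""
    boundaries = np.flatnonzero(np.diff(bits)) + 1
    runs = np.split(bits, boundaries)
    return ",".join(f"{run[0]}x{len(run)}" for run in runs)


def rle_decode(text: str) -> np.ndarray:
    if not text:
        return np.zeros(0, dtype=np.uint8)
    parts = []
    for token in text.split(","):
        value, _, count = token.partition("x")
        parts.append(np.full(int(count), int(value), dtype=np.uint8))
    return np.concatenate(parts)
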