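"""Synthetic complexes and fingerprint datasets for the screening pipeline.

Two generators stand in for docking output:

* :func:`make_toy_complex` places receptor and ligand atoms at known
  geometries so that exactly a requested set of interaction classes fires
  under the default cutoffs — the ground truth for fingerprint geometry
  tests.

* :func:`simulate_fingerprints` draws multi-conformation binary SIFt
  datasets directly. Actives share a conserved interaction pattern whose
  signal bits are flipped independently per conformation with probability
  ``flip_prob``; all remaining bit positions (and every position of
  inactives and decoys) are background noise at rate ``background_rate``;
  whole (compound, conformation) fingerprints drop out with
  ``pose_fail_prob``, modelling docking failures. Averaging over
  conformations therefore denoises the conserved pattern — the mechanism by
  which larger receptor ensembles are expected to help classification. A
  noise-correlation knob ρ shares flip draws across conformations,
  emulating the restricted conformational diversity of a crystal-structure
  ensemble: at ρ = 1 every conformation repeats the same error and
  averaging recovers nothing.

Default sizes follow the retrospective-screening data shape (550 active
and 601 inactive instances, ~2500 decoys, 20 conformations); tests use
reduced counts documented per test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .complex_io import Atom, LigandPose, ReceptorConformation, Residue
from .sift_core import BITS_PER_RESIDUE, Sift

__all__ = [
    "FingerprintSimConfig",
    "make_toy_complex",
    "make_receptor_conformers",
    "simulate_fingerprints",
    "simulate_centroid_scores",
]

# bit indices within a chunk
_ANY, _MAIN, _SIDE = 0, 1, 2
_PAYLOAD = slice(1, 9)  # all bits except "any" are drawable contacts


@dataclass(frozen=True)
class FingerprintSimConfig:
    """Study-shaped defaults for the fingerprint-level simulator.

    ``n_signal_bits`` conserved positions (drawn among the six
    interaction-class bits, never any/main/side) are set for every active;
    ``flip_prob`` is the per-conformation Bernoulli flip on those positions;
    ``background_rate`` the density of random contacts elsewhere;
    ``noise_correlation`` ∈ [0,1] shares flip/background draws across
    conformations ("crystal-like" mode).
    """

    n_active: int = 550
    n_inactive: int = 601
    n_decoy: int = 2526
    n_conformations: int = 20
    n_residues: int = 24
    n_signal_bits: int = 3
    flip_prob: float = 0.3
    background_rate: float = 0.05
    pose_fail_prob: float = 0.1
    noise_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.flip_prob < 1):
            raise ValueError("flip_prob must be in [0, 1)")
        if not (0 <= self.background_rate < 1):
            raise ValueError("background_rate must be in [0, 1)")
        if not (0 <= self.pose_fail_prob < 1):
            raise ValueError("pose_fail_prob must be in [0, 1)")
        if not (0 <= self.noise_correlation <= 1):
            raise ValueError("noise_correlation must be in [0, 1]")
        if self.n_signal_bits > 6 * self.n_residues:
            raise ValueError("n_signal_bits exceeds available interaction bits")
        if min(self.n_active, self.n_conformations, self.n_residues) < 1:
            raise ValueError("counts must be positive")

    def with_(self, **kwargs) -> "FingerprintSimConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "FingerprintSimConfig":
        kwargs = {}
        valid = {f.name: f.type for f in fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in valid:
                raise ValueError(f"unknown simulation key {key!r}")
            cast = float if "float" in str(valid[key]) else int
            kwargs[key] = cast(value)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# toy 3D complexes
# ---------------------------------------------------------------------------

_RESIDUE_SPACING = 20.0  # Å between residue anchors: beyond every cutoff
_FAR = 60.0              # parking offset for the "nothing here" direction

#: interaction classes plantable per residue
PLANTABLE = ("any_main", "any_side", "polar", "hydrophobic",
             "hb_donor", "hb_acceptor", "aromatic", "charged")

#: the exact chunk bits each planted class produces under default cutoffs
_CLASS_BITS = {
    "any_main": ("any", "main_chain"),
    "any_side": ("any", "side_chain"),
    "polar": ("any", "main_chain", "polar"),
    "hydrophobic": ("any", "side_chain", "hydrophobic"),
    "hb_donor": ("any", "main_chain", "polar", "hb_donor"),
    "hb_acceptor": ("any", "main_chain", "polar", "hb_acceptor"),
    "aromatic": ("any", "side_chain", "aromatic"),
    "charged": ("any", "side_chain", "charged"),
}


def expected_bits(classes: Sequence[str]):
    """The InteractionBits a plan entry should produce under defaults."""
    from .sift_core import InteractionBits

    names = {bit for cls in classes for bit in _CLASS_BITS[cls]}
    return InteractionBits(**{n: True for n in names})


def _backbone(origin: np.ndarray, resname: str) -> list[Atom]:
    from .complex_io import _annotate_receptor_atom as ann

    return [
        ann(resname, "N", "N", origin + [0.0, 0.0, 0.0]),
        ann(resname, "CA", "C", origin + [1.46, 0.0, 0.0]),
        ann(resname, "C", "C", origin + [2.0, 1.4, 0.0]),
        ann(resname, "O", "O", origin + [3.2, 1.6, 0.0]),
    ]


def _toy_residue(index: int, resname: str) -> Residue:
    from .complex_io import _annotate_receptor_atom as ann

    origin = np.array([index * _RESIDUE_SPACING, 0.0, 0.0])
    atoms = _backbone(origin, resname)
    side = origin + [1.46, -1.5, 0.0]
    if resname == "ALA":
        atoms.append(ann(resname, "CB", "C", side))
    elif resname == "LEU":
        atoms += [ann(resname, "CB", "C", side),
                  ann(resname, "CG", "C", side + [0.0, -1.5, 0.0]),
                  ann(resname, "CD1", "C", side + [-1.2, -2.3, 0.0]),
                  ann(resname, "CD2", "C", side + [1.2, -2.3, 0.0])]
    elif resname == "SER":
        atoms += [ann(resname, "CB", "C", side),
                  ann(resname, "OG", "O", side + [0.0, -1.4, 0.0])]
    elif resname == "ASP":
        atoms += [ann(resname, "CB", "C", side),
                  ann(resname, "CG", "C", side + [0.0, -1.5, 0.0]),
                  ann(resname, "OD1", "O", side + [-1.1, -2.2, 0.0]),
                  ann(resname, "OD2", "O", side + [1.1, -2.2, 0.0])]
    elif resname == "PHE":
        ring_center = side + [0.0, -2.6, 0.0]
        names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        angles = (90.0, 150.0, 30.0, 210.0, -30.0, 270.0)
        atoms.append(ann(resname, "CB", "C", side))
        for name, deg in zip(names, angles):
            rad = np.radians(deg)
            atoms.append(ann(
                resname, name, "C",
                ring_center + 1.39 * np.array([np.cos(rad), np.sin(rad), 0.0]),
            ))
    else:
        raise ValueError(f"no toy template for residue {resname!r}")
    return Residue("A", index + 1, resname, atoms)


def _ligand_atom(element: str, coords: np.ndarray, *, donor=False,
                 acceptor=False, aromatic=False, charge=0,
                 hydrophobic=False) -> Atom:
    return Atom(
        name=element, element=element, coords=coords,
        is_polar=element in {"N", "O", "S"},
        is_hydrophobic=hydrophobic,
        is_donor=donor, is_acceptor=acceptor,
        is_aromatic=aromatic, formal_charge=charge,
    )


def make_toy_complex(
    plan: Mapping[int, Sequence[str]],
    n_residues: int = 3,
    compound_id: str = "toy",
    conformation_id: str = "conf1",
    seed: int = 0,
) -> tuple[ReceptorConformation, LigandPose]:
    """Build a receptor/ligand pair realizing a planted interaction plan.

    ``plan`` maps 0-based residue indices to interaction classes from
    :data:`PLANTABLE`. Residues are spaced 20 Å apart so classes fire only
    where requested; ligand atoms sit at textbook geometries (H-bond pair at
    2.9 Å, hydrophobic pair at 4.0 Å, ring stack at 3.8 Å, salt bridge at
    3.5 Å). Unreferenced ligand mass is parked 60 Å away. The seed only
    perturbs parked-atom placement; planted geometry is deterministic.
    """
    for idx, wanted in plan.items():
        if not 0 <= idx < n_residues:
            raise ValueError(f"residue index {idx} outside 0..{n_residues - 1}")
        unknown = set(wanted) - set(PLANTABLE)
        if unknown:
            raise ValueError(f"unplantable interaction classes: {sorted(unknown)}")

    def resname_for(wanted: Sequence[str]) -> str:
        if "aromatic" in wanted:
            return "PHE"
        if "charged" in wanted:
            return "ASP"
        if "hydrophobic" in wanted:
            return "LEU"
        return "ALA"

    residues = [
        _toy_residue(i, resname_for(plan.get(i, ()))) for i in range(n_residues)
    ]
    for idx in sorted(plan):
        # a plan combining aromatic and charged exceeds any one standard
        # side chain: graft an anionic oxygen onto the PHE toy residue
        if {"aromatic", "charged"} <= set(plan[idx]):
            res = residues[idx]
            cb = next(a for a in res.atoms if a.name == "CB")
            res.atoms.append(Atom(
                name="OD2", element="O", coords=cb.coords + [2.5, -1.0, 0.0],
                is_polar=True, formal_charge=-1,
            ))

    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    rings: list[frozenset[int]] = []
    for idx in sorted(plan):
        wanted = set(plan[idx])
        res = residues[idx]
        by_name = {a.name: a for a in res.atoms}
        if "any_main" in wanted:
            # non-polar, non-hydrophobic ligand C 4.0 Å above CA: bare contact
            atoms.append(_ligand_atom("C", by_name["CA"].coords + [0.0, 4.0, 0.0]))
        if "any_side" in wanted:
            # polar ligand N off CB, > 4.5 Å from every backbone atom
            atoms.append(_ligand_atom("N", by_name["CB"].coords + [0.0, -1.5, 4.0]))
        if "polar" in wanted:
            # non-donor non-acceptor polar N vs backbone O at 3.2 Å
            atoms.append(_ligand_atom("N", by_name["O"].coords + [0.0, 3.2, 0.0]))
        if "hydrophobic" in wanted:
            target = "CD1" if "CD1" in by_name else "CB"
            offset = [0.0, -4.0, 0.0] if target == "CD1" else [0.0, -1.0, 4.2]
            atoms.append(_ligand_atom(
                "C", by_name[target].coords + offset, hydrophobic=True
            ))
        if "hb_donor" in wanted:
            # residue backbone N donates to a ligand carbonyl-like O at 2.9 Å
            atoms.append(_ligand_atom(
                "O", by_name["N"].coords + [0.0, 2.9, 0.0], acceptor=True
            ))
        if "hb_acceptor" in wanted:
            # residue backbone O accepts from a ligand hydroxyl-like O
            atoms.append(_ligand_atom(
                "O", by_name["O"].coords + [0.0, 2.9, 0.0], donor=True, acceptor=True
            ))
        if "charged" in wanted:
            # quaternary-ammonium-like N⁺ (no donatable H) at 3.8 Å: inside
            # the charged cutoff, outside the polar/H-bond cutoffs
            atoms.append(_ligand_atom(
                "N", by_name["OD2"].coords + [0.0, -3.8, 0.0], charge=+1,
            ))
        if "aromatic" in wanted:
            ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
            centroid = np.mean([by_name[n].coords for n in ring_names], axis=0)
            start = len(atoms)
            for deg in (90.0, 150.0, 30.0, 210.0, -30.0, 270.0):
                rad = np.radians(deg)
                offset = 1.39 * np.array([np.cos(rad), np.sin(rad), 0.0])
                atoms.append(_ligand_atom(
                    "C", centroid + [0.0, 0.0, 3.8] + offset, aromatic=True
                ))
            rings.append(frozenset(range(start, start + 6)))

    if not atoms:  # empty plan still needs one heavy atom, parked far away
        atoms.append(_ligand_atom(
            "C", np.array([-_FAR, _FAR, _FAR]) + rng.normal(0, 0.5, 3)
        ))
    pose = LigandPose(compound_id, conformation_id, atoms, rings)
    receptor = ReceptorConformation("toy_receptor", residues, source_path="")
    return receptor, pose


def make_receptor_conformers(base: ReceptorConformation, n: int,
                             seed: int = 0, jitter: float = 0.2
                             ) -> list[ReceptorConformation]:
    """n jittered copies of one receptor (same sequence, perturbed coords)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        residues = []
        for res in base.residues:
            atoms = [
                Atom(
                    name=a.name, element=a.element,
                    coords=a.coords + rng.normal(0.0, jitter, 3),
                    is_main_chain=a.is_main_chain, is_polar=a.is_polar,
                    is_hydrophobic=a.is_hydrophobic, is_donor=a.is_donor,
                    is_acceptor=a.is_acceptor, is_aromatic=a.is_aromatic,
                    formal_charge=a.formal_charge,
                )
                for a in res.atoms
            ]
            residues.append(Residue(res.chain, res.resnum, res.resname, atoms))
        out.append(ReceptorConformation(f"conf{i + 1}", residues))
    return out


# ---------------------------------------------------------------------------
# fingerprint-level simulation
# ---------------------------------------------------------------------------

def _repair_chunks(bits: np.ndarray, n_residues: int) -> np.ndarray:
    """Recompute any/main/side so every chunk satisfies the invariants."""
    chunks = bits.reshape(n_residues, BITS_PER_RESIDUE)
    payload_any = chunks[:, _PAYLOAD].any(axis=1)
    chunks[:, _ANY] = payload_any
    orphan = payload_any & ~chunks[:, _MAIN].astype(bool) & ~chunks[:, _SIDE].astype(bool)
    chunks[orphan, _SIDE] = 1  # unattributed synthetic contacts go side-chain
    return chunks.reshape(-1)


def signal_positions(cfg: FingerprintSimConfig) -> np.ndarray:
    """The conserved active-pattern bit positions implied by cfg and seed."""
    rng = np.random.default_rng(cfg.seed)
    eligible = np.array([
        r * BITS_PER_RESIDUE + b
        for r in range(cfg.n_residues)
        for b in range(3, BITS_PER_RESIDUE)
    ])
    return np.sort(rng.choice(eligible, size=cfg.n_signal_bits, replace=False))


def _mixed_draws(rng: np.random.Generator, shared_row: np.ndarray,
                 p: float, rho: float, n_conf: int) -> np.ndarray:
    """(n_conf, len(row)) Bernoulli(p) draws; each entry copies the shared
    per-compound draw with probability ρ, keeping the marginal rate at p."""
    independent = rng.random((n_conf, shared_row.size)) < p
    if rho == 0:
        return independent
    use_shared = rng.random((n_conf, shared_row.size)) < rho
    return np.where(use_shared, shared_row[None, :], independent)


def simulate_fingerprints(
    cfg: FingerprintSimConfig,
) -> tuple[list[Sift], dict[str, int]]:
    """Draw per-conformation SIFts and ±1 labels under the signal/noise model.

    Returns a flat list of :class:`Sift` (one per surviving
    (compound, conformation) pair, conformation ids ``conf1..confN``) and a
    label map (+1 actives, −1 inactives ``inact*`` and decoys ``dec*``).
    Compounds whose every pose fails are omitted entirely.
    """
    rng = np.random.default_rng(cfg.seed)
    n_bits = cfg.n_residues * BITS_PER_RESIDUE
    signal = signal_positions(cfg)
    conf_ids = [f"conf{i + 1}" for i in range(cfg.n_conformations)]

    compounds = (
        [(f"act{i + 1}", 1) for i in range(cfg.n_active)]
        + [(f"inact{i + 1}", -1) for i in range(cfg.n_inactive)]
        + [(f"dec{i + 1}", -1) for i in range(cfg.n_decoy)]
    )

    sifts: list[Sift] = []
    labels: dict[str, int] = {}
    rho = cfg.noise_correlation
    for cid, y in compounds:
        shared_flips = rng.random(signal.size) < cfg.flip_prob
        shared_bg = rng.random(n_bits) < cfg.background_rate
        flips = _mixed_draws(rng, shared_flips, cfg.flip_prob, rho,
                             cfg.n_conformations)
        background = _mixed_draws(rng, shared_bg, cfg.background_rate, rho,
                                  cfg.n_conformations)
        background[:, ::BITS_PER_RESIDUE] = False  # "any" is derived, not drawn
        pose_ok = rng.random(cfg.n_conformations) >= cfg.pose_fail_prob
        if not pose_ok.any():
            continue
        for c in range(cfg.n_conformations):
            if not pose_ok[c]:
                continue
            bits = background[c].astype(np.uint8)
            if y == 1:
                bits[signal] = (~flips[c]).astype(np.uint8)
            sifts.append(Sift(cid, conf_ids[c],
                              _repair_chunks(bits, cfg.n_residues)))
        labels[cid] = y
    return sifts, labels


def simulate_centroid_scores(
    informativeness: Mapping[str, float],
    n_pos: int = 100,
    n_neg: int = 100,
    seed: int = 0,
    max_shift: float = 3.0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Docking-score stand-in for per-conformation AUROC pre-evaluation.

    For each conformation, active-centroid scores are drawn from
    N(max_shift · informativeness, 1) and inactive-centroid scores from
    N(0, 1): informativeness 0 is an uninformative model (AUROC ≈ 0.5),
    informativeness 1 separates the classes by 3σ (AUROC ≈ 0.98).
    """
    rng = np.random.default_rng(seed)
    out = {}
    for conf_id in informativeness:
        level = float(informativeness[conf_id])
        if not 0 <= level <= 1:
            raise ValueError(f"informativeness must be in [0,1], got {level}")
        pos = rng.normal(max_shift * level, 1.0, size=n_pos)
        neg = rng.normal(0.0, 1.0, size=n_neg)
        out[conf_id] = (pos, neg)
    return out
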