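"""Compound curation: activity labelling, clustering/centroids, decoys.

Labelling follows the affinity protocol for the screening study: activity in
Ki or IC50 (nM) with Ki assumed to be IC50/2; a compound is *active* when
Ki < 100 nM, *inactive* when Ki > 1000 nM, and excluded in between — both
thresholds strict, so 100 nM and 1000 nM exactly are excluded. Duplicate
measurements for one compound are merged by geometric mean of Ki, the
natural average on a log-scaled affinity.

Clustering reduces each compound group to ~30% cluster centroids for fast
receptor-model pre-evaluation. The original work used a proprietary tool;
here hierarchical average-linkage clustering on Tanimoto distance of 2D
hashed fingerprints is used as an open, reproducible equivalent, with the
centroid of a cluster defined as the member minimizing mean intra-cluster
distance (ties to the lexicographically smaller id).

Decoy selection is a simplified property-matched (DUD-style) filter:
candidates inside MW/logP/HBD/HBA/rotatable-bond windows of at least one
active, topologically dissimilar (Tanimoto < 0.6) to every active, then
uniformly down-sampled to the requested count with a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ActivityRecord",
    "LabelledCompound",
    "ACTIVE_KI_NM",
    "INACTIVE_KI_NM",
    "label_compounds",
    "cluster_count",
    "cluster_and_pick_centroids",
    "select_decoys",
    "tanimoto_distance_matrix",
    "compound_properties_from_smiles",
]

ACTIVE_KI_NM = 100.0
INACTIVE_KI_NM = 1000.0

#: DUD-style property windows relative to any single active
PROPERTY_WINDOWS = {"mw": 25.0, "logp": 1.0, "hbd": 1.0, "hba": 1.0, "rotb": 2.0}
DECOY_TANIMOTO_MAX = 0.6


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    measure: str  # "Ki" | "IC50"
    value_nM: float
    smiles: str | None = None

    def __post_init__(self) -> None:
        if self.measure not in ("Ki", "IC50"):
            raise ValueError(f"measure must be Ki or IC50, got {self.measure!r}")
        if not (self.value_nM > 0):
            raise ValueError(f"{self.compound_id}: nonpositive activity value")

    @property
    def ki_nM(self) -> float:
        return self.value_nM / 2 if self.measure == "IC50" else self.value_nM


@dataclass(frozen=True)
class LabelledCompound:
    compound_id: str
    label: str  # "active" | "inactive" | "excluded"
    ki_nM: float


def label_compounds(records: Sequence[ActivityRecord]) -> list[LabelledCompound]:
    """Convert, merge and threshold activity records into class labels."""
    ki_values: dict[str, list[float]] = {}
    for rec in records:
        ki_values.setdefault(rec.compound_id, []).append(rec.ki_nM)
    out = []
    for cid in sorted(ki_values):
        ki = math.exp(float(np.mean(np.log(ki_values[cid]))))
        if ki < ACTIVE_KI_NM:
            label = "active"
        elif ki > INACTIVE_KI_NM:
            label = "inactive"
        else:
            label = "excluded"
        out.append(LabelledCompound(cid, label, ki))
    return out


def cluster_count(n_compounds: int) -> int:
    """Number of clusters: ~30% of the compound count (floor, minimum 1)."""
    if n_compounds < 1:
        raise ValueError("need at least one compound")
    return max(1, int(math.floor(0.3 * n_compounds)))


def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise 1 − Tanimoto for rows of a binary fingerprint matrix.

    Two all-zero fingerprints count as identical (distance 0).
    """
    fps = np.asarray(fps, dtype=bool)
    inter = (fps[:, None, :] & fps[None, :, :]).sum(axis=-1).astype(float)
    union = (fps[:, None, :] | fps[None, :, :]).sum(axis=-1).astype(float)
    sim = np.divide(inter, union, out=np.ones_like(inter), where=union > 0)
    return 1.0 - sim


def cluster_and_pick_centroids(fingerprints: Mapping[str, np.ndarray],
                               k: int, seed: int = 0) -> list[str]:
    """Cluster compounds into k groups, return one centroid id per cluster.

    Average-linkage hierarchical clustering on Tanimoto distance; the
    centroid is the member with minimal mean distance to the other members
    of its cluster, ties broken by lexicographic compound id. Deterministic;
    the seed is accepted for interface stability but unused (no sampling is
    performed at these input sizes).
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    ids = sorted(fingerprints)
    if not ids:
        raise ValueError("empty input")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of compounds ({len(ids)})")
    if k == len(ids):
        return ids
    fps = np.stack([np.asarray(fingerprints[i], dtype=bool) for i in ids])
    dist = tanimoto_distance_matrix(fps)
    z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(z, t=k, criterion="maxclust")

    centroids = []
    for cluster in np.unique(assignment):
        members = np.flatnonzero(assignment == cluster)
        if len(members) == 1:
            centroids.append(ids[members[0]])
            continue
        sub = dist[np.ix_(members, members)]
        mean_dist = sub.sum(axis=1) / (len(members) - 1)
        best = min(range(len(members)),
                   key=lambda j: (mean_dist[j], ids[members[j]]))
        centroids.append(ids[members[best]])
    return sorted(centroids)


def _within_windows(cand: Mapping[str, float],
                    active: Mapping[str, float]) -> bool:
    return all(
        abs(float(cand[prop]) - float(active[prop])) <= window
        for prop, window in PROPERTY_WINDOWS.items()
    )


def select_decoys(candidates: Sequence[Mapping[str, object]],
                  actives: Sequence[Mapping[str, object]],
                  n: int, seed: int) -> list[str]:
    """Pick n property-matched, topologically dissimilar decoy ids.

    ``candidates`` and ``actives`` are records with keys ``compound_id``,
    the properties in :data:`PROPERTY_WINDOWS`, and ``fingerprint`` (binary
    array). A candidate survives when it matches the property windows of at
    least one active, has Tanimoto < 0.6 to every active, and is not itself
    an active id; survivors are down-sampled uniformly at random to n.
    """
    if not actives:
        raise ValueError("no actives to match against")
    active_ids = {a["compound_id"] for a in actives}
    active_fps = np.stack(
        [np.asarray(a["fingerprint"], dtype=bool) for a in actives]
    )

    survivors = []
    for cand in candidates:
        cid = str(cand["compound_id"])
        if cid in active_ids:
            continue
        if not any(_within_windows(cand, a) for a in actives):
            continue
        fp = np.asarray(cand["fingerprint"], dtype=bool)
        inter = (active_fps & fp).sum(axis=1).astype(float)
        union = (active_fps | fp).sum(axis=1).astype(float)
        sim = np.divide(inter, union, out=np.ones_like(inter), where=union > 0)
        if (sim >= DECOY_TANIMOTO_MAX).any():
            continue
        survivors.append(cid)

    if len(survivors) < n:
        raise ValueError(
            f"only {len(survivors)} candidates survive the filters; {n} requested"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(survivors), size=n, replace=False)
    return [survivors[i] for i in sorted(picked)]


def compound_properties_from_smiles(smiles_by_id: Mapping[str, str],
                                    n_bits: int = 1024) -> list[dict]:
    """Compute the decoy-selection property record for each SMILES.

    Returns records with MW, Crippen logP, H-bond donor/acceptor counts,
    rotatable bonds, and a hashed Morgan (radius 2) fingerprint.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    records = []
    for cid in sorted(smiles_by_id):
        mol = Chem.MolFromSmiles(smiles_by_id[cid])
        if mol is None:
            raise ValueError(f"unparsable SMILES for {cid!r}")
        fp = np.zeros(n_bits, dtype=np.uint8)
        fp[list(gen.GetFingerprint(mol).GetOnBits())] = 1
        records.append({
            "compound_id": cid,
            "mw": Descriptors.MolWt(mol),
            "logp": Crippen.MolLogP(mol),
            "hbd": Lipinski.NumHDonors(mol),
            "hba": Lipinski.NumHAcceptors(mol),
            "rotb": Lipinski.NumRotatableBonds(mol),
            "fingerprint": fp,
        })
    return records
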