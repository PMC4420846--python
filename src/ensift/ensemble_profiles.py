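"""Per-ligand SIFt profiles: binary fingerprints averaged over an ensemble.

For every compound with at least one pose in the ensemble, each bit position
is averaged over the receptor conformations. The default denominator is the
full ensemble size, with conformations in which the compound received no
pose contributing zero vectors ("all models" averaging). Because the source
protocol is ambiguous on this point, an alternate mode normalizing by the
number of posed conformations is also provided (``denominator="posed"``).
The resulting real-valued vector in [0, 1] per position is the feature
vector for classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .screening_ml import FeatureMatrix
from .sift_core import BITS_PER_RESIDUE, Sift

__all__ = ["SiftProfile", "build_profile", "profile_matrix",
           "write_profiles", "read_profiles"]


@dataclass
class SiftProfile:
    compound_id: str
    ensemble_ids: tuple[str, ...]
    values: np.ndarray  # float in [0,1], length 9 × n_residues
    n_poses: int

    def __post_init__(self) -> None:
        self.ensemble_ids = tuple(self.ensemble_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) % BITS_PER_RESIDUE:
            raise ValueError("profile length must be a multiple of 9")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("profile values must lie in [0, 1]")
        if self.n_poses < 1:
            raise ValueError("a profile requires at least one pose")


def build_profile(sifts: Sequence[Sift], ensemble_ids: Sequence[str],
                  denominator: str = "all_models") -> SiftProfile:
    """Average one compound's binary SIFts over the ensemble.

    ``denominator="all_models"`` divides by the ensemble size (missing poses
    count as zero vectors); ``denominator="posed"`` divides by the number of
    conformations in which the compound actually has a pose.
    """
    if denominator not in ("all_models", "posed"):
        raise ValueError("denominator must be 'all_models' or 'posed'")
    sifts = list(sifts)
    if not sifts:
        raise ValueError("a compound with zero poses must be dropped upstream")
    ensemble_ids = tuple(ensemble_ids)
    compound_ids = {s.compound_id for s in sifts}
    if len(compound_ids) != 1:
        raise ValueError(f"one compound per profile; got {sorted(compound_ids)}")
    seen_confs = [s.conformation_id for s in sifts]
    if len(set(seen_confs)) != len(seen_confs):
        raise ValueError("duplicate conformation ids among this compound's poses")
    if not set(seen_confs) <= set(ensemble_ids):
        extra = set(seen_confs) - set(ensemble_ids)
        raise ValueError(f"poses reference conformations outside the ensemble: {sorted(extra)}")
    lengths = {len(s.bits) for s in sifts}
    if len(lengths) != 1:
        raise ValueError("SIFt lengths differ")

    total = np.sum([s.bits.astype(float) for s in sifts], axis=0)
    denom = len(ensemble_ids) if denominator == "all_models" else len(sifts)
    return SiftProfile(
        compound_id=sifts[0].compound_id,
        ensemble_ids=ensemble_ids,
        values=total / denom,
        n_poses=len(sifts),
    )


def profile_matrix(profiles: Sequence[SiftProfile],
                   labels: Mapping[str, object],
                   groups: Mapping[str, str] | None = None,
                   feature_names: Sequence[str] | None = None) -> FeatureMatrix:
    """Stack profiles into a FeatureMatrix with ±1 labels.

    ``labels`` maps compound id to +1/−1 or to "active"/"inactive"/"decoy"
    (anything but "active" counts as the negative class). ``groups`` maps a
    compound instance to its parent compound for leakage-safe folding;
    instances default to being their own group.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles supplied")
    ref = profiles[0].ensemble_ids
    n_feat = len(profiles[0].values)
    for p in profiles[1:]:
        if p.ensemble_ids != ref or len(p.values) != n_feat:
            raise ValueError(
                f"profile {p.compound_id!r} built on a different ensemble"
            )
    y = []
    for p in profiles:
        if p.compound_id not in labels:
            raise ValueError(f"compound {p.compound_id!r} has no label")
        raw = labels[p.compound_id]
        if raw in (1, -1):
            y.append(int(raw))
        elif isinstance(raw, str):
            y.append(1 if raw == "active" else -1)
        else:
            raise ValueError(f"unusable label {raw!r} for {p.compound_id!r}")
    ids = [p.compound_id for p in profiles]
    return FeatureMatrix(
        X=np.stack([p.values for p in profiles]),
        y=np.array(y),
        ids=ids,
        groups=[groups.get(i, i) for i in ids] if groups else list(ids),
        feature_names=list(feature_names) if feature_names else [],
    )


def write_profiles(profiles: Sequence[SiftProfile], path: str | Path) -> None:
    import pandas as pd

    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to write")
    frame = pd.DataFrame(np.stack([p.values for p in profiles]))
    frame.columns = [f"pos{j}" for j in range(frame.shape[1])]
    frame.insert(0, "n_poses", [p.n_poses for p in profiles])
    frame.insert(0, "compound_id", [p.compound_id for p in profiles])
    with open(path, "w") as fh:
        fh.write(f"# ensemble={','.join(profiles[0].ensemble_ids)}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_profiles(path: str | Path) -> list[SiftProfile]:
    import pandas as pd

    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# ensemble="):
            raise ValueError(f"{path}: missing ensemble header line")
        ensemble_ids = tuple(header.strip().split("=", 1)[1].split(","))
        frame = pd.read_csv(fh, sep="\t", dtype={"compound_id": str})
    value_cols = [c for c in frame.columns if c.startswith("pos")]
    return [
        SiftProfile(row["compound_id"], ensemble_ids,
                    row[value_cols].to_numpy(dtype=float), int(row["n_poses"]))
        for _, row in frame.iterrows()
    ]
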