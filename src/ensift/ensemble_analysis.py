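"""Ensemble-size sweep: classification performance vs. receptor count.

The central experiment: starting from three receptor conformations and
adding the remaining ones one by one in a fixed order, rebuild every
compound's SIFt profile at each ensemble size, re-run the full C-grid
cross-validation, and track the pooled MCC. The sweep reports the per-step
MCC change, the best and worst ensemble sizes (ties to the smaller, cheaper
ensemble), and — when a per-conformation AUROC pre-evaluation is supplied —
the step at which the top-ranked conformation enters the profile.

The addition order is the caller's manifest order by default; ordering by
descending AUROC is available via :func:`ConformationRanking.order`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ensemble_profiles import build_profile, profile_matrix
from .screening_ml import DEFAULT_C_GRID, compute_auroc, cross_validate
from .sift_core import Sift

__all__ = [
    "CvConfig",
    "ConformationRanking",
    "SweepResult",
    "rank_conformations",
    "run_sweep",
    "summarize_sweeps",
]

MIN_ENSEMBLE_SIZE = 3


@dataclass(frozen=True)
class CvConfig:
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    k_folds: int = 10
    seed: int = 0


@dataclass
class ConformationRanking:
    auroc_by_conformation: dict[str, float]

    @property
    def best(self) -> str:
        return max(
            self.auroc_by_conformation,
            key=lambda c: (self.auroc_by_conformation[c], c),
        )

    def order(self, descending: bool = True) -> list[str]:
        return sorted(
            self.auroc_by_conformation,
            key=lambda c: self.auroc_by_conformation[c],
            reverse=descending,
        )


@dataclass
class SweepResult:
    ensemble_order: tuple[str, ...]
    sizes: tuple[int, ...]
    mcc_by_size: dict[int, float]
    auroc_by_size: dict[int, float]
    best_C_by_size: dict[int, float]
    delta_mcc: dict[int, float]
    best_size: int
    worst_size: int
    best_auroc_conformation: str | None = None
    best_auroc_step: int | None = None

    def to_dict(self) -> dict:
        return {
            "ensemble_order": list(self.ensemble_order),
            "sizes": list(self.sizes),
            "mcc_by_size": {str(k): v for k, v in self.mcc_by_size.items()},
            "auroc_by_size": {str(k): v for k, v in self.auroc_by_size.items()},
            "best_C_by_size": {str(k): v for k, v in self.best_C_by_size.items()},
            "delta_mcc": {str(k): v for k, v in self.delta_mcc.items()},
            "best_size": self.best_size,
            "worst_size": self.worst_size,
            "best_auroc_conformation": self.best_auroc_conformation,
            "best_auroc_step": self.best_auroc_step,
        }


def rank_conformations(
    centroid_scores: Mapping[str, tuple[Sequence[float], Sequence[float]]],
) -> ConformationRanking:
    """AUROC of each conformation's (active, inactive) centroid scores."""
    return ConformationRanking({
        conf: compute_auroc(pos, neg)
        for conf, (pos, neg) in centroid_scores.items()
    })


def _profiles_for_prefix(by_compound: Mapping[str, list[Sift]],
                         prefix: tuple[str, ...], denominator: str):
    prefix_set = set(prefix)
    profiles = []
    for cid in by_compound:
        subset = [s for s in by_compound[cid] if s.conformation_id in prefix_set]
        if subset:  # "at least one pose" rule at this ensemble size
            profiles.append(build_profile(subset, prefix, denominator=denominator))
    return profiles


def run_sweep(
    sifts: Sequence[Sift],
    labels: Mapping[str, object],
    ensemble_order: Sequence[str],
    min_size: int = MIN_ENSEMBLE_SIZE,
    cv: CvConfig | None = None,
    ranking: ConformationRanking | None = None,
    groups: Mapping[str, str] | None = None,
    denominator: str = "all_models",
) -> SweepResult:
    """Evaluate pooled CV MCC at every ensemble size min_size..N.

    At each size s the profile is built on the *prefix* of the first s
    conformations of ``ensemble_order`` and the full C grid re-optimized.
    """
    cv = cv or CvConfig()
    order = tuple(ensemble_order)
    if len(set(order)) != len(order):
        raise ValueError("duplicate conformation ids in ensemble_order")
    if len(order) < min_size:
        raise ValueError(
            f"need at least {min_size} conformations, got {len(order)}"
        )
    by_compound: dict[str, list[Sift]] = {}
    for s in sifts:
        by_compound.setdefault(s.compound_id, []).append(s)

    sizes = tuple(range(min_size, len(order) + 1))
    mcc_by_size: dict[int, float] = {}
    auroc_by_size: dict[int, float] = {}
    best_C_by_size: dict[int, float] = {}
    for size in sizes:
        profiles = _profiles_for_prefix(by_compound, order[:size], denominator)
        data = profile_matrix(profiles, labels, groups=groups)
        result = cross_validate(data, C_grid=cv.C_grid, k_folds=cv.k_folds,
                                seed=cv.seed)
        mcc_by_size[size] = result.pooled_mcc
        auroc_by_size[size] = result.pooled_auroc
        best_C_by_size[size] = result.best_C

    delta_mcc = {
        s: mcc_by_size[s] - mcc_by_size[s - 1] for s in sizes if s - 1 in mcc_by_size
    }
    best_size = min(sizes, key=lambda s: (-mcc_by_size[s], s))
    worst_size = min(sizes, key=lambda s: (mcc_by_size[s], s))

    best_conf = best_step = None
    if ranking is not None:
        best_conf = ranking.best
        if best_conf in order:
            best_step = order.index(best_conf) + 1
    return SweepResult(
        ensemble_order=order, sizes=sizes, mcc_by_size=mcc_by_size,
        auroc_by_size=auroc_by_size, best_C_by_size=best_C_by_size,
        delta_mcc=delta_mcc, best_size=best_size, worst_size=worst_size,
        best_auroc_conformation=best_conf, best_auroc_step=best_step,
    )


def summarize_sweeps(results: Mapping[str, SweepResult]):
    """One-row-per-scenario summary table (optimal/worst ensemble sizes)."""
    import pandas as pd

    if not results:
        raise ValueError("no sweep results to summarize")
    rows = []
    for scenario, res in results.items():
        rows.append({
            "scenario": scenario,
            "optimal_size": res.best_size,
            "mcc_at_optimal": res.mcc_by_size[res.best_size],
            "worst_size": res.worst_size,
            "mcc_at_worst": res.mcc_by_size[res.worst_size],
        })
    return pd.DataFrame(rows)
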