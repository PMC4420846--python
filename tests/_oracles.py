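"""Independent reference implementations used only by tests.

Deliberately naive: plain Python loops and exhaustive enumeration, sharing
no code path with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from ensift.complex_io import RESIDUE_AROMATIC_RINGS


def _d(a, b) -> float:
    return math.dist(list(a), list(b))


def _hs_on(atoms, heavy) -> list:
    return [h for h in atoms
            if h.element == "H" and _d(h.coords, heavy.coords) <= 1.3]


def _angle_ok(donor, acceptor, hs, min_deg) -> bool:
    if not hs:
        return True
    for h in hs:
        v1 = np.asarray(donor.coords) - np.asarray(h.coords)
        v2 = np.asarray(acceptor.coords) - np.asarray(h.coords)
        norm = np.linalg.norm(v1) * np.linalg.norm(v2)
        if norm == 0:
            continue
        ang = math.degrees(math.acos(max(-1.0, min(1.0, float(v1 @ v2) / norm))))
        if ang >= min_deg:
            return True
    return False


def pairwise_residue_bits(residue, ligand, cfg) -> dict[str, bool]:
    """Exhaustive per-pair evaluation of the nine interaction predicates."""
    bits = {k: False for k in (
        "any", "main_chain", "side_chain", "polar", "hydrophobic",
        "hb_acceptor", "hb_donor", "aromatic", "charged")}
    r_heavy = [a for a in residue.atoms if a.element != "H"]
    l_heavy = [a for a in ligand.atoms if a.element != "H"]
    touched = []  # residue atoms participating in any detected interaction

    for ra in r_heavy:
        for la in l_heavy:
            d = _d(ra.coords, la.coords)
            if d <= cfg.contact_cutoff:
                touched.append(ra)
            if ra.is_polar and la.is_polar and d <= cfg.polar_cutoff:
                bits["polar"] = True
                touched.append(ra)
            if ra.is_hydrophobic and la.is_hydrophobic and d <= cfg.hydrophobic_cutoff:
                bits["hydrophobic"] = True
                touched.append(ra)
            if d <= cfg.hbond_dist:
                if ra.is_donor and la.is_acceptor and _angle_ok(
                        ra, la, _hs_on(residue.atoms, ra), cfg.hbond_angle_min):
                    bits["hb_donor"] = True
                    bits["polar"] = True
                    touched.append(ra)
                if ra.is_acceptor and la.is_donor and _angle_ok(
                        la, ra, _hs_on(ligand.atoms, la), cfg.hbond_angle_min):
                    bits["hb_acceptor"] = True
                    bits["polar"] = True
                    touched.append(ra)
            if ra.formal_charge * la.formal_charge < 0 and d <= cfg.charged_cutoff:
                bits["charged"] = True
                touched.append(ra)

    by_name = {a.name: a for a in residue.atoms}
    for ring_names in RESIDUE_AROMATIC_RINGS.get(residue.resname, []):
        if not all(n in by_name for n in ring_names):
            continue
        rc = np.mean([by_name[n].coords for n in ring_names], axis=0)
        for lring in ligand.ring_systems:
            lc = np.mean([ligand.atoms[i].coords for i in lring], axis=0)
            if _d(rc, lc) <= cfg.aromatic_centroid_cutoff:
                bits["aromatic"] = True
                touched.extend(by_name[n] for n in ring_names)

    bits["any"] = bool(touched)
    bits["main_chain"] = any(a.is_main_chain for a in touched)
    bits["side_chain"] = any(not a.is_main_chain for a in touched)
    return bits


def qp_dual_optimum(X: np.ndarray, y: np.ndarray, C: float) -> float:
    """Maximum of the soft-margin SVM dual by exhaustive active-set search.

    Enumerates every lower-bound / free / upper-bound assignment of the α_i
    (3^n cases, n ≤ ~8), solves the stationarity system for the free set,
    and keeps the best feasible objective. Any feasible candidate bounds the
    optimum from below and the optimal assignment attains it exactly.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    Q = (y[:, None] * y[None, :]) * (X @ X.T)
    eps = 1e-9
    best = -np.inf
    for assign in itertools.product((0, 1, 2), repeat=n):
        free = [i for i, a in enumerate(assign) if a == 1]
        upper = [i for i, a in enumerate(assign) if a == 2]
        alpha = np.zeros(n)
        alpha[upper] = C
        if free:
            m = len(free)
            A = np.zeros((m + 1, m + 1))
            A[:m, :m] = Q[np.ix_(free, free)]
            A[:m, m] = y[free]
            A[m, :m] = y[free]
            rhs = np.zeros(m + 1)
            rhs[:m] = 1.0 - (Q[np.ix_(free, upper)] @ alpha[upper] if upper else 0.0)
            rhs[m] = -(y[upper] @ alpha[upper]) if upper else 0.0
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            if not np.allclose(A @ sol, rhs, atol=1e-7):
                continue
            alpha[free] = sol[:m]
        if (alpha < -eps).any() or (alpha > C + eps).any():
            continue
        if abs(float(y @ alpha)) > 1e-7 * max(1.0, float(alpha.sum())):
            continue
        obj = float(alpha.sum() - 0.5 * alpha @ Q @ alpha)
        best = max(best, obj)
    return best


def auroc_pair_count(pos, neg) -> float:
    """All-pairs Mann–Whitney count, loop form."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
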