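"""Rigid-body superposition and TM-score.

The TM-score compares two structures over a residue correspondence:

    TM = max over superpositions of (1/L_norm) * sum_i 1 / (1 + (d_i/d0)^2)

where d_i are Cα–Cα distances of corresponding residues after a rigid
superposition, L_norm a normalization length, and
d0 = 1.24·(L_norm − 15)^(1/3) − 1.8 Å (floored at 0.5 Å) the
length-dependent scale that makes the score length-independent.  Scores
lie in (0, 1]; below 0.17 is what a random structure pair achieves,
above 0.3 indicates significant similarity, above 0.5 the same overall
fold.

The maximisation is a heuristic search: a global Kabsch superposition
plus Kabsch fits on contiguous seed fragments (full, half, quarter
length at every offset), each refined by iteratively re-superposing on
the residue subset whose distance falls under a cutoff until that subset
is stable.  The reported score is the best found and is never below the
plain global-Kabsch score.

Residue correspondence is always by author residue number
(structures.map_common_residues); there is no sequence-order-independent
alignment here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Conformation, map_common_residues

__all__ = [
    "SuperpositionResult",
    "TMResult",
    "kabsch_superpose",
    "compute_d0",
    "tm_score",
    "similarity_band",
    "SIMILARITY_THRESHOLDS",
]

SIMILARITY_THRESHOLDS = (0.17, 0.3, 0.5)

#: refinement keeps residue pairs with d_i below max(d0, this) Å
_REFINE_FLOOR = 4.5
_MAX_REFINE_ITER = 20


@dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping 'moving' onto 'fixed':
    x_fixed ≈ rotation @ x_moving + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    per_residue_distance: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class TMResult:
    tm: float
    normalization_length: int
    d0: float
    superposition: SuperpositionResult
    n_mapped: int


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Optimal proper-rotation + translation superposing moving onto fixed.

    Reflections are excluded (chirality is physical).  Degenerate input
    (fewer than 3 points, or all points collinear) is an error.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("moving and fixed must be equal-shape (n, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    mc = moving - moving.mean(axis=0)
    fc = fixed - fixed.mean(axis=0)
    # collinear point sets leave the rotation about that axis unconstrained
    for pts in (mc, fc):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise ValueError("degenerate (collinear) point set")
    rot, _ = Rotation.align_vectors(fc, mc)
    R = rot.as_matrix()
    t = fixed.mean(axis=0) - moving.mean(axis=0) @ R.T
    d = np.linalg.norm(moving @ R.T + t - fixed, axis=1)
    return SuperpositionResult(rotation=R, translation=t,
                               rmsd=float(np.sqrt(np.mean(d**2))),
                               per_residue_distance=d)


def compute_d0(L_norm: int) -> float:
    """Length-dependent TM-score distance scale, floored at 0.5 Å so
    short fragments (L ≤ 21) remain scorable."""
    if L_norm < 1:
        raise ValueError("L_norm must be >= 1")
    return max(0.5, 1.24 * np.cbrt(L_norm - 15) - 1.8)


def _tm_of_distances(d: np.ndarray, d0: float, L_norm: int) -> float:
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)


def _refine(X: np.ndarray, Y: np.ndarray, R: np.ndarray, t: np.ndarray,
            cutoff: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iteratively re-superpose moving Y onto fixed X on the subset with
    distance below cutoff, to a fixed point; returns final (R, t, d)."""
    d = np.linalg.norm(Y @ R.T + t - X, axis=1)
    prev: np.ndarray | None = None
    for _ in range(_MAX_REFINE_ITER):
        incl = d < cutoff
        if incl.sum() < 3 or (prev is not None and np.array_equal(incl, prev)):
            break
        prev = incl
        try:
            sup = kabsch_superpose(Y[incl], X[incl])
        except ValueError:  # included subset degenerate
            break
        R, t = sup.rotation, sup.translation
        d = np.linalg.norm(Y @ R.T + t - X, axis=1)
    return R, t, d


def tm_score(target: Conformation, model: Conformation,
             normalization: str = "common") -> TMResult:
    """TM-score of model against target over their shared residues.

    normalization:
        ``"common"`` (default) — L_norm is the number of mapped residues;
        appropriate when comparing partial chains of unequal coverage.
        ``"target"`` — conventional asymmetric TM-score, L_norm is the
        target's residue count.
        ``"shorter"`` — L_norm is the shorter chain's residue count.
    """
    if normalization not in {"common", "target", "shorter"}:
        raise ValueError(f"unknown normalization {normalization!r}")
    pairs = map_common_residues(target, model)
    n = len(pairs)
    if n < 3:
        raise ValueError(f"only {n} mapped residue pairs; need >= 3")
    ia = [i for i, _ in pairs]
    ib = [j for _, j in pairs]
    X = target.coords[ia]   # fixed
    Y = model.coords[ib]    # moving
    if normalization == "common":
        L_norm = n
    elif normalization == "target":
        L_norm = len(target)
    else:
        L_norm = min(len(target), len(model))
    d0 = compute_d0(L_norm)
    cutoff = max(d0, _REFINE_FLOOR)

    best_tm = -1.0
    best_Rt: tuple[np.ndarray, np.ndarray] | None = None

    def consider(R: np.ndarray, t: np.ndarray) -> None:
        nonlocal best_tm, best_Rt
        d = np.linalg.norm(Y @ R.T + t - X, axis=1)
        tm = _tm_of_distances(d, d0, L_norm)
        if tm > best_tm:
            best_tm, best_Rt = tm, (R, t)

    frag_lengths = sorted({n, max(3, n // 2), max(3, n // 4)}, reverse=True)
    for flen in frag_lengths:
        for off in range(0, n - flen + 1):
            sl = slice(off, off + flen)
            try:
                sup = kabsch_superpose(Y[sl], X[sl])
            except ValueError:
                continue
            # unrefined seed (the global Kabsch when flen == n, off == 0)
            consider(sup.rotation, sup.translation)
            R, t, _ = _refine(X, Y, sup.rotation, sup.translation, cutoff)
            consider(R, t)

    if best_Rt is None:
        raise ValueError("no valid superposition found (degenerate geometry)")
    R, t = best_Rt
    d = np.linalg.norm(Y @ R.T + t - X, axis=1)
    sup = SuperpositionResult(rotation=R, translation=t,
                              rmsd=float(np.sqrt(np.mean(d**2))),
                              per_residue_distance=d)
    return TMResult(tm=best_tm, normalization_length=L_norm, d0=d0,
                    superposition=sup, n_mapped=n)


def similarity_band(tm: float) -> str:
    """Interpretation band of a TM-score.

    Below 0.17: random-like similarity; (0.17, 0.3]: intermediate zone;
    above 0.3: significant; above 0.5: same overall fold.  Boundaries
    belong to the lower band ("above" is strict).
    """
    if not (0 < tm <= 1):
        raise ValueError(f"TM-score must lie in (0, 1], got {tm}")
    lo, mid, hi = SIMILARITY_THRESHOLDS
    if tm < lo:
        return "random_like"
    if tm <= mid:
        return "intermediate_zone"
    if tm <= hi:
        return "significant"
    return "same_fold"
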