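"""Synthetic structure and pathway generators.

Everything downstream (superposition, PSNs, classification, kinetics)
is exercised on generated Cα traces instead of downloaded coordinates:
ideal helices and strands, self-avoiding coils, hinge-perturbed
conformers, simulated co-translational pathways whose early segments
relax toward the native over time, and labelled datasets for the
dynamic-vs-static classification comparison.

All generators are pure functions of their parameters and seed.  Chain
geometry is kept physical: consecutive Cα distances are 3.8 ± 0.1 Å and
no two Cα atoms come closer than 2 Å.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .proxy import generate_proxy_intermediates, proxy_schedule
from .structures import Conformation, Pathway, Residue

__all__ = [
    "GeneratorParams", "make_helix", "make_strand", "make_coil",
    "make_hinged", "simulate_cotranslational_pathway",
    "make_classification_dataset",
]

#: ideal α-helix Cα geometry: 1.5 Å rise and 100° twist per residue on a
#: 2.3 Å radius -> consecutive Cα distance 3.83 Å
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3

#: extended-strand Cα geometry: 3.5 Å rise with a zigzag whose
#: half-amplitude makes the consecutive Cα distance exactly 3.8 Å
STRAND_RISE = 3.5
STRAND_ZIGZAG = float(np.sqrt(3.8**2 - STRAND_RISE**2))  # ~1.478 Å step offset

COIL_STEP = 3.8
_COIL_MIN_DIST = 3.2


@dataclass
class GeneratorParams:
    """Bundle of generator defaults (documented constants above)."""

    seed: int = 0
    helix_rise: float = HELIX_RISE
    helix_twist_deg: float = HELIX_TWIST_DEG
    helix_radius: float = HELIX_RADIUS
    strand_rise: float = STRAND_RISE
    strand_zigzag: float = STRAND_ZIGZAG
    noise_sigma: float = 0.0
    hinge_angle: float = 0.0
    hinge_position: int = 0


def _from_coords(coords: np.ndarray, protein_id: str, **kw) -> Conformation:
    residues = [Residue(seq_index=i + 1, aa="A", ca=c)
                for i, c in enumerate(coords)]
    return Conformation(protein_id=protein_id, residues=residues, **kw)


def make_helix(n: int, seed: int | None = None, protein_id: str = "helix") -> Conformation:
    """Ideal α-helical Cα trace (deterministic; seed unused)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    theta = np.deg2rad(HELIX_TWIST_DEG) * np.arange(n)
    coords = np.column_stack([
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * np.arange(n),
    ])
    return _from_coords(coords, protein_id)


def make_strand(n: int, seed: int | None = None, protein_id: str = "strand") -> Conformation:
    """Ideal extended-strand Cα trace (deterministic; seed unused)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    coords = np.column_stack([
        STRAND_RISE * i,
        STRAND_ZIGZAG * (i % 2),
        np.zeros(n),
    ])
    return _from_coords(coords, protein_id)


def make_coil(n: int, seed: int = 0, protein_id: str = "coil") -> Conformation:
    """Self-avoiding random walk with 3.8 Å steps."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    for _attempt in range(100):
        pts = [np.zeros(3)]
        ok = True
        while len(pts) < n:
            for _try in range(500):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = pts[-1] + COIL_STEP * u
                if len(pts) < 2 or np.min(np.linalg.norm(
                        np.asarray(pts[:-1]) - cand, axis=1)) >= _COIL_MIN_DIST:
                    pts.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            return _from_coords(np.asarray(pts), protein_id)
    raise RuntimeError("self-avoiding walk failed to complete")  # pragma: no cover


def make_hinged(conf: Conformation, hinge_position: int, hinge_angle: float,
                seed: int | None = None) -> Conformation:
    """Rigidly rotate the residues after ``hinge_position`` (1-based list
    position) by ``hinge_angle`` degrees about the local chain axis at
    the hinge.

    The axis passes through the hinge residue's Cα along the direction
    between its neighbors, so bond lengths across the hinge (and hence
    chain connectivity) are preserved.  A zero angle returns an
    unmodified copy.  ``seed`` is accepted for generator-API uniformity
    but unused (the operation is deterministic).
    """
    n = len(conf)
    if not (1 < hinge_position < n):
        raise ValueError(f"hinge_position must lie strictly inside (1, {n})")
    coords = conf.coords.copy()
    if hinge_angle != 0.0:
        pivot = coords[hinge_position - 1]
        axis = coords[hinge_position] - coords[hinge_position - 2]
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.deg2rad(hinge_angle) * axis)
        coords[hinge_position:] = rot.apply(coords[hinge_position:] - pivot) + pivot
    residues = [replace(r, ca=c) for r, c in zip(conf.residues, coords)]
    return replace(conf, residues=residues)


def simulate_cotranslational_pathway(
    native: Conformation,
    k: int = 5,
    nonnative_hinge_per_step: float = 0.0,
    seed: int = 0,
) -> Pathway:
    """Nascent-chain pathway with conformational change over time.

    Intermediates follow the proxy schedule (prefix lengths k, 2k, ...,
    L).  Intermediate t is the native prefix with hinge perturbations at
    regular interior positions (every half segment, so even the earliest
    subsequence changes conformation over time), of magnitude
    ``nonnative_hinge_per_step * (T - 1 - t)`` degrees — decreasing to
    zero at the final snapshot, so the last intermediate is exactly the
    native.  A zero per-step angle reduces bit-identically to
    generate_proxy_intermediates.
    """
    if len(native) < k:
        raise ValueError("native must have at least k residues")
    proxies = generate_proxy_intermediates(native, k)
    if nonnative_hinge_per_step == 0.0:
        return proxies
    rng = np.random.default_rng(seed)
    T = len(proxies)
    step = max(2, k // 2)
    n_hinges = len(native) // step + 1
    signs = rng.choice([-1.0, 1.0], size=n_hinges)
    intermediates = []
    for t, confs in proxies.intermediates:
        conf = confs[0]
        angle = nonnative_hinge_per_step * (T - 1 - t)
        if angle > 0:
            for j in range(1, len(conf) // step + 1):
                pos = j * step
                if 1 < pos < len(conf):
                    conf = make_hinged(conf, pos, float(signs[j] * angle))
        intermediates.append((t, [conf]))
    return Pathway(protein_id=native.protein_id, intermediates=intermediates)


def _jitter(conf: Conformation, sigma: float, rng: np.random.Generator) -> Conformation:
    coords = conf.coords + rng.normal(scale=sigma, size=(len(conf), 3))
    return replace(conf, residues=[replace(r, ca=c)
                                   for r, c in zip(conf.residues, coords)])


def _helix_strand_native(L: int, protein_id: str) -> Conformation:
    """Helical N-terminal half joined to an extended C-terminal half —
    a chain whose two halves have distinct contact topology."""
    h = L // 2
    helix = make_helix(h).coords
    start = helix[-1] + np.array([0.0, 0.0, 3.8])
    i = np.arange(L - h)
    strand = np.column_stack([
        start[0] + STRAND_RISE * i,
        start[1] + STRAND_ZIGZAG * (i % 2),
        np.full(L - h, start[2]),
    ])
    return _from_coords(np.vstack([helix, strand]), protein_id)


def _suffix_pathway(native: Conformation, k: int) -> Pathway:
    """Pathway growing from the C-terminus: snapshots are suffixes of
    the native of the proxy-schedule lengths."""
    L = len(native)
    sched = proxy_schedule(L, k)
    intermediates = []
    for t, n in enumerate(sched.prefix_lengths):
        conf = native.subset(range(L - n, L))
        conf = replace(conf, intermediate_index=t)
        intermediates.append((t, [conf]))
    return Pathway(protein_id=native.protein_id, intermediates=intermediates)


def make_classification_dataset(
    n_per_class: int,
    class_spec: str = "order_only",
    k: int = 5,
    seed: int = 0,
    length: int = 48,
    noise_sigma: float = 0.3,
) -> tuple[list[Pathway], np.ndarray]:
    """Labelled pathway dataset for the dynamic-vs-static comparison.

    ``order_only``: both classes end in the same native structure (a
    helix half plus a strand half, per-item jitter only) but fold in
    opposite order — class 0 grows from the N-terminus, class 1 from the
    C-terminus.  Final-snapshot (static) features are therefore
    class-identical in distribution; only the dynamics separates them.

    ``topology``: class 0 natives are helical, class 1 natives extended
    strands — separable statically.
    """
    if n_per_class < 10:
        raise ValueError("n_per_class must be >= 10")
    if class_spec not in {"order_only", "topology"}:
        raise ValueError("class_spec must be 'order_only' or 'topology'")
    rng = np.random.default_rng(seed)
    pathways: list[Pathway] = []
    labels = []
    for item in range(2 * n_per_class):
        label = item % 2
        pid = f"{class_spec}-{item}"
        if class_spec == "topology":
            base = make_helix(length, protein_id=pid) if label == 0 \
                else make_strand(length, protein_id=pid)
            native = _jitter(base, noise_sigma, rng)
            pw = generate_proxy_intermediates(native, k)
        else:
            native = _jitter(_helix_strand_native(length, pid), noise_sigma, rng)
            pw = generate_proxy_intermediates(native, k) if label == 0 \
                else _suffix_pathway(native, k)
        pathways.append(pw)
        labels.append(label)
    return pathways, np.asarray(labels)
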