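"""Residue-displacement descriptor: symmetry-aware RMSD against a reference pose.

The descriptor is the root-mean-square deviation between the positions of a
chosen residue's atoms in a docked pose and the corresponding atoms of the
reference ligand, both expressed in the same receptor frame.  No translation
or rotation fitting is ever applied — the quantity measures how far the
residue sits from where the reference ligand places it in the pocket, not
how different the two conformations are.

Chemically equivalent atoms (the two ortho/meta carbon pairs of a phenyl
ring) are indistinguishable, so the RMSD is minimised over the automorphisms
declared by the selections' symmetry groups (for one ring: identity and the
180° flip).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pose_io import Pose, ResidueSelection, select_residue

__all__ = [
    "DisplacementResult",
    "residue_rmsd",
    "best_pose_rmsd",
    "symmetry_mappings",
]


@dataclass(frozen=True)
class DisplacementResult:
    compound_id: str
    residue_index: int
    rmsd: float
    mapping_used: tuple[tuple[str, str], ...]
    n_atoms: int

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        if self.n_atoms != len(self.mapping_used):
            raise ValueError("n_atoms inconsistent with mapping length")


def _flip_permutation(cycle_idx: Sequence[int], n: int) -> tuple[int, ...]:
    """Permutation of range(n) reversing the cycle about its first element."""
    perm = list(range(n))
    k = len(cycle_idx)
    for i, src in enumerate(cycle_idx):
        perm[src] = cycle_idx[(k - i) % k]
    return tuple(perm)


def symmetry_mappings(selection: ResidueSelection) -> list[tuple[int, ...]]:
    """All automorphisms (as index permutations of the selection's atom
    order) generated by the declared symmetry groups: per ring the identity
    and the flip, composed across independent groups."""
    n = len(selection.atom_names)
    index = {name: i for i, name in enumerate(selection.atom_names)}
    identity = tuple(range(n))
    per_group: list[list[tuple[int, ...]]] = []
    for group in selection.symmetry_groups:
        cycle_idx = [index[name] for name in group]
        per_group.append([identity, _flip_permutation(cycle_idx, n)])
    mappings: set[tuple[int, ...]] = {identity}
    for combo in itertools.product(*per_group):
        composed = identity
        for perm in combo:
            composed = tuple(perm[i] for i in composed)
        mappings.add(composed)
    return sorted(mappings)


def _plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def residue_rmsd(
    pose: Pose,
    reference: Pose,
    pose_sel: ResidueSelection,
    ref_sel: ResidueSelection,
) -> DisplacementResult:
    """Symmetry-aware, superposition-free RMSD of a residue's atoms.

    The atom correspondence is positional: the i-th name of ``pose_sel``
    pairs with the i-th name of ``ref_sel`` (the reference residue need not
    be chemically identical to the pose residue).  The RMSD is minimised
    over the automorphisms of both selections; among ties the
    lexicographically smallest pose-side mapping is reported.
    """
    if len(pose_sel.atom_names) != len(ref_sel.atom_names):
        raise ValueError(
            f"selection length mismatch: {len(pose_sel.atom_names)} vs "
            f"{len(ref_sel.atom_names)}"
        )
    p = select_residue(pose, pose_sel)
    r = select_residue(reference, ref_sel)
    best: tuple[float, tuple[int, ...], tuple[int, ...]] | None = None
    for ref_perm in symmetry_mappings(ref_sel):
        r_perm = r[list(ref_perm)]
        for pose_perm in symmetry_mappings(pose_sel):
            val = _plain_rmsd(p[list(pose_perm)], r_perm)
            key = (val, pose_perm, ref_perm)
            if best is None or key < best:
                best = key
    rmsd, pose_perm, ref_perm = best
    mapping = tuple(
        (pose_sel.atom_names[pose_perm[i]], ref_sel.atom_names[ref_perm[i]])
        for i in range(len(pose_perm))
    )
    return DisplacementResult(
        compound_id=pose.compound_id,
        residue_index=pose_sel.residue_index,
        rmsd=rmsd,
        mapping_used=mapping,
        n_atoms=len(mapping),
    )


def best_pose_rmsd(
    poses: Sequence[Pose],
    reference: Pose,
    pose_sel: ResidueSelection,
    ref_sel: ResidueSelection,
    policy: str = "best-score",
) -> DisplacementResult:
    """Displacement of the representative pose of a docking ensemble.

    policy ``best-score``: pose with the lowest (most favourable) score,
    falling back to file order when scores are missing; ``first``: first
    pose; ``min-rmsd``: smallest displacement across all poses (sensitivity
    analysis, not a docking-selection rule).
    """
    if not poses:
        raise ValueError("empty pose list")
    if policy == "first":
        chosen = [poses[0]]
    elif policy == "best-score":
        scored = [p for p in poses if p.score is not None]
        chosen = [min(scored, key=lambda p: p.score)] if scored else [poses[0]]
    elif policy == "min-rmsd":
        chosen = list(poses)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    results = [residue_rmsd(p, reference, pose_sel, ref_sel) for p in chosen]
    return min(results, key=lambda r: r.rmsd)
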