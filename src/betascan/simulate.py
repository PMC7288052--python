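"""Synthetic fixtures with known ground truth.

Docking output and wet-lab assay data are emulated by controlled
simulators so that every downstream computation (displacement RMSD,
descriptor regression, competition and decay fits) can be checked against
the exact truth that generated its input:

* receptor-frame poses: the reference ligand's fourth-residue ring rigidly
  translated by a prescribed magnitude along a random direction, optionally
  ring-flipped (atom relabelling, a pure bookkeeping change) and jittered;
* a linear descriptor–affinity relationship pIC50 = a − b·RMSD + ε;
* one-site competition curves on the assay's 10⁻¹¹–10⁻⁵ M concentration
  ladder;
* first-order decay on the 0–96 h plasma sampling grid.

One integer seed drives an independent named ``numpy`` generator per
sub-simulator, so fixtures are reproducible and streams do not interact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pharmacology import BindingRecord, CompetitionCurve
from .pose_io import RING_ATOM_CYCLE, AtomRecord, Pose
from .stability import PLASMA_TIME_GRID_H, TimeCourse

__all__ = [
    "PoseSimSpec",
    "SarSimSpec",
    "make_reference_ligand",
    "simulate_poses",
    "simulate_sar",
    "simulate_competition",
    "simulate_decay",
    "COMPETITION_CONCENTRATIONS_M",
]

#: Assay concentration ladder, 1e-11 to 1e-5 M (half-log steps).
COMPETITION_CONCENTRATIONS_M: tuple[float, ...] = tuple(
    10.0**e for e in np.arange(-11.0, -4.75, 0.5)
)

#: Documented origin offset of the reference fourth-residue ring centroid, Å.
REFERENCE_RING_CENTROID = np.array([10.0, 2.0, -1.0])

_RING_RADIUS = 1.39  # Å; a regular hexagon's circumradius equals its edge


_STREAM_IDS = {"pose": 1, "sar": 2, "assay": 3, "decay": 4}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Named independent generator stream derived from one integer seed."""
    if stream not in _STREAM_IDS:
        raise ValueError(f"unknown stream {stream!r}")
    return np.random.default_rng([int(seed), _STREAM_IDS[stream]])


@dataclass(frozen=True)
class PoseSimSpec:
    n_compounds: int
    displacement_magnitudes: tuple[float, ...]  # Å, one per compound
    jitter_sigma: float = 0.0  # Å, isotropic per-atom noise
    ring_flip: bool = False  # relabel ring atoms by the 180° flip
    seed: int = 0

    def __post_init__(self) -> None:
        mags = tuple(float(m) for m in self.displacement_magnitudes)
        if len(mags) != self.n_compounds:
            raise ValueError("one displacement magnitude per compound required")
        if any(m < 0 for m in mags):
            raise ValueError("displacement magnitudes must be >= 0")
        object.__setattr__(self, "displacement_magnitudes", mags)


@dataclass(frozen=True)
class SarSimSpec:
    intercept: float = 9.0  # pIC50 at zero displacement
    slope: float = 0.8  # pIC50 lost per Å of displacement
    noise_sigma: float = 0.2  # pIC50 units
    seed: int = 0


def _ring_coordinates(centroid: np.ndarray) -> np.ndarray:
    """Ideal planar hexagon (C–C 1.39 Å) in the xy plane around centroid."""
    angles = np.deg2rad(60.0 * np.arange(6))
    ring = np.stack(
        [np.cos(angles), np.sin(angles), np.zeros(6)], axis=1
    ) * _RING_RADIUS
    return ring + centroid


def make_reference_ligand() -> Pose:
    """Deterministic four-residue peptide-like pose in the receptor frame.

    Residues 1–3 carry minimal backbone atoms along a straight chain;
    residue 4 additionally carries an ideal phenyl ring (atoms named by the
    usual CG/CD/CE/CZ convention, cyclic order ``RING_ATOM_CYCLE``) whose
    centroid sits at ``REFERENCE_RING_CENTROID``.
    """
    atoms: list[AtomRecord] = []
    for i in range(4):
        base = np.array([3.0 * i, 0.0, 0.0])
        for name, offset in (
            ("N", (0.0, 0.0, 0.0)),
            ("CA", (1.2, 0.6, 0.0)),
            ("C", (2.4, 0.0, 0.0)),
            ("O", (2.4, -1.2, 0.0)),
        ):
            x, y, z = base + np.array(offset)
            atoms.append(AtomRecord(name, name[0], i + 1, x, y, z))
    cb = REFERENCE_RING_CENTROID + np.array([-1.5, -1.0, 0.5])
    atoms.append(AtomRecord("CB", "C", 4, *cb))
    ring = _ring_coordinates(REFERENCE_RING_CENTROID)
    for name, xyz in zip(RING_ATOM_CYCLE, ring):
        atoms.append(AtomRecord(name, "C", 4, *xyz))
    return Pose(compound_id="REF", model_id=1, atoms=tuple(atoms), score=None)


def _flip_ring_labels(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Relabel residue-4 ring atoms by the 180° flip (CD1↔CD2, CE1↔CE2).

    The coordinates are untouched: the flip is the chemically equivalent
    alternative naming of the same physical ring.
    """
    k = len(RING_ATOM_CYCLE)
    flip = {
        RING_ATOM_CYCLE[i]: RING_ATOM_CYCLE[(k - i) % k] for i in range(k)
    }
    out = []
    for a in atoms:
        if a.residue_index == 4 and a.atom_name in flip:
            out.append(
                AtomRecord(flip[a.atom_name], a.element, a.residue_index, a.x, a.y, a.z)
            )
        else:
            out.append(a)
    return out


def simulate_poses(spec: PoseSimSpec) -> tuple[list[Pose], pd.DataFrame]:
    """Poses with controlled fourth-residue displacement, plus a truth table.

    Each compound's pose is the reference with every residue-4 atom
    translated by its magnitude along a seeded random unit vector (a rigid
    translation, so the applied RMSD equals the magnitude exactly when
    jitter is zero), optionally ring-flip-relabelled, with isotropic
    Gaussian jitter of ``jitter_sigma`` added to residue-4 atoms last.
    The truth table records the exact post-jitter RMSD actually applied.
    """
    rng = stream_rng(spec.seed, "pose")
    reference = make_reference_ligand()
    ref_ring = np.array(
        [a.xyz for a in reference.atoms if a.residue_index == 4 and a.atom_name in RING_ATOM_CYCLE]
    )
    poses: list[Pose] = []
    rows = []
    for i, magnitude in enumerate(spec.displacement_magnitudes):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        shift = magnitude * direction
        atoms: list[AtomRecord] = []
        ring_new = {}
        for a in reference.atoms:
            if a.residue_index == 4:
                xyz = a.xyz + shift
                if spec.jitter_sigma > 0:
                    xyz = xyz + rng.normal(0.0, spec.jitter_sigma, 3)
                atoms.append(
                    AtomRecord(a.atom_name, a.element, a.residue_index, *xyz)
                )
                if a.atom_name in RING_ATOM_CYCLE:
                    ring_new[a.atom_name] = xyz
            else:
                atoms.append(a)
        if spec.ring_flip:
            atoms = _flip_ring_labels(atoms)
        cid = f"cmpd{i + 1:02d}"
        poses.append(Pose(compound_id=cid, model_id=1, atoms=tuple(atoms)))
        new_ring = np.array([ring_new[n] for n in RING_ATOM_CYCLE])
        applied = float(np.sqrt(np.mean(np.sum((new_ring - ref_ring) ** 2, axis=1))))
        rows.append(
            {"compound_id": cid, "magnitude": magnitude, "applied_rmsd": applied}
        )
    return poses, pd.DataFrame(rows)


def simulate_sar(
    spec: SarSimSpec, rmsds: dict[str, float] | Sequence[tuple[str, float]]
) -> list[BindingRecord]:
    """Binding records from the linear model pIC50 = a − b·RMSD + N(0, σ²).

    The noisy pIC50 is converted back to an IC50 in nM
    (IC50[nM] = 10^(9 − pIC50)).
    """
    rng = stream_rng(spec.seed, "sar")
    items = rmsds.items() if isinstance(rmsds, dict) else rmsds
    records = []
    for cid, rmsd in items:
        p = spec.intercept - spec.slope * rmsd
        if spec.noise_sigma > 0:
            p += rng.normal(0.0, spec.noise_sigma)
        records.append(
            BindingRecord(compound_id=cid, receptor="mu", ic50=10.0 ** (9.0 - p))
        )
    return records


def simulate_competition(
    ic50_nm: float,
    concentrations: Sequence[float] = COMPETITION_CONCENTRATIONS_M,
    sigma: float = 0.0,
    seed: int = 0,
    compound_id: str = "sim",
    top: float = 1.0,
    bottom: float = 0.0,
) -> CompetitionCurve:
    """One-site displacement curve with additive Gaussian noise of
    ``sigma`` (in units of the top−bottom span)."""
    rng = stream_rng(seed, "assay")
    c = np.asarray(concentrations, dtype=float)
    log_ic50 = np.log10(ic50_nm * 1e-9)
    response = bottom + (top - bottom) / (1.0 + 10.0 ** (np.log10(c) - log_ic50))
    if sigma > 0:
        response = response + rng.normal(0.0, sigma * (top - bottom), len(c))
    return CompetitionCurve(
        compound_id=compound_id,
        concentrations=tuple(c),
        responses=tuple(float(r) for r in response),
    )


def simulate_decay(
    t_half_h: float,
    times: Sequence[float] = PLASMA_TIME_GRID_H,
    sigma: float = 0.0,
    seed: int = 0,
    compound_id: str = "sim",
) -> TimeCourse:
    """First-order decay time course with multiplicative log-normal noise
    of coefficient ``sigma`` (fractions stay positive at any noise level)."""
    rng = stream_rng(seed, "decay")
    t = np.asarray(times, dtype=float)
    k = np.log(2.0) / t_half_h
    conc = np.exp(-k * t)
    if sigma > 0:
        conc = conc * np.exp(rng.normal(0.0, sigma, len(t)))
    return TimeCourse(
        compound_id=compound_id,
        times=tuple(t),
        concentrations=tuple(float(x) for x in conc),
    )
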