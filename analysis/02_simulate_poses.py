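#!/usr/bin/env python
"""Generate receptor-frame poses with controlled ring displacement.

Stands in for a docking run: takes the idealized reference ligand (a
four-residue peptide-like pose with an ideal phenyl ring at residue 4),
translates the fourth residue of each synthetic compound by a prescribed
magnitude along a seeded random direction, ring-flips half of them (an
atom-relabelling with no geometric effect) and adds 0.05 Å jitter.

Writes the multi-model reference/compound PDB files and the ground-truth
displacement table, then verifies by re-reading the files that the
symmetry-aware descriptor recovers the applied displacement.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from betascan.displacement import residue_rmsd
from betascan.pose_io import phenyl_ring_selection, read_poses, write_poses
from betascan.simulate import PoseSimSpec, make_reference_ligand, simulate_poses

SEED = 7
N = 11
OUT = Path(__file__).resolve().parents[1] / "results" / "poses"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    reference = make_reference_ligand()
    write_poses(reference, OUT / "reference.pdb")

    magnitudes = tuple(np.linspace(0.3, 4.0, N))
    poses, truth = simulate_poses(
        PoseSimSpec(N, magnitudes, jitter_sigma=0.05, seed=SEED)
    )
    flipped, _ = simulate_poses(
        PoseSimSpec(N, magnitudes, jitter_sigma=0.05, ring_flip=True, seed=SEED)
    )
    for pose in poses:
        write_poses(pose, OUT / f"{pose.compound_id}.pdb")

    sel = phenyl_ring_selection()
    rows = []
    for pose, flip in zip(poses, flipped):
        on_disk = read_poses(OUT / f"{pose.compound_id}.pdb")[0]
        measured = residue_rmsd(on_disk, reference, sel, sel).rmsd
        in_memory = residue_rmsd(pose, reference, sel, sel).rmsd
        relabelled = residue_rmsd(flip, reference, sel, sel).rmsd - in_memory
        rows.append(
            {
                "compound_id": pose.compound_id,
                "measured_rmsd": measured,
                "ring_flip_effect": relabelled,
            }
        )
    table = truth.merge(pd.DataFrame(rows), on="compound_id")
    table.to_csv(OUT / "displacements.csv", index=False)

    print(table.to_string(index=False))
    err = np.abs(table.measured_rmsd - table.applied_rmsd).max()
    flip_err = np.abs(table.ring_flip_effect).max()
    print(f"\nmax |measured - applied| after PDB round trip: {err:.4f} A")
    print(f"max effect of ring relabelling on the descriptor: {flip_err:.2e} A")
    print(f"tables and pose files -> {OUT}")


if __name__ == "__main__":
    main()
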