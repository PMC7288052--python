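"""Symmetry-aware displacement RMSD against the reference pose."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betascan.displacement import best_pose_rmsd, residue_rmsd, symmetry_mappings
from betascan.pose_io import (
    RING_ATOM_CYCLE,
    AtomRecord,
    Pose,
    ResidueSelection,
    phenyl_ring_selection,
)
from betascan.simulate import PoseSimSpec, make_reference_ligand, simulate_poses


def brute_force_rmsd(pose, reference, sel):
    """Independent oracle: naive minimum over all declared automorphisms,
    built directly from the cycle definition (reversal about the first atom)
    and evaluated with explicit loops."""

    def coords(p):
        by = {a.atom_name: (a.x, a.y, a.z) for a in p.atoms if a.residue_index == sel.residue_index}
        return [by[n] for n in sel.atom_names]

    p, r = coords(pose), coords(reference)
    orderings = [list(sel.atom_names)]
    for group in sel.symmetry_groups:
        g = list(group)
        flipped_group = [g[0]] + g[1:][::-1]
        relabel = dict(zip(g, flipped_group))
        new = []
        for order in orderings:
            new.append([relabel.get(n, n) for n in order])
        orderings += new
    name_to_idx = {n: i for i, n in enumerate(sel.atom_names)}
    best = math.inf
    for order in orderings:
        total = 0.0
        for slot, name in enumerate(order):
            pi = p[name_to_idx[name]]
            ri = r[slot]
            total += sum((a - b) ** 2 for a, b in zip(pi, ri))
        best = min(best, math.sqrt(total / len(order)))
    return best


def _translated(pose, vector, residue_index=None):
    atoms = []
    for a in pose.atoms:
        if residue_index is None or a.residue_index == residue_index:
            atoms.append(
                AtomRecord(a.atom_name, a.element, a.residue_index,
                           a.x + vector[0], a.y + vector[1], a.z + vector[2])
            )
        else:
            atoms.append(a)
    return Pose(pose.compound_id, pose.model_id, tuple(atoms), pose.score)


class TestResidueRmsd:
    def test_identity_is_zero(self, reference_pose, ring_selection):
        res = residue_rmsd(reference_pose, reference_pose, ring_selection, ring_selection)
        assert res.rmsd == 0.0
        assert res.n_atoms == 6 == len(res.mapping_used)

    def test_uniform_translation_gives_vector_norm(self, reference_pose, ring_selection):
        moved = _translated(reference_pose, (3.0, 0.0, 0.0))
        res = residue_rmsd(moved, reference_pose, ring_selection, ring_selection)
        assert res.rmsd == pytest.approx(3.0, abs=1e-9)

    def test_ring_flip_relabelling_is_invisible(self, reference_pose, ring_selection):
        poses, _ = simulate_poses(PoseSimSpec(1, (2.0,), ring_flip=True, seed=5))
        res = residue_rmsd(poses[0], reference_pose, ring_selection, ring_selection)
        assert res.rmsd == pytest.approx(2.0, abs=1e-9)

    def test_matches_brute_force_oracle_on_randomized_rings(
        self, reference_pose, ring_selection
    ):
        rng = np.random.default_rng(20)
        for _ in range(100):
            atoms = [
                AtomRecord(name, "C", 4, *rng.normal(0, 5, 3))
                for name in RING_ATOM_CYCLE
            ]
            pose = Pose("rand", 1, tuple(atoms))
            mine = residue_rmsd(pose, reference_pose, ring_selection, ring_selection).rmsd
            oracle = brute_force_rmsd(pose, reference_pose, ring_selection)
            assert mine == pytest.approx(oracle, abs=1e-9)

    def test_selection_length_mismatch_rejected(self, reference_pose, ring_selection):
        short = ResidueSelection(4, ("CG", "CZ"))
        with pytest.raises(ValueError, match="mismatch"):
            residue_rmsd(reference_pose, reference_pose, short, ring_selection)

    def test_cross_residue_positional_correspondence(self, reference_pose):
        """Pose and reference selections may name different atoms; pairing
        is positional (an N-methylated reference residue still maps)."""
        pose_sel = ResidueSelection(4, ("CG", "CZ"))
        ref_sel = ResidueSelection(4, ("CZ", "CG"))
        res = residue_rmsd(reference_pose, reference_pose, pose_sel, ref_sel)
        # CG vs CZ are para across the ring: distance 2 * 1.39
        assert res.rmsd == pytest.approx(2 * 1.39, abs=1e-6)

    def test_symmetry_mapping_count_for_one_ring(self, ring_selection):
        assert len(symmetry_mappings(ring_selection)) == 2

    def test_no_symmetry_groups_means_identity_only(self):
        sel = ResidueSelection(4, ("CG", "CD1"))
        assert symmetry_mappings(sel) == [(0, 1)]


class TestRigidMotionProperties:
    @given(
        vec=st.tuples(
            st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10)
        )
    )
    @settings(derandomize=True, max_examples=25)
    def test_common_translation_cancels(self, vec):
        reference = make_reference_ligand()
        sel = phenyl_ring_selection()
        a = _translated(reference, vec)
        res = residue_rmsd(a, _translated(reference, vec), sel, sel)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    @given(
        vec=st.tuples(
            st.floats(0.1, 10), st.floats(-10, 10), st.floats(-10, 10)
        )
    )
    @settings(derandomize=True, max_examples=25)
    def test_one_sided_translation_adds_its_norm(self, vec):
        reference = make_reference_ligand()
        sel = phenyl_ring_selection()
        moved = _translated(reference, vec)
        res = residue_rmsd(moved, reference, sel, sel)
        # a uniform hexagon translation cannot be improved by the ring flip
        assert res.rmsd <= float(np.linalg.norm(vec)) + 1e-9
        plain = math.sqrt(sum(v * v for v in vec))
        identity_rmsd = brute_force_rmsd(
            moved, reference, ResidueSelection(4, RING_ATOM_CYCLE)
        )
        assert identity_rmsd == pytest.approx(plain, abs=1e-9)


class TestBestPoseRmsd:
    def _ensemble(self, magnitudes, scores, seed=7):
        poses, truth = simulate_poses(PoseSimSpec(len(magnitudes), tuple(magnitudes), seed=seed))
        return [
            Pose("ens", i + 1, p.atoms, score=s)
            for i, (p, s) in enumerate(zip(poses, scores))
        ], truth

    def test_single_pose(self, reference_pose, ring_selection):
        poses, _ = self._ensemble([1.0], [-9.0])
        res = best_pose_rmsd(poses, reference_pose, ring_selection, ring_selection)
        assert res.rmsd == pytest.approx(1.0, abs=1e-9)

    def test_best_score_policy_picks_lowest_score(self, reference_pose, ring_selection):
        poses, _ = self._ensemble([1.0, 2.5], [-9.0, -7.0])
        res = best_pose_rmsd(
            poses, reference_pose, ring_selection, ring_selection, policy="best-score"
        )
        assert res.rmsd == pytest.approx(1.0, abs=1e-9)
        swapped, _ = self._ensemble([1.0, 2.5], [-7.0, -9.0])
        res2 = best_pose_rmsd(
            swapped, reference_pose, ring_selection, ring_selection, policy="best-score"
        )
        assert res2.rmsd == pytest.approx(2.5, abs=1e-9)

    def test_min_rmsd_policy(self, reference_pose, ring_selection):
        poses, _ = self._ensemble([2.5, 1.0], [-9.0, -7.0])
        res = best_pose_rmsd(
            poses, reference_pose, ring_selection, ring_selection, policy="min-rmsd"
        )
        assert res.rmsd == pytest.approx(1.0, abs=1e-9)

    def test_empty_list_rejected(self, reference_pose, ring_selection):
        with pytest.raises(ValueError):
            best_pose_rmsd([], reference_pose, ring_selection, ring_selection)
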