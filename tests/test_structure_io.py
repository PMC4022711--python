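"""Structure/ensemble I/O, selections, superposition and RMSD."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import allopath as ap
from allopath.errors import (
    CongruenceError,
    DegenerateFitError,
    ParseError,
    SelectionError,
)

from .conftest import bead_ensemble, bead_model
from .oracles import quaternion_superpose_rmsd


def _multi_model_pdb(tmp_path, frames):
    ens = bead_ensemble(frames)
    p = tmp_path / "traj.pdb"
    ap.write_ensemble(p, ens)
    return p


class TestReadStructure:
    def test_minimal_file_positions_echoed(self, minimal_pdb):
        model = ap.read_structure(minimal_pdb)
        assert model.n_atoms == 2
        np.testing.assert_allclose(model.coords[0], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(model.coords[1], [4.8, 2.0, 3.0])
        assert model.atoms[0].residue_number == 1
        assert model.atoms[1].atom_name == "CA"

    def test_model_index_picks_second_model(self, tmp_path, rng):
        frames = rng.normal(size=(3, 4, 3)) * 5
        p = _multi_model_pdb(tmp_path, frames)
        m1 = ap.read_structure(p, model_index=1)
        np.testing.assert_allclose(m1.coords, frames[1], atol=1e-3)

    def test_missing_model_index(self, minimal_pdb):
        with pytest.raises(IndexError):
            ap.read_structure(minimal_pdb, model_index=3)

    def test_duplicate_atom_rejected(self, tmp_path):
        text = (
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        p = tmp_path / "dup.pdb"
        p.write_text(text)
        with pytest.raises(ParseError, match="duplicate"):
            ap.read_structure(p)


class TestReadEnsemble:
    def test_one_frame_per_model(self, tmp_path, rng):
        frames = rng.normal(size=(3, 5, 3)) * 4
        ens = ap.read_ensemble(_multi_model_pdb(tmp_path, frames))
        assert ens.n_frames == 3 and ens.n_atoms == 5
        np.testing.assert_allclose(ens.coords, frames, atol=1e-3)

    def test_single_model_is_one_frame(self, minimal_pdb):
        ens = ap.read_ensemble(minimal_pdb)
        assert ens.n_frames == 1

    def test_incongruent_models_rejected(self, tmp_path):
        lines = ["MODEL        1",
                 "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C",
                 "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C",
                 "ENDMDL",
                 "MODEL        2",
                 "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C",
                 "ENDMDL", "END"]
        p = tmp_path / "bad.pdb"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(CongruenceError):
            ap.read_ensemble(p)

    def test_roundtrip_to_pdb_precision(self, tmp_path, rng):
        frames = rng.normal(size=(4, 6, 3)) * 10
        ens = bead_ensemble(frames)
        p = tmp_path / "rt.pdb"
        ap.write_ensemble(p, ens)
        back = ap.read_ensemble(p)
        np.testing.assert_allclose(back.coords, ens.coords, atol=1e-3)
        assert back.topology.atom_keys() == ens.topology.atom_keys()

    def test_times_follow_stride(self, tmp_path, rng):
        frames = rng.normal(size=(3, 4, 3))
        ens = ap.read_ensemble(_multi_model_pdb(tmp_path, frames), dt=4.0)
        np.testing.assert_allclose(ens.times, [0.0, 4.0, 8.0])


class TestSelect:
    def test_wpd_loop_ca_count(self):
        model = ap.make_reference_chain(298, "helix")
        sel = ap.select(model, "name CA and resid 177-185")
        assert len(sel) == 9
        assert [model.atoms[i].residue_number for i in sel.atom_indices] == \
            list(range(177, 186))

    def test_all_ca_of_short_chain(self):
        model = ap.make_reference_chain(10)
        assert len(ap.select(model, "name CA")) == 10

    def test_absent_residue_is_an_error(self):
        model = ap.make_reference_chain(10)
        with pytest.raises(SelectionError):
            ap.select(model, "resid 99")

    def test_sidechain_excludes_backbone(self):
        atoms = [
            ap.Atom(1, "N", "TRP", "A", 179, "N", np.zeros(3)),
            ap.Atom(2, "CA", "TRP", "A", 179, "C", np.ones(3)),
            ap.Atom(3, "CB", "TRP", "A", 179, "C", np.ones(3) * 2),
            ap.Atom(4, "CG", "TRP", "A", 179, "C", np.ones(3) * 3),
        ]
        model = ap.StructureModel(atoms)
        sel = ap.select(model, "resid 179 and sidechain")
        assert [model.atoms[i].atom_name for i in sel.atom_indices] == ["CB", "CG"]


class TestKabsch:
    def test_pure_rotation_translation_recovered(self, rng):
        ref = rng.normal(size=(8, 3)) * 5
        theta = np.pi / 2
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        mobile = ref @ R.T + np.array([1.0, -2.0, 3.0])
        aligned, rot, trans, rmsd = ap.kabsch_superpose(mobile, ref)
        assert rmsd < 1e-10
        np.testing.assert_allclose(aligned, ref, atol=1e-10)
        assert np.isclose(np.linalg.det(rot), 1.0)

    def test_identity_on_self(self, rng):
        ref = rng.normal(size=(5, 3))
        aligned, rot, _, rmsd = ap.kabsch_superpose(ref, ref)
        assert rmsd < 1e-12
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(20):
            mobile = rng.normal(size=(6, 3)) * 3
            ref = rng.normal(size=(6, 3)) * 3
            _, _, _, rmsd = ap.kabsch_superpose(mobile, ref)
            assert abs(rmsd - quaternion_superpose_rmsd(mobile, ref)) < 1e-8

    def test_too_few_fit_atoms(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0]])
        with pytest.raises(DegenerateFitError):
            ap.kabsch_superpose(pts, pts + 1)

    def test_collinear_fit_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateFitError):
            ap.kabsch_superpose(pts, pts[::-1])

    def test_idempotent_alignment(self, rng):
        mobile = rng.normal(size=(7, 3)) * 4
        ref = rng.normal(size=(7, 3)) * 4
        once, _, _, _ = ap.kabsch_superpose(mobile, ref)
        twice, _, _, _ = ap.kabsch_superpose(once, ref)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_rmsd_symmetric(self, rng):
        a = rng.normal(size=(6, 3)) * 2
        b = rng.normal(size=(6, 3)) * 2
        _, _, _, r_ab = ap.kabsch_superpose(a, b)
        _, _, _, r_ba = ap.kabsch_superpose(b, a)
        assert abs(r_ab - r_ba) < 1e-10


class TestRmsdSeries:
    def test_identical_frames_zero(self):
        ref = ap.make_reference_chain(6, "helix")
        frames = np.tile(ref.coords, (4, 1, 1))
        series = ap.rmsd_series(bead_ensemble(frames), ref)
        assert series.shape == (4, 2)
        np.testing.assert_allclose(series[:, 1], 0.0, atol=1e-10)

    def test_internal_distortion_gives_hand_value(self):
        # symmetric in/out distortion: no net translation or rotation to
        # remove, so aligned RMSD equals sqrt(sum d^2 / n) exactly
        ref = bead_model([[-3.0, 0, 0], [-1, 0, 0], [1, 0, 0], [3, 0, 0],
                          [0, 2, 0], [0, -2, 0]])
        distorted = ref.coords.copy()
        distorted[0, 0] -= 1.0   # stretch outer pair apart along x
        distorted[3, 0] += 1.0
        frames = np.stack([ref.coords, distorted])
        series = ap.rmsd_series(bead_ensemble(frames), ref)
        expected = np.sqrt(2.0 / 6.0)  # two atoms moved 1 Å each, n = 6
        assert abs(series[1, 1] - expected) < 1e-9
        assert series[0, 1] < 1e-12


class TestSliceFrames:
    def test_window_and_stride_count(self):
        ref = ap.make_reference_chain(4)
        frames = np.tile(ref.coords, (100, 1, 1))
        ens = ap.Ensemble(ref, frames, np.arange(100, dtype=float))
        out = ap.slice_frames(ens, 20.0, 99.0, stride=4)
        assert out.n_frames == 20
        assert out.times[0] == 20.0 and out.times[-1] == 96.0

    def test_full_range_stride_one_is_identity(self):
        ref = ap.make_reference_chain(4)
        frames = np.tile(ref.coords, (10, 1, 1))
        ens = ap.Ensemble(ref, frames, np.arange(10, dtype=float))
        out = ap.slice_frames(ens, 0.0, 9.0, stride=1)
        np.testing.assert_array_equal(out.coords, ens.coords)

    def test_empty_window_is_an_error(self):
        ref = ap.make_reference_chain(4)
        frames = np.tile(ref.coords, (10, 1, 1))
        ens = ap.Ensemble(ref, frames, np.arange(10, dtype=float))
        with pytest.raises(ValueError):
            ap.slice_frames(ens, 50.0, 60.0)


@given(st.integers(0, 2 ** 31 - 1))
def test_superposition_idempotence_property(seed):
    rng = np.random.default_rng(seed)
    mobile = rng.normal(size=(5, 3)) * 3
    ref = rng.normal(size=(5, 3)) * 3
    once, _, _, r1 = ap.kabsch_superpose(mobile, ref)
    twice, _, _, r2 = ap.kabsch_superpose(once, ref)
    assert np.abs(once - twice).max() < 1e-10
    assert abs(r1 - r2) < 1e-10
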