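"""Kabsch superposition, RMSF, AF2-score and concordance statistics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import t as student_t

from flexrin.errors import GeometryError, MismatchError, ParameterError
from flexrin.flexibility import (
    FlexProfile,
    RmsdSeries,
    af2_score,
    pearson_concordance,
    rmsd_series,
    rmsf,
    superpose,
    tail_mean,
)
from flexrin.structure import Ensemble, PlddtProfile, StructureFrame
from flexrin.synthetic import SynthSpec, make_base_fold, sample_ensemble


def rigid(points, seed=0, angle_deg=None):
    rng = np.random.default_rng(seed)
    R = (Rotation.from_euler("z", angle_deg, degrees=True) if angle_deg is not None
         else Rotation.random(rng=rng)).as_matrix()
    t = rng.uniform(-5, 5, 3)
    return points @ R.T + t, R, t


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        tr, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_rotation_translation(self):
        ref = np.random.default_rng(1).normal(size=(8, 3))
        mobile, R, t = rigid(ref, seed=2, angle_deg=90)
        tr, rmsd = superpose(mobile, ref)
        assert rmsd < 1e-9
        np.testing.assert_allclose(tr.apply(mobile), ref, atol=1e-9)

    def test_mirror_image_never_yields_reflection(self):
        chiral = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        mirror = chiral * np.array([1, 1, -1.0])
        tr, rmsd = superpose(mirror, chiral)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_scipy_cross_check(self):
        """Independent route: scipy's constrained alignment agrees on RMSD."""
        ref = np.random.default_rng(3).normal(size=(12, 3))
        mobile = ref + np.random.default_rng(4).normal(scale=0.3, size=ref.shape)
        tr, rmsd = superpose(mobile, ref)
        rot, rssd = Rotation.align_vectors(ref - ref.mean(0), mobile - mobile.mean(0))
        assert rmsd == pytest.approx(rssd / np.sqrt(len(ref)), rel=1e-9)

    def test_degenerate_inputs(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(GeometryError):
            superpose(line, line)
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsf:
    def test_identical_frames_give_zero(self):
        base = make_base_fold(10)
        spec = SynthSpec(n_residues=10, sigma_profile=np.zeros(10), n_frames=4, seed=0)
        profile = rmsf(sample_ensemble(base, spec))
        np.testing.assert_allclose(profile.values, 0.0, atol=1e-12)

    def test_two_frame_displacement_halves(self):
        """Residue moved by d between two frames -> RMSF d/2 (variance identity)."""
        base = make_base_fold(10)
        moved = make_base_fold(10)
        d = 1.6
        for a in moved.residues[4].atoms:
            a.coords = a.coords + np.array([0, 0, d])
        ens = Ensemble([base, moved])
        profile = rmsf(ens, do_superpose=False)
        assert profile.values[4] == pytest.approx(d / 2)

    def test_invariant_under_global_rigid_motion(self, jittered_ensemble):
        ref = rmsf(jittered_ensemble, do_superpose=True)
        frames = []
        for k, frame in enumerate(jittered_ensemble.frames):
            residues = []
            for r in frame.residues:
                atoms = []
                for a in r.atoms:
                    moved, _, _ = rigid(a.coords[None, :], seed=k, angle_deg=15.0 * k)
                    atoms.append(type(a)(a.serial, a.name, a.element, moved[0],
                                         a.bfactor, a.occupancy))
                residues.append(type(r)(r.chain_id, r.seq_id, r.res_name, atoms, r.kind))
            frames.append(StructureFrame(residues, frame_label=frame.frame_label))
        moved_profile = rmsf(Ensemble(frames), do_superpose=True)
        np.testing.assert_allclose(moved_profile.values, ref.values, atol=1e-9)

    def test_heavy_selection_and_single_frame_error(self, jittered_ensemble):
        # rigid-residue jitter moves every atom of a residue together, so the
        # heavy-atom average equals the Cα value (superposition off: a frame
        # fit would rotate atoms at different offsets differently)
        heavy = rmsf(jittered_ensemble, atom_selection="heavy", do_superpose=False)
        ca = rmsf(jittered_ensemble, atom_selection="CA", do_superpose=False)
        np.testing.assert_allclose(heavy.values, ca.values, rtol=1e-9)
        with pytest.raises(ParameterError):
            rmsf(Ensemble([jittered_ensemble.frames[0]]))


class TestAf2Score:
    def test_direct_substitution(self):
        profile = PlddtProfile([("A", 1), ("A", 2), ("A", 3)], [90.0, 70.0, 50.0])
        np.testing.assert_allclose(af2_score(profile).values, [0.0, 0.5, 1.0])

    def test_constant_profile_maps_to_zeros_with_warning(self, caplog):
        profile = PlddtProfile([("A", i) for i in range(3)], [80.0] * 3)
        with caplog.at_level("WARNING"):
            scores = af2_score(profile)
        np.testing.assert_array_equal(scores.values, 0.0)
        assert any("constant" in r.message for r in caplog.records)

    def test_affine_invariance_and_span(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(40, 95, 30)
        keys = [("A", i + 1) for i in range(30)]
        s1 = af2_score(PlddtProfile(keys, v)).values
        s2 = af2_score(PlddtProfile(keys, np.clip(0.4 * v + 30.0, 0, 100))).values
        np.testing.assert_allclose(s1, s2, atol=1e-12)
        assert s1.min() == 0.0 and s1.max() == 1.0


class TestConcordance:
    def keys(self, n):
        return [("A", i + 1) for i in range(n)]

    def test_affine_relation_is_perfect(self):
        a = FlexProfile(self.keys(5), [1, 2, 3, 4, 5.0])
        b = FlexProfile(self.keys(5), [3, 5, 7, 9, 11.0])
        result = pearson_concordance(a, b)
        assert result.pcc == pytest.approx(1.0, abs=1e-12)
        assert result.p_value < 1e-6

    def test_four_point_textbook_case(self):
        """r = 0.8 with p from t = r sqrt((n-2)/(1-r^2)), n = 4."""
        a = FlexProfile(self.keys(4), [1, 2, 3, 4.0])
        b = FlexProfile(self.keys(4), [1, 3, 2, 4.0])
        result = pearson_concordance(a, b)
        assert result.pcc == pytest.approx(0.8, abs=1e-12)
        t_stat = 0.8 * np.sqrt(2 / (1 - 0.64))
        assert result.p_value == pytest.approx(2 * student_t.sf(t_stat, df=2), rel=1e-6)

    def test_anticorrelation_and_errors(self):
        a = FlexProfile(self.keys(4), [1, 2, 3, 4.0])
        neg = FlexProfile(self.keys(4), [4, 3, 2, 1.0])
        assert pearson_concordance(a, neg).pcc == pytest.approx(-1.0, abs=1e-12)
        with pytest.raises(ParameterError):
            pearson_concordance(a, FlexProfile(self.keys(4), [2, 2, 2, 2.0]))
        with pytest.raises(MismatchError):
            pearson_concordance(a, FlexProfile([("B", 1)] + self.keys(4)[1:], [1, 2, 3, 4.0]))


class TestRmsdSeries:
    def test_reference_and_rigid_motion(self, jittered_ensemble):
        series = rmsd_series(jittered_ensemble, reference_frame=0)
        assert series.values[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(series.values >= 0)

    def test_translated_frame_reads_zero(self):
        base = make_base_fold(8)
        shifted = make_base_fold(8)
        for r in shifted.residues:
            for a in r.atoms:
                a.coords = a.coords + np.array([3.0, -2.0, 1.0])
        series = rmsd_series(Ensemble([base, shifted]))
        assert series.values[1] == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_matches_direct_formula(self):
        base = make_base_fold(40)
        moved = make_base_fold(40)
        d = 2.0
        ca = moved.residues[20].atom("CA")
        ca.coords = ca.coords + np.array([0, 0, d])
        # oracle: unsuperposed RMSD bound sqrt(d^2 / N); refit can only lower it
        bound = np.sqrt(d ** 2 / 40)
        series = rmsd_series(Ensemble([base, moved]))
        assert 0 < series.values[1] <= bound + 1e-12

    def test_bad_reference_index(self, jittered_ensemble):
        with pytest.raises(ParameterError):
            rmsd_series(jittered_ensemble, reference_frame=999)


@pytest.mark.parametrize(
    "values, fraction, expected",
    [([2.0, 2.0, 2.0], 1.0, (2.0, 0.0)),
     ([1, 2, 3, 4.0], 0.5, (3.5, 0.5)),
     ([1, 2, 3, 4.0], 1.0, (2.5, np.std([1, 2, 3, 4.0])))],
)
def test_tail_mean(values, fraction, expected):
    series = RmsdSeries([str(i) for i in range(len(values))], np.array(values))
    mean, sd = tail_mean(series, fraction)
    assert mean == pytest.approx(expected[0])
    assert sd == pytest.approx(expected[1])


def test_tail_mean_validation():
    series = RmsdSeries(["1"], np.array([1.0]))
    with pytest.raises(ParameterError):
        tail_mean(series, 0.0)
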