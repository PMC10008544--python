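"""Sequence pairing, rigid ligand grafting, clash checks, binding sites."""


import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from flexrin.dynrin import interaction_frequency, per_frame_rins
from flexrin.errors import ParameterError
from flexrin.structure import StructureFrame
from flexrin.synthetic import LigandSchedule, SynthSpec, make_base_fold, sample_ensemble
from flexrin.transfer import (
    ResiduePairing,
    binding_site_residues,
    clash_check,
    pair_by_alignment,
    transfer_ligands,
    transfer_transform,
)


def holo_frame(n_res=25, target=12, seed=0):
    base = make_base_fold(n_res)
    spec = SynthSpec(n_residues=n_res, sigma_profile=np.zeros(n_res), n_frames=1,
                     seed=seed, ligand_schedules=[LigandSchedule("BVQ", ("A", target), 1.0)])
    return sample_ensemble(base, spec).frames[0]


def apply_rigid(frame, R, t):
    residues = []
    for r in frame.residues:
        atoms = [type(a)(a.serial, a.name, a.element, R @ a.coords + t, a.bfactor,
                         a.occupancy) for a in r.atoms]
        residues.append(type(r)(r.chain_id, r.seq_id, r.res_name, atoms, r.kind))
    return StructureFrame(residues, frame_label=frame.frame_label)


class TestPairByAlignment:
    def test_identity(self):
        pairing = pair_by_alignment("ACDEF", "ACDEF")
        assert len(pairing) == 5
        assert pairing.pairs[0] == (("A", 1), ("A", 1))

    def test_leading_deletion_skips_template(self):
        pairing = pair_by_alignment("MKLVAACDEF", "ACDEF")
        assert len(pairing) == 5
        assert pairing.pairs[0] == (("A", 6), ("A", 1))
        assert pairing.pairs[-1] == (("A", 10), ("A", 5))

    def test_all_mismatch_three_mers_score_is_optimal(self):
        """Exhaustive enumeration of global alignments of two 3-mers."""
        a, b = "AAA", "CCC"
        match, mismatch, gap = 1.0, 0.0, -1.0

        def score_all(i, j):
            # best global alignment score of a[i:], b[j:] by brute recursion
            if i == len(a) and j == len(b):
                return 0.0
            best = -np.inf
            if i < len(a) and j < len(b):
                best = max(best, (match if a[i] == b[j] else mismatch)
                           + score_all(i + 1, j + 1))
            if i < len(a):
                best = max(best, gap + score_all(i + 1, j))
            if j < len(b):
                best = max(best, gap + score_all(i, j + 1))
            return best

        pairing = pair_by_alignment(a, b, match=match, mismatch=mismatch, gap=gap)
        achieved = sum(mismatch for _ in pairing.pairs) \
            - abs(len(a) - len(pairing.pairs)) - abs(len(b) - len(pairing.pairs))
        assert len(pairing) == 3  # global alignment still pairs everything
        assert achieved == pytest.approx(score_all(0, 0))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            pair_by_alignment("", "ACD")

    def test_one_to_one_enforced(self):
        with pytest.raises(ParameterError):
            ResiduePairing([(("A", 1), ("A", 1)), (("A", 1), ("A", 2))])


class TestTransferLigands:
    def identity_pairing(self, frame):
        return ResiduePairing([(k, k) for k in frame.residue_keys])

    def test_identity_model(self):
        holo = holo_frame()
        apo = StructureFrame(holo.residues, [], "apo")
        grafted, _, rmsd = transfer_ligands(holo, apo, self.identity_pairing(holo))
        assert rmsd < 1e-9
        np.testing.assert_allclose(
            grafted.ligand("BVQ").heavy_coords(),
            holo.ligand("BVQ").heavy_coords(), atol=1e-9)

    def test_known_rigid_motion_is_reproduced(self):
        holo = holo_frame()
        rng = np.random.default_rng(8)
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-10, 10, 3)
        model = apply_rigid(StructureFrame(holo.residues, [], "m"), R, t)
        grafted, _, rmsd = transfer_ligands(holo, model, self.identity_pairing(holo))
        assert rmsd < 1e-9
        expected = holo.ligand("BVQ").heavy_coords() @ R.T + t
        err = np.abs(grafted.ligand("BVQ").heavy_coords() - expected).max()
        assert err < 1e-6

    def test_noisy_model_bounded_by_superposition_rmsd(self):
        """Coordinate noise moves the grafted group by at most ~the fit RMSD."""
        holo = holo_frame(n_res=40)
        worst = 0.0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            residues = []
            for r in holo.residues:
                atoms = [type(a)(a.serial, a.name, a.element,
                                 a.coords + rng.normal(0, 0.5, 3), a.bfactor,
                                 a.occupancy) for a in r.atoms]
                residues.append(type(r)(r.chain_id, r.seq_id, r.res_name, atoms, r.kind))
            model = StructureFrame(residues, [], "noisy")
            grafted, _, rmsd = transfer_ligands(holo, model, self.identity_pairing(holo))
            shift = np.linalg.norm(
                grafted.ligand("BVQ").heavy_coords() - holo.ligand("BVQ").heavy_coords(),
                axis=1).max()
            worst = max(worst, shift)
            assert shift < 1.0
        assert worst > 0  # noise did move the placement

    def test_composition_of_motions(self):
        holo = holo_frame()
        apo = StructureFrame(holo.residues, [], "apo")
        rng = np.random.default_rng(9)
        Ra = Rotation.random(rng=rng).as_matrix()
        ta = rng.uniform(-3, 3, 3)
        Rb = Rotation.random(rng=rng).as_matrix()
        tb = rng.uniform(-3, 3, 3)
        m_ab = apply_rigid(apply_rigid(apo, Ra, ta), Rb, tb)
        m_direct = apply_rigid(apo, Rb @ Ra, Rb @ ta + tb)
        pa = self.identity_pairing(holo)
        tr1, _ = transfer_transform(holo, m_ab, pa)
        tr2, _ = transfer_transform(holo, m_direct, pa)
        np.testing.assert_allclose(tr1.rotation, tr2.rotation, atol=1e-9)
        np.testing.assert_allclose(tr1.translation, tr2.translation, atol=1e-8)

    def test_no_ligands_to_transfer(self):
        apo = StructureFrame(make_base_fold(10).residues, [], "apo")
        with pytest.raises(ParameterError):
            transfer_ligands(apo, apo, self.identity_pairing(apo))

    def test_grafted_complex_round_trips_pdb(self, tmp_path):
        from flexrin.structure import read_multimodel_pdb, write_multimodel_pdb

        holo = holo_frame()
        apo = StructureFrame(holo.residues, [], "apo")
        grafted, _, _ = transfer_ligands(holo, apo, self.identity_pairing(holo))
        path = tmp_path / "complex.pdb"
        write_multimodel_pdb(grafted, path)
        back = read_multimodel_pdb(path)
        assert [g.label for g in back.frames[0].ligands] == ["BVQ"]
        np.testing.assert_allclose(
            back.frames[0].ligand("BVQ").heavy_coords(),
            grafted.ligand("BVQ").heavy_coords(), atol=1e-3)


class TestClashCheck:
    def test_distant_ligand_is_clean(self):
        holo = holo_frame()  # placed at 3.0 Å, beyond the 2.0 Å clash cutoff
        assert clash_check(holo, holo.ligand("BVQ"), 2.0) == []

    def test_coincident_atom_reports_zero_distance(self):
        holo = holo_frame()
        lig = holo.ligand("BVQ")
        lig.residues[0].atoms[0].coords = holo.residues[0].atom("CA").coords.copy()
        clashes = clash_check(holo, lig, 2.0)
        assert clashes and clashes[0][2] == pytest.approx(0.0)

    def test_zero_cutoff_always_empty(self):
        holo = holo_frame()
        lig = holo.ligand("BVQ")
        lig.residues[0].atoms[0].coords = holo.residues[0].atom("CA").coords.copy()
        assert clash_check(holo, lig, 0.0) == []


class TestBindingSite:
    def test_exact_contact_set(self):
        holo = holo_frame(target=12)
        sites = binding_site_residues(holo)
        assert ("A", 12) in sites["BVQ"]

    def test_no_contacts_when_far(self):
        base = make_base_fold(20)
        spec = SynthSpec(n_residues=20, sigma_profile=np.zeros(20), n_frames=1, seed=0,
                         ligand_schedules=[LigandSchedule("PFO", ("A", 10), 0.0)])
        frame = sample_ensemble(base, spec).frames[0]
        assert binding_site_residues(frame)["PFO"] == []

    def test_consistent_with_dynamic_frequencies_on_static_ensemble(self):
        """Single-frame pocket equals 100%/0% rows of the frequency table."""
        base = make_base_fold(20)
        spec = SynthSpec(n_residues=20, sigma_profile=np.zeros(20), n_frames=10, seed=0,
                         ligand_schedules=[LigandSchedule("BVQ", ("A", 10), 1.0)])
        ens = sample_ensemble(base, spec)
        table = interaction_frequency(per_frame_rins(ens), "BVQ")
        hundred = {k for k, pct in table.percents().items() if pct == 100.0}
        assert set(binding_site_residues(ens.frames[0])["BVQ"]) == hundred
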