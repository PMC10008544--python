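import numpy as np
import pytest

from flexrin.structure import AtomRecord, ResidueNode, StructureFrame
from flexrin.synthetic import (
    LigandSchedule,
    SynthSpec,
    make_base_fold,
    ramp_sigma_profile,
    sample_ensemble,
)


def make_residue(seq_id, coords_by_name, res_name="ALA", chain="A", kind="polymer",
                 bfactor=0.0, elements=None):
    """Hand-placed residue for toy geometry tests."""
    atoms = []
    for k, (name, xyz) in enumerate(coords_by_name.items()):
        elem = (elements or {}).get(name, name[0])
        atoms.append(AtomRecord(serial=k + 1, name=name, element=elem,
                                coords=np.asarray(xyz, float), bfactor=bfactor))
    return ResidueNode(chain_id=chain, seq_id=seq_id, res_name=res_name,
                       atoms=atoms, kind=kind)


@pytest.fixture
def base_fold_50():
    return make_base_fold(50, gly_positions=(9,))


@pytest.fixture
def small_scheduled_ensemble():
    """Static 30-residue fold with one ligand contacting residue 15 in 80/100 frames."""
    spec = SynthSpec(
        n_residues=30,
        sigma_profile=np.zeros(30),
        n_frames=100,
        seed=7,
        ligand_schedules=[LigandSchedule("BVQ", ("A", 15), 0.80)],
    )
    base = make_base_fold(30)
    return sample_ensemble(base, spec)


@pytest.fixture
def jittered_ensemble():
    """Rigid-core/flexible-termini ensemble, 40 residues, 60 frames."""
    n = 40
    spec = SynthSpec(n_residues=n, sigma_profile=ramp_sigma_profile(n),
                     n_frames=60, seed=3)
    return sample_ensemble(make_base_fold(n), spec)
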