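"""Shared study design for the numbered analysis scripts.

Defines the synthetic systems every script uses: five trajectory-like
ensembles of one fold whose confidence tracks degrade from perfectly
informative to heavily blurred (emulating complexes that progressively
lose their cofactors), plus one model-population ensemble.  System 1
additionally carries four scheduled ligand vertices — a corrinoid-like
cofactor (BVQ), two iron-sulfur-like clusters (FS4A, FS4B) and a
substrate (PFO) — with designed per-residue contact fractions spanning
the 15-100% range.

Heavy intermediate data (multi-model PDBs) goes under scratch/; summary
tables belong in results/.
"""

from pathlib import Path

import numpy as np

from flexrin.synthetic import (
    LigandSchedule,
    SynthSpec,
    ramp_sigma_profile,
    write_synthetic_system,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis_systems"
RESULTS = ROOT / "results"

N_RESIDUES = 60
N_FRAMES = 100
BASE_SEED = 20240901

# (label, plddt_noise_sd, ligand schedules)
LIGANDS_SYSTEM1 = [
    # labels double as PDB residue names: FSA/FSB are the two
    # iron-sulfur-like clusters
    LigandSchedule("BVQ", ("A", 30), 1.00),   # buried cofactor, permanent contact
    LigandSchedule("FSA", ("A", 44), 0.82),
    LigandSchedule("FSB", ("A", 50), 0.15),   # transient cluster contact
    LigandSchedule("PFO", ("A", 36), 0.40),   # substrate, intermittent
]
SYSTEM_DESIGNS = [
    ("sys1_full_complex", 0.0, LIGANDS_SYSTEM1),
    ("sys2_apo", 20.0, []),
    ("sys3_cofactor_only", 18.0, []),
    ("sys4_clusters_only", 15.0, []),
    ("sys5_holo_no_substrate", 8.0, []),
    ("sys6_model_population", 2.0, []),
]


def system_spec(label: str, noise_sd: float, schedules) -> SynthSpec:
    return SynthSpec(
        n_residues=N_RESIDUES,
        sigma_profile=ramp_sigma_profile(N_RESIDUES, sigma_core=0.5,
                                         sigma_term=2.5, ramp_length=10),
        n_frames=N_FRAMES,
        seed=BASE_SEED + SYSTEM_INDEX[label],
        plddt_noise_sd=noise_sd,
        ligand_schedules=list(schedules),
    )


SYSTEM_INDEX = {label: k for k, (label, _, _) in enumerate(SYSTEM_DESIGNS)}


def ensure_systems() -> dict[str, dict]:
    """Generate (or reuse) all study systems; returns label -> file paths."""
    out = {}
    for label, noise_sd, schedules in SYSTEM_DESIGNS:
        outdir = SCRATCH / label
        if not (outdir / "ensemble.pdb").exists():
            write_synthetic_system(outdir, system_spec(label, noise_sd, schedules))
        out[label] = {
            "pdb": outdir / "ensemble.pdb",
            "confidence": outdir / "confidence.json",
            "sigma": outdir / "sigma.csv",
        }
    RESULTS.mkdir(exist_ok=True)
    return out
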