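"""Ground-truth conformer ensembles with known flexibility and contacts.

Real reductive-dehalogenase trajectories and predicted-model populations are
large and rarely deposited, so the test bed is synthetic: an idealized
helical fold, rigid-residue Gaussian jitter with a prescribed per-residue
amplitude profile (rigid core, mobile termini), confidence profiles built to
anti-correlate with that amplitude, and ligand groups whose contacts with
chosen residues occur in an exact, prescribed fraction of frames.

Every quantity downstream modules estimate (RMSF, concordance, contact
frequency) therefore has a closed-form ground truth:

* isotropic per-coordinate jitter of s.d. sigma gives RMSF -> sqrt(3)*sigma;
* noise-free confidence is an affine map of sigma, so the rank/Pearson
  concordance with flexibility is exactly 1;
* contact fractions are realized by exact frame counts, not Bernoulli draws.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .structure import (
    AtomRecord,
    Ensemble,
    LigandGroup,
    PlddtProfile,
    ResidueNode,
    StructureFrame,
)

logger = logging.getLogger(__name__)

# idealized helix: 1.5 Å rise and 100 deg twist per residue on a 2.3 Å radius
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST_DEG = 100.0


@dataclass
class LigandSchedule:
    """One ligand vertex and its designed contact behaviour.

    In ``round(contact_fraction * n_frames)`` frames (an exact count, chosen
    without replacement) the ligand's nearest heavy atom sits ``d_on`` Å from
    the target residue's Cβ (Cα for Gly); in all others, ``d_off`` Å.
    """

    label: str
    target_key: tuple[str, int]
    contact_fraction: float
    d_on: float = 3.0
    d_off: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ParameterError("contact_fraction must lie in [0, 1]")
        if not self.d_on < 3.5 < self.d_off:
            raise ParameterError("need d_on < 3.5 Å < d_off")
        if not 1 <= len(self.label) <= 3:
            # ligand labels double as PDB residue names (3-char field)
            raise ParameterError("ligand label must be 1-3 characters")


@dataclass
class SynthSpec:
    """Parameters of one synthetic system.

    ``sigma_profile`` is the per-residue, per-coordinate jitter s.d. in Å.
    Use :func:`ramp_sigma_profile` for the canonical rigid-core /
    flexible-termini shape.  ``plddt_slope`` is the confidence lost per Å of
    jitter; ``plddt_noise_sd`` blurs the confidence-flexibility relation.
    """

    n_residues: int
    sigma_profile: np.ndarray
    n_frames: int = 100
    seed: int = 0
    plddt_slope: float = 10.0
    plddt_noise_sd: float = 0.0
    ligand_schedules: list[LigandSchedule] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sigma_profile = np.asarray(self.sigma_profile, dtype=float)
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if len(self.sigma_profile) != self.n_residues:
            raise ParameterError("sigma_profile length must equal n_residues")
        if np.any(self.sigma_profile < 0):
            raise ParameterError("sigma values must be >= 0")


def ramp_sigma_profile(
    n_residues: int,
    sigma_core: float = 0.5,
    sigma_term: float = 2.5,
    ramp_length: int = 10,
) -> np.ndarray:
    """Rigid core, flexible termini: linear ramps of ``ramp_length`` residues."""
    if sigma_core <= 0 or sigma_term <= 0:
        raise ParameterError("sigma values must be > 0")
    sigma = np.full(n_residues, sigma_core)
    L = min(ramp_length, n_residues // 2)
    if L > 0:
        ramp = np.linspace(sigma_term, sigma_core, L + 1)[:-1]
        sigma[:L] = ramp
        sigma[n_residues - L:] = ramp[::-1]
    return sigma


def make_base_fold(n_residues: int, seed: int = 0, gly_positions: tuple[int, ...] = ()) -> StructureFrame:
    """Idealized helical backbone with N, CA, C, O, CB heavy atoms per residue.

    Residues listed in ``gly_positions`` (0-based) become GLY and carry no
    Cβ.  Geometry is deterministic given the seed (the seed only perturbs
    nothing today but is kept in the signature so future stochastic folds
    stay reproducible).
    """
    if n_residues < 2:
        raise ParameterError("need at least 2 residues")
    twist = np.deg2rad(HELIX_TWIST_DEG)
    idx = np.arange(n_residues)
    theta = idx * twist
    ca = np.stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * idx],
        axis=1,
    )
    # local frame per residue: analytic helix tangent t (no radial
    # component, which keeps backbone atoms clear of Cβ), outward radial u
    u = np.stack([np.cos(theta), np.sin(theta), np.zeros(n_residues)], axis=1)
    v = np.stack([-np.sin(theta), np.cos(theta), np.zeros(n_residues)], axis=1)
    z = np.array([0.0, 0.0, 1.0])
    t = (HELIX_RADIUS * twist) * v + HELIX_RISE * z
    t /= np.linalg.norm(t, axis=1, keepdims=True)

    residues = []
    serial = 1
    for i in range(n_residues):
        is_gly = i in gly_positions
        res_name = "GLY" if is_gly else "ALA"
        c_pos = ca[i] + 1.2 * t[i] - 0.5 * u[i] - 0.35 * z
        c_dir = c_pos - ca[i]
        c_dir = c_dir / np.linalg.norm(c_dir)
        o_dir = c_dir - 0.8 * z  # tilted below the chain, clear of N(i+1)
        o_dir = o_dir / np.linalg.norm(o_dir)
        pos = {
            "N": ca[i] - 1.2 * t[i] - 0.5 * u[i] + 0.35 * z,
            "CA": ca[i],
            "C": c_pos,
            "O": c_pos + 1.23 * o_dir,
        }
        if not is_gly:
            pos["CB"] = ca[i] + 1.53 * u[i]
        atoms = []
        for name, xyz in pos.items():
            atoms.append(
                AtomRecord(serial=serial, name=name, element=name[0], coords=xyz, bfactor=0.0)
            )
            serial += 1
        residues.append(
            ResidueNode(chain_id="A", seq_id=i + 1, res_name=res_name, atoms=atoms)
        )
    return StructureFrame(residues=residues, frame_label="base")


def _anchor_geometry(frame: StructureFrame, target_key: tuple[str, int]) -> tuple[np.ndarray, np.ndarray]:
    """Anchor atom (Cβ, Cα for Gly) and outward unit vector for a residue."""
    for r in frame.residues:
        if r.key == target_key:
            anchor = r.atom("CB") or r.atom("CA")
            if anchor is None:
                raise ParameterError(f"residue {r.label}: no CB or CA anchor")
            ca = frame.ca_coords()
            centroid = ca.mean(axis=0)
            # radial direction: away from the chain's principal axis, so the
            # ligand clears residues on adjacent helical turns
            _, _, vt = np.linalg.svd(ca - centroid)
            axis = vt[0]
            rel = anchor.coords - centroid
            out = rel - np.dot(rel, axis) * axis
            n = np.linalg.norm(out)
            if n < 1e-9:
                out = np.array([1.0, 0.0, 0.0])
            else:
                out = out / n
            return anchor.coords.copy(), out
    raise KeyError(f"target residue {target_key} not found")


def _make_ligand_residue(label: str, origin: np.ndarray, direction: np.ndarray,
                         serial0: int, seq_id: int = 1) -> ResidueNode:
    """Small rigid tetrahedral heavy-atom group; nearest atom at ``origin``."""
    d = direction
    # orthonormal complement of the approach direction
    a = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    offsets = [
        np.zeros(3),
        1.5 * d,
        1.5 * d + 1.4 * e1,
        1.5 * d - 0.7 * e1 + 1.2 * e2,
    ]
    names = ["C1", "C2", "O1", "N1"]
    elements = ["C", "C", "O", "N"]
    atoms = [
        AtomRecord(serial=serial0 + k, name=n, element=el, coords=origin + off)
        for k, (n, el, off) in enumerate(zip(names, elements, offsets))
    ]
    return ResidueNode(chain_id="L", seq_id=seq_id, res_name=label, atoms=atoms,
                       kind="ligand")


def sample_ensemble(base: StructureFrame, spec: SynthSpec) -> Ensemble:
    """Jittered conformer ensemble around ``base`` with scheduled ligands.

    Each frame displaces every atom of residue i by one shared draw from an
    isotropic Gaussian with per-coordinate s.d. sigma_i (rigid-residue
    jitter), so inter-residue heavy-atom distances fluctuate coherently and
    the RMSF ground truth sqrt(3)*sigma_i is exact in expectation.
    """
    n_res = len(base.residues)
    if len(spec.sigma_profile) != n_res:
        raise ParameterError("sigma_profile length must equal base residue count")
    rng = np.random.default_rng(spec.seed)
    disp = rng.normal(0.0, 1.0, size=(spec.n_frames, n_res, 3)) * spec.sigma_profile[None, :, None]

    frames = []
    for tframe in range(spec.n_frames):
        residues = []
        for i, r in enumerate(base.residues):
            atoms = [
                AtomRecord(a.serial, a.name, a.element, a.coords + disp[tframe, i],
                           a.bfactor, a.occupancy)
                for a in r.atoms
            ]
            residues.append(ResidueNode(r.chain_id, r.seq_id, r.res_name, atoms, r.kind))
        frames.append(StructureFrame(residues=residues, frame_label=str(tframe + 1)))
    ensemble = Ensemble(frames=frames, source="trajectory")
    for schedule in spec.ligand_schedules:
        ensemble = place_ligand_schedule(base, ensemble, schedule, seed=spec.seed)
    return ensemble


def place_ligand_schedule(
    base: StructureFrame, ensemble: Ensemble, schedule: LigandSchedule, seed: int = 0
) -> Ensemble:
    """Attach one rigid ligand group realizing an exact contact fraction.

    The contact frames are an exact count ``round(f * n_frames)`` drawn
    without replacement, so downstream frequency estimates have no sampling
    noise.  Placement is relative to the *per-frame* (jittered) anchor, so
    the designed minimum distance holds in every frame exactly.
    """
    n_frames = ensemble.n_frames
    n_on = int(round(schedule.contact_fraction * n_frames))
    label_salt = zlib.crc32(schedule.label.encode()) % (2**31)
    rng = np.random.default_rng((seed, label_salt))
    on_frames = set(rng.choice(n_frames, size=n_on, replace=False).tolist()) if n_on else set()

    _, out = _anchor_geometry(base, schedule.target_key)  # stable outward direction
    frames = []
    for tframe, frame in enumerate(ensemble.frames):
        # per-frame anchor follows the jittered residue
        anchor_now, _ = _anchor_geometry(frame, schedule.target_key)
        dist = schedule.d_on if tframe in on_frames else schedule.d_off
        origin = anchor_now + dist * out
        n_existing = len(frame.ligands)
        lig_res = _make_ligand_residue(schedule.label, origin, out,
                                       serial0=90000 + 10 * n_existing,
                                       seq_id=n_existing + 1)
        ligands = list(frame.ligands) + [LigandGroup(schedule.label, [lig_res])]
        frames.append(StructureFrame(frame.residues, ligands, frame.frame_label))
    return Ensemble(frames=frames, source=ensemble.source)


def write_synthetic_system(
    outdir,
    spec: SynthSpec,
    gly_positions: tuple[int, ...] = (),
    with_pae: bool = True,
) -> dict:
    """Write one complete synthetic system to disk (all files synthetic).

    Produces ``ensemble.pdb`` (multi-model, pLDDT in the B-factor column of
    frame atoms), ``confidence.json`` (pLDDT array and, optionally, a
    synthetic PAE stand-in: a monotone transform of the base fold's
    residue distance map, so the map-similarity machinery has a ground
    truth of rank correlation 1), and ``sigma.csv`` (the designed
    flexibility profile).  Returns the paths.
    """
    import json
    from pathlib import Path

    from .contacts import ContactDialect, distance_map
    from .structure import write_multimodel_pdb, write_profile_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = make_base_fold(spec.n_residues, seed=spec.seed, gly_positions=gly_positions)
    plddt = synth_plddt(
        spec.sigma_profile, spec.plddt_slope, spec.plddt_noise_sd, spec.seed,
        residue_keys=base.residue_keys, res_names=base.res_names,
    )
    for res, value in zip(base.residues, plddt.values):
        for atom in res.atoms:
            atom.bfactor = float(value)
    ensemble = sample_ensemble(base, spec)
    # carry pLDDT into every frame's B-factor column
    for frame in ensemble.frames:
        for res, value in zip(frame.residues, plddt.values):
            for atom in res.atoms:
                atom.bfactor = float(value)

    pdb_path = outdir / "ensemble.pdb"
    write_multimodel_pdb(ensemble, pdb_path)

    payload: dict = {"plddt": [round(float(v), 2) for v in plddt.values]}
    if with_pae:
        dmap = distance_map(base, ContactDialect("heavy_min"), include_ligands=False)
        pae = np.sqrt(dmap.matrix)  # monotone transform: synthetic PAE stand-in
        payload["pae"] = [[round(float(x), 3) for x in row] for row in pae]
    json_path = outdir / "confidence.json"
    json_path.write_text(json.dumps(payload))

    sigma_path = outdir / "sigma.csv"

    class _SigmaTrack:  # duck-typed track for the CSV writer
        residue_keys = base.residue_keys
        res_names = base.res_names
        values = spec.sigma_profile

    write_profile_csv(_SigmaTrack(), sigma_path)
    return {"pdb": pdb_path, "confidence": json_path, "sigma": sigma_path, "base": base}


def synth_plddt(
    sigma_profile: np.ndarray,
    slope: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    residue_keys: list[tuple[str, int]] | None = None,
    res_names: list[str] | None = None,
) -> PlddtProfile:
    """Confidence profile anti-correlated with the jitter amplitude.

    pLDDT_i = clamp(95 - slope * sigma_i + eta_i, 0, 100) with
    eta_i ~ N(0, noise_sd^2).  With ``noise_sd = 0`` the profile is an exact
    decreasing affine function of sigma, so the flexibility score derived
    from it correlates perfectly with sigma.
    """
    sigma = np.asarray(sigma_profile, dtype=float)
    if slope <= 0:
        raise ParameterError("slope must be > 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    eta = rng.normal(0.0, noise_sd, size=len(sigma)) if noise_sd > 0 else 0.0
    values = np.clip(95.0 - slope * sigma + eta, 0.0, 100.0)
    keys = residue_keys or [("A", i + 1) for i in range(len(sigma))]
    return PlddtProfile(keys, values, res_names=res_names)
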