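"""Domain types and I/O for multi-model structures with ligand groups.

The central containers are :class:`StructureFrame` (one conformer: polymer
residues plus whole-ligand groups) and :class:`Ensemble` (an ordered list of
frames with identical topology, either a trajectory or a population of
predicted models).  Per-residue confidence (pLDDT, stored by AlphaFold-style
models in the B-factor column) is carried as a :class:`PlddtProfile`.

File I/O goes through gemmi for the PDB dialect; the topology-uniformity
check, water removal, altloc resolution and ligand grouping are layered on
top because they are contracts of this package, not of the format.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import FormatError, MismatchError, ParameterError, TopologyError

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

ResidueKey = tuple[str, int]


@dataclass
class AtomRecord:
    """One atom: name, element, coordinates (Å), B-factor slot, occupancy.

    The B-factor slot holds either a crystallographic B-factor or, for
    predicted models, the per-residue pLDDT.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.element:
            raise ParameterError(f"atom {self.name!r}: empty element symbol")
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ParameterError(f"atom {self.name!r}: coords must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class ResidueNode:
    """A polymer residue or one residue of a ligand group.

    ``seq_id`` keeps author numbering (1-based, as printed in structure
    files) so residue labels like W343 are reproducible.
    """

    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[AtomRecord]
    kind: str = "polymer"  # polymer | ligand

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ParameterError(f"residue {self.res_name} {self.seq_id}: no atoms")
        if self.kind not in ("polymer", "ligand"):
            raise ParameterError(f"unknown residue kind {self.kind!r}")

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_id)

    @property
    def label(self) -> str:
        return f"{self.res_name}{self.seq_id}"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms()
        if not atoms:
            raise ParameterError(f"residue {self.label}: no heavy atoms")
        return np.array([a.coords for a in atoms])


@dataclass
class LigandGroup:
    """A whole ligand (cofactor/substrate) treated as a single network vertex.

    May span several HETATM residues (corrinoid cofactors often do); the
    formal charge is metadata only (e.g. Fe4S4Cys4 is -2 oxidized, -3
    reduced) and enters no computation.
    """

    label: str
    residues: list[ResidueNode]
    formal_charge: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ParameterError(f"ligand {self.label}: empty group")
        if not any(not a.is_hydrogen for r in self.residues for a in r.atoms):
            raise ParameterError(f"ligand {self.label}: no heavy atoms")

    def heavy_coords(self) -> np.ndarray:
        return np.vstack([r.heavy_coords() for r in self.residues])

    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]


@dataclass
class StructureFrame:
    """One conformer: ordered polymer residues plus ligand groups."""

    residues: list[ResidueNode]
    ligands: list[LigandGroup] = field(default_factory=list)
    frame_label: str = "1"

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for r in self.residues:
            prev = seen.get(r.chain_id)
            if prev is not None and r.seq_id <= prev:
                raise TopologyError(
                    f"chain {r.chain_id}: residue numbering not strictly "
                    f"increasing at {r.label}"
                )
            seen[r.chain_id] = r.seq_id
        labels = [g.label for g in self.ligands]
        if len(set(labels)) != len(labels):
            raise TopologyError(f"duplicate ligand labels in frame {self.frame_label}")

    @property
    def residue_keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    @property
    def res_names(self) -> list[str]:
        return [r.res_name for r in self.residues]

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates of the polymer, (n_residues, 3)."""
        out = []
        for r in self.residues:
            ca = r.atom("CA")
            if ca is None:
                raise TopologyError(f"residue {r.label}: no CA atom")
            out.append(ca.coords)
        return np.array(out)

    def ligand(self, label: str) -> LigandGroup:
        for g in self.ligands:
            if g.label == label:
                return g
        raise KeyError(f"no ligand group {label!r} in frame {self.frame_label}")

    def sequence(self) -> str:
        """One-letter polymer sequence (X for non-standard residues)."""
        from Bio.SeqUtils import seq1

        return "".join(seq1(r.res_name, undef_code="X") for r in self.residues)

    def topology_signature(self) -> list[tuple]:
        sig: list[tuple] = [
            (r.chain_id, r.seq_id, r.res_name, tuple(a.name for a in r.atoms))
            for r in self.residues
        ]
        for g in self.ligands:
            for r in g.residues:
                sig.append((g.label, r.seq_id, r.res_name, tuple(a.name for a in r.atoms)))
        return sig


@dataclass
class Ensemble:
    """Ordered frames with identical topology.

    ``source`` distinguishes a time-ordered trajectory from an unordered
    population of predicted models; no computation branches on it, it is
    provenance carried into reports.
    """

    frames: list[StructureFrame]
    source: str = "trajectory"  # trajectory | model_population

    def __post_init__(self) -> None:
        if not self.frames:
            raise ParameterError("ensemble must contain at least one frame")
        check_uniform_topology(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def check_uniform_topology(frames: Sequence[StructureFrame]) -> None:
    """Raise TopologyError naming the first divergent residue."""
    ref = frames[0].topology_signature()
    for k, frame in enumerate(frames[1:], start=2):
        sig = frame.topology_signature()
        if sig == ref:
            continue
        for a, b in zip(ref, sig):
            if a != b:
                raise TopologyError(
                    f"frame {k} ({frame.frame_label!r}) diverges from frame 1 "
                    f"at residue {b[2]} {b[1]} (chain/group {b[0]}): "
                    f"expected {a[2]} {a[1]} with atoms {a[3]}"
                )
        raise TopologyError(
            f"frame {k} ({frame.frame_label!r}) has {len(sig)} residues, "
            f"frame 1 has {len(ref)}"
        )


@dataclass
class PlddtProfile:
    """Per-residue pLDDT track in [0, 100], aligned to a polymer residue list."""

    residue_keys: list[ResidueKey]
    values: np.ndarray
    res_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residue_keys) != len(self.values):
            raise MismatchError("residue_keys and values differ in length")
        if len(self.values) == 0:
            raise ParameterError("empty pLDDT profile")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ParameterError("pLDDT values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# PDB reading / writing


def _resolve_altlocs(raw_atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties by altloc letter."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in raw_atoms:
        by_name.setdefault(a.name, []).append(a)
    picked = []
    for name, group in by_name.items():
        group.sort(key=lambda a: (-a.occ, a.altloc or "A"))
        picked.append(group[0])
    return picked


def _convert_residue(res: gemmi.Residue, chain_id: str, kind: str) -> ResidueNode:
    atoms = []
    for a in _resolve_altlocs(list(res)):
        elem = a.element.name or a.name[:1]
        atoms.append(
            AtomRecord(
                serial=a.serial,
                name=a.name,
                element=elem,
                coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                bfactor=a.b_iso,
                occupancy=a.occ,
            )
        )
    return ResidueNode(
        chain_id=chain_id,
        seq_id=res.seqid.num,
        res_name=res.name,
        atoms=atoms,
        kind=kind,
    )


def read_multimodel_pdb(
    path: str | Path,
    ligand_labels: Mapping[str, str] | None = None,
    source: str = "trajectory",
) -> Ensemble:
    """Read a multi-model PDB file into an Ensemble.

    HETATM residues are grouped into ligand groups by residue name (or by
    the supplied res_name -> label map); waters are dropped.  Topology must
    be identical across models.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports line numbers itself
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models found")

    frames = []
    for model in st:
        residues: list[ResidueNode] = []
        ligand_members: dict[str, list[ResidueNode]] = {}
        for chain in model:
            for res in chain:
                if res.name in WATER_NAMES:
                    continue
                if res.het_flag == "H":
                    label = (ligand_labels or {}).get(res.name, res.name)
                    node = _convert_residue(res, chain.name, "ligand")
                    ligand_members.setdefault(label, []).append(node)
                else:
                    residues.append(_convert_residue(res, chain.name, "polymer"))
        ligands = [LigandGroup(label, members) for label, members in ligand_members.items()]
        frames.append(
            StructureFrame(residues=residues, ligands=ligands, frame_label=str(model.num))
        )
    return Ensemble(frames=frames, source=source)


def write_multimodel_pdb(ensemble_or_frame: Ensemble | StructureFrame, path: str | Path) -> None:
    """Write frames as a MODEL/ENDMDL multi-model PDB via gemmi."""
    if isinstance(ensemble_or_frame, StructureFrame):
        frames: Sequence[StructureFrame] = [ensemble_or_frame]
    else:
        frames = ensemble_or_frame.frames
    st = gemmi.Structure()
    st.name = "flexrin"
    for k, frame in enumerate(frames, start=1):
        model = gemmi.Model(k)
        chains: dict[str, gemmi.Chain] = {}

        def add(node: ResidueNode, het: bool) -> None:
            ch = chains.get(node.chain_id)
            if ch is None:
                ch = gemmi.Chain(node.chain_id)
                chains[node.chain_id] = ch
            res = gemmi.Residue()
            res.name = node.res_name
            res.seqid = gemmi.SeqId(node.seq_id, " ")
            res.het_flag = "H" if het else "A"
            for a in node.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.coords)
                atom.b_iso = a.bfactor
                atom.occ = a.occupancy
                res.add_atom(atom)
            ch.add_residue(res)

        for node in frame.residues:
            add(node, het=False)
        for g in frame.ligands:
            for node in g.residues:
                add(node, het=True)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# Confidence tracks


def extract_plddt(frame: StructureFrame, per_residue_mean: bool = False) -> PlddtProfile:
    """Read pLDDT from the B-factor column of a predicted-model frame.

    Default takes the Cα value (AlphaFold writes one value per residue on
    every atom anyway); ``per_residue_mean`` averages over the residue's
    atoms instead, and is also the fallback when Cα is absent.  Values
    outside [0, 100] are clamped with a warning.
    """
    if not frame.residues:
        raise ParameterError("frame has no polymer residues")
    values = []
    for r in frame.residues:
        ca = r.atom("CA")
        if per_residue_mean or ca is None:
            v = float(np.mean([a.bfactor for a in r.atoms]))
        else:
            v = float(ca.bfactor)
        values.append(v)
    arr = np.array(values)
    if np.any(arr < 0) or np.any(arr > 100):
        logger.warning(
            "pLDDT values outside [0, 100] clamped (min %.1f, max %.1f)",
            arr.min(), arr.max(),
        )
        arr = np.clip(arr, 0.0, 100.0)
    return PlddtProfile(frame.residue_keys, arr, res_names=frame.res_names)


def read_confidence_json(
    path: str | Path, expected_length: int | None = None
) -> tuple[PlddtProfile, np.ndarray | None]:
    """Read an AlphaFold-style confidence JSON: pLDDT array, optional PAE.

    Accepts the common key spellings (``plddt`` / ``confidenceScore``;
    ``pae`` / ``predicted_aligned_error``).
    """
    data = json.loads(Path(path).read_text())
    plddt = data.get("plddt", data.get("confidenceScore"))
    if plddt is None:
        raise FormatError(f"{path}: no per-residue pLDDT array found")
    values = np.asarray(plddt, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise FormatError(f"{path}: pLDDT must be a non-empty 1-D array")
    if expected_length is not None and len(values) != expected_length:
        raise MismatchError(
            f"{path}: pLDDT length {len(values)} != structure length {expected_length}"
        )
    keys = [("A", i + 1) for i in range(len(values))]
    profile = PlddtProfile(keys, values)

    pae = data.get("pae", data.get("predicted_aligned_error"))
    pae_matrix = None
    if pae is not None:
        pae_matrix = np.asarray(pae, dtype=float)
        if pae_matrix.ndim != 2 or pae_matrix.shape[0] != pae_matrix.shape[1]:
            raise FormatError(f"{path}: PAE matrix is not square")
        if pae_matrix.shape[0] != len(values):
            raise MismatchError(
                f"{path}: PAE dimension {pae_matrix.shape[0]} != pLDDT length {len(values)}"
            )
    return profile, pae_matrix


def write_profile_csv(profile, path: str | Path) -> None:
    """Write a per-residue track as CSV (chain, seq_id, res_name, value)."""
    if len(profile.residue_keys) == 0:
        raise ParameterError("refusing to write an empty profile")
    res_names = getattr(profile, "res_names", None) or ["UNK"] * len(profile.residue_keys)
    df = pd.DataFrame(
        {
            "chain": [k[0] for k in profile.residue_keys],
            "seq_id": [k[1] for k in profile.residue_keys],
            "res_name": res_names,
            "value": np.asarray(profile.values, dtype=float),
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"chain", "seq_id", "res_name", "value"}
    if not expected.issubset(df.columns):
        raise FormatError(f"{path}: profile CSV needs columns {sorted(expected)}")
    return df
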