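"""Template-based cofactor/ligand grafting into a predicted model.

Predicted structures come without their cofactors.  When a holo template of
a close homolog exists, the bound groups can be transplanted: pair the two
chains residue-by-residue (global sequence alignment), superpose the
template onto the model over the paired Cα atoms, and apply that rigid
motion to every template ligand atom.  The ligand's internal geometry is
preserved exactly; a clash check flags placements that collide with the
model.

Unweighted Kabsch over a Needleman-Wunsch pairing is exact whenever the two
sequences are near-identical, which is the regime template transfer is
meant for.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .contacts import ContactDialect, build_rin
from .errors import GeometryError, ParameterError
from .flexibility import Transform, superpose
from .structure import LigandGroup, ResidueKey, StructureFrame


@dataclass
class ResiduePairing:
    """One-to-one correspondence between template and model residues."""

    pairs: list[tuple[ResidueKey, ResidueKey]]

    def __post_init__(self) -> None:
        t = [p[0] for p in self.pairs]
        m = [p[1] for p in self.pairs]
        if len(set(t)) != len(t) or len(set(m)) != len(m):
            raise ParameterError("pairing must be one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)


def pair_by_alignment(template_seq: str, model_seq: str,
                      template_keys: list[ResidueKey] | None = None,
                      model_keys: list[ResidueKey] | None = None,
                      match: float = 1.0, mismatch: float = 0.0,
                      gap: float = -1.0) -> ResiduePairing:
    """Needleman-Wunsch global alignment; aligned non-gap columns become pairs.

    Traceback ties resolve diagonal > up > left, so the pairing is
    deterministic for any scoring.
    """
    if not template_seq or not model_seq:
        raise ParameterError("sequences must be non-empty")
    a, b = template_seq, model_seq
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            score[i, j] = max(diag, up, left)

    tkeys = template_keys or [("A", i + 1) for i in range(n)]
    mkeys = model_keys or [("A", j + 1) for j in range(m)]
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
        if score[i, j] == diag:
            pairs.append((tkeys[i - 1], mkeys[j - 1]))
            i, j = i - 1, j - 1
        elif score[i, j] == score[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return ResiduePairing(pairs)


def _paired_ca(template_frame: StructureFrame, model_frame: StructureFrame,
               pairing: ResiduePairing) -> tuple[np.ndarray, np.ndarray]:
    t_index = {r.key: r for r in template_frame.residues}
    m_index = {r.key: r for r in model_frame.residues}
    tc, mc = [], []
    for tkey, mkey in pairing.pairs:
        tr, mr = t_index.get(tkey), m_index.get(mkey)
        if tr is None or mr is None:
            raise ParameterError(f"pairing references missing residue {tkey}/{mkey}")
        ta, ma = tr.atom("CA"), mr.atom("CA")
        if ta is None or ma is None:
            continue
        tc.append(ta.coords)
        mc.append(ma.coords)
    if len(tc) < 3:
        raise GeometryError("fewer than 3 paired CA atoms")
    return np.array(tc), np.array(mc)


def transfer_transform(template_frame: StructureFrame, model_frame: StructureFrame,
                       pairing: ResiduePairing) -> tuple[Transform, float]:
    """Rigid motion carrying the template chain onto the model chain."""
    tc, mc = _paired_ca(template_frame, model_frame, pairing)
    return superpose(tc, mc)


def transfer_ligands(template_frame: StructureFrame, model_frame: StructureFrame,
                     pairing: ResiduePairing) -> tuple[StructureFrame, Transform, float]:
    """Graft every template ligand group into the model frame.

    Returns the augmented model frame, the transform used, and the Cα
    superposition RMSD (the natural bound on placement error).
    """
    if not template_frame.ligands:
        raise ParameterError("template frame has no ligand groups to transfer")
    transform, rmsd = transfer_transform(template_frame, model_frame, pairing)

    new_ligands = list(model_frame.ligands)
    for g in template_frame.ligands:
        moved = copy.deepcopy(g)
        for res in moved.residues:
            for atom in res.atoms:
                atom.coords = transform.apply(atom.coords)
        new_ligands.append(moved)
    out = StructureFrame(
        residues=model_frame.residues,
        ligands=new_ligands,
        frame_label=model_frame.frame_label,
    )
    return out, transform, rmsd


def clash_check(frame: StructureFrame, ligand: LigandGroup,
                clash_cutoff: float = 2.0) -> list[tuple[str, str, float]]:
    """Heavy-atom ligand-polymer pairs closer than the cutoff, nearest first."""
    if clash_cutoff < 0:
        raise ParameterError("clash cutoff must be >= 0")
    if clash_cutoff == 0:
        return []
    lig_atoms = [a for r in ligand.residues for a in r.atoms if not a.is_hydrogen]
    out = []
    for res in frame.residues:
        prot_atoms = res.heavy_atoms()
        D = cdist(np.array([a.coords for a in lig_atoms]),
                  np.array([a.coords for a in prot_atoms]))
        ii, jj = np.nonzero(D < clash_cutoff)
        for i, j in zip(ii, jj):
            out.append((lig_atoms[i].name, f"{res.label}:{prot_atoms[j].name}",
                        float(D[i, j])))
    out.sort(key=lambda r: r[2])
    return out


def binding_site_residues(frame: StructureFrame,
                          dialect: ContactDialect | None = None
                          ) -> dict[str, list[ResidueKey]]:
    """Residues in contact with each ligand group in a single frame."""
    if not frame.ligands:
        raise ParameterError("frame has no ligand groups")
    rin = build_rin(frame, dialect or ContactDialect())
    out: dict[str, list[ResidueKey]] = {}
    for g in frame.ligands:
        ti = rin.index(g.label)
        partners = [
            rin.vertex_keys[i]
            for i in np.nonzero(rin.adjacency[ti])[0]
            if rin.vertex_kinds[i] == "polymer"
        ]
        out[g.label] = partners
    return out
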