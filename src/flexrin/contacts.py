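"""Distance maps, contact maps and residue interaction networks (RINs).

Two contact dialects are supported:

* ``heavy_min`` — d_ij is the shortest distance over all heavy-atom pairs
  of two residues (or of a residue and a whole ligand group), with a
  3.5 Å cutoff motivated by the longest common hydrogen-bond donor-acceptor
  separation (C-H...O);
* ``cbeta`` — the classic Cβ-Cβ distance (Cα for Gly) with an 8 Å cutoff.

The Cβ dialect can miss or invent contacts when sidechains reach across a
gap, which is why the heavy-atom rule is the default here.  Contacts are
strict: an edge exists iff 0 < d_ij < cutoff.  Ligand groups (cofactors,
substrates) enter the network as single vertices; their distance to a
residue is the minimum over all of the group's heavy atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .errors import GeometryError, MismatchError, ParameterError
from .structure import LigandGroup, ResidueNode, StructureFrame

logger = logging.getLogger(__name__)

POSITIVE = {"LYS", "ARG"}
NEGATIVE = {"GLU", "ASP"}
AROMATIC = {"HIS", "TYR", "PHE", "TRP"}


def residue_class(res_name: str) -> str:
    if res_name in POSITIVE:
        return "positive"
    if res_name in NEGATIVE:
        return "negative"
    if res_name in AROMATIC:
        return "aromatic"
    return "other"


@dataclass
class ContactDialect:
    """Contact definition: distance mode plus cutoff in Å."""

    mode: str = "heavy_min"  # heavy_min | cbeta
    cutoff: float | None = None

    DEFAULT_CUTOFF = {"heavy_min": 3.5, "cbeta": 8.0}

    def __post_init__(self) -> None:
        if self.mode not in self.DEFAULT_CUTOFF:
            raise ParameterError(f"unknown dialect mode {self.mode!r}")
        if self.cutoff is None:
            self.cutoff = self.DEFAULT_CUTOFF[self.mode]
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be > 0")


@dataclass
class DistanceMap:
    """Symmetric residue/ligand distance matrix for one frame."""

    vertex_keys: list
    matrix: np.ndarray
    dialect: ContactDialect
    vertex_kinds: list[str] = field(default_factory=list)  # polymer | ligand
    vertex_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, float)
        if M.shape != (len(self.vertex_keys),) * 2:
            raise MismatchError("matrix shape does not match vertex list")
        if not np.allclose(M, M.T, atol=1e-9):
            raise ParameterError("distance matrix must be symmetric")
        self.matrix = M


@dataclass
class RINGraph:
    """Residue interaction network: binary adjacency over residues + ligands."""

    vertex_keys: list
    adjacency: np.ndarray
    vertex_kinds: list[str]
    vertex_classes: list[str]
    vertex_names: list[str] | None = None
    bonded_mask: np.ndarray | None = None
    dialect: ContactDialect | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        n = len(self.vertex_keys)
        if A.shape != (n, n):
            raise MismatchError("adjacency shape does not match vertex list")
        if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
            raise ParameterError("adjacency must be symmetric with zero diagonal")
        if not np.isin(A, (0, 1)).all():
            raise ParameterError("adjacency must be binary")
        self.adjacency = A.astype(np.int8)

    def index(self, key) -> int:
        return self.vertex_keys.index(key)

    def has_edge(self, a, b) -> bool:
        return bool(self.adjacency[self.index(a), self.index(b)])

    def degree(self, key, restrict_kind: str | None = None) -> int:
        i = self.index(key)
        row = self.adjacency[i]
        if restrict_kind is None:
            return int(row.sum())
        mask = np.array([k == restrict_kind for k in self.vertex_kinds])
        return int(row[mask].sum())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for key, kind, cls in zip(self.vertex_keys, self.vertex_kinds, self.vertex_classes):
            g.add_node(key, kind=kind, residue_class=cls)
        n = len(self.vertex_keys)
        for i in range(n):
            for j in range(i + 1, n):
                if self.adjacency[i, j]:
                    bonded = bool(self.bonded_mask[i, j]) if self.bonded_mask is not None else False
                    g.add_edge(self.vertex_keys[i], self.vertex_keys[j], bonded=bonded)
        return g


def residue_min_distance(a: ResidueNode | LigandGroup, b: ResidueNode | LigandGroup) -> float:
    """Shortest heavy-atom distance between two residues/ligand groups."""
    if a is b:
        return 0.0
    ca, cb = a.heavy_coords(), b.heavy_coords()
    return float(cdist(ca, cb).min())


def _cbeta_anchor(res: ResidueNode) -> np.ndarray:
    atom = res.atom("CB") or res.atom("CA")  # Cα stands in for Gly
    if atom is None:
        raise GeometryError(f"residue {res.label}: neither CB nor CA present")
    return atom.coords


def distance_map(frame: StructureFrame, dialect: ContactDialect | None = None,
                 include_ligands: bool = True) -> DistanceMap:
    """Pairwise residue(-and-ligand) distances under a dialect.

    Ligand groups are single vertices in heavy_min mode; the Cβ dialect has
    no anchor for a multi-atom ligand, so ligands are excluded there.
    """
    dialect = dialect or ContactDialect()
    entities: list = list(frame.residues)
    kinds = ["polymer"] * len(frame.residues)
    keys: list = list(frame.residue_keys)
    names = list(frame.res_names)
    if include_ligands and dialect.mode == "heavy_min":
        for g in frame.ligands:
            entities.append(g)
            kinds.append("ligand")
            keys.append(g.label)
            names.append(g.label)
    elif include_ligands and dialect.mode == "cbeta" and frame.ligands:
        logger.warning("cbeta dialect has no ligand anchor; ligand groups excluded")

    n = len(entities)
    M = np.zeros((n, n))
    if dialect.mode == "cbeta":
        anchors = np.array([_cbeta_anchor(r) for r in frame.residues])
        M = cdist(anchors, anchors)
        np.fill_diagonal(M, 0.0)
    else:
        coords = [e.heavy_coords() for e in entities]
        for i in range(n):
            for j in range(i + 1, n):
                d = float(cdist(coords[i], coords[j]).min())
                M[i, j] = M[j, i] = d
    return DistanceMap(keys, M, dialect, vertex_kinds=kinds, vertex_names=names)


def contact_map(dmap: DistanceMap) -> np.ndarray:
    """Binary adjacency: edge iff 0 < d_ij < cutoff (strict)."""
    M = dmap.matrix
    A = ((M > 0) & (M < dmap.dialect.cutoff)).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A


def _bonded_mask(keys: list, kinds: list[str]) -> np.ndarray:
    """Flag sequence-adjacent polymer pairs (same chain, |Δseq| == 1)."""
    n = len(keys)
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        if kinds[i] != "polymer":
            continue
        for j in range(i + 1, n):
            if kinds[j] != "polymer":
                continue
            (ca_, sa), (cb_, sb) = keys[i], keys[j]
            if ca_ == cb_ and abs(sa - sb) == 1:
                mask[i, j] = mask[j, i] = True
    return mask


def build_rin(frame: StructureFrame, dialect: ContactDialect | None = None,
              exclude_bonded: bool = False) -> RINGraph:
    """RIN for one frame: residues + ligand groups as vertices, contacts as edges.

    Sequence-adjacent polymer contacts are kept (flagged ``bonded``) unless
    ``exclude_bonded`` removes them.
    """
    dialect = dialect or ContactDialect()
    dmap = distance_map(frame, dialect, include_ligands=True)
    A = contact_map(dmap)
    bonded = _bonded_mask(dmap.vertex_keys, dmap.vertex_kinds)
    if exclude_bonded:
        A = A.copy()
        A[bonded] = 0
    classes = [
        residue_class(name) if kind == "polymer" else "ligand"
        for name, kind in zip(dmap.vertex_names, dmap.vertex_kinds)
    ]
    return RINGraph(dmap.vertex_keys, A, dmap.vertex_kinds, classes,
                    vertex_names=dmap.vertex_names, bonded_mask=bonded,
                    dialect=dialect)


def map_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation of two square maps over the strict upper triangle.

    Used to quantify how well a structural distance map mirrors a predicted
    aligned error (PAE) map; rank correlation is insensitive to the
    monotone rescaling between the two quantities.
    """
    A = np.asarray(a, float)
    B = np.asarray(b, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise MismatchError("maps must be square and of equal shape")
    iu = np.triu_indices(A.shape[0], k=1)
    rho, _ = spearmanr(A[iu], B[iu])
    return float(rho)


def write_edge_list_tsv(rin: RINGraph, dmap: DistanceMap, path) -> None:
    """Edge list TSV: vertex_a, vertex_b, distance_Å, bonded flag."""
    lines = ["vertex_a\tvertex_b\tdistance_A\tbonded"]
    n = len(rin.vertex_keys)
    for i in range(n):
        for j in range(i + 1, n):
            if rin.adjacency[i, j]:
                bonded = int(rin.bonded_mask[i, j]) if rin.bonded_mask is not None else 0
                lines.append(
                    f"{_fmt_key(rin.vertex_keys[i])}\t{_fmt_key(rin.vertex_keys[j])}"
                    f"\t{dmap.matrix[i, j]:.3f}\t{bonded}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _fmt_key(key) -> str:
    if isinstance(key, tuple):
        return f"{key[0]}:{key[1]}"
    return str(key)
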