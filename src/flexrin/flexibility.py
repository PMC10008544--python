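"""Flexibility metrics and confidence-flexibility concordance.

The core quantities:

* RMSF_i = sqrt(mean_t |r_i(t) - mean_t r_i|^2) over an ensemble, after
  optional Cα superposition of every frame onto the first;
* the AF2-score, a reverse min-max normalization of per-residue pLDDT,
  AF2_i = (pLDDT_max - pLDDT_i) / (pLDDT_max - pLDDT_min), so high score
  means low confidence, i.e. predicted flexibility;
* Pearson concordance between the two tracks with the usual t-based
  two-sided p-value;
* per-frame Cα RMSD to a reference frame, and tail means of that series.

Rigid superposition is a direct Kabsch solve (SVD with the reflection
branch corrected), exposed because ligand grafting and the RMSD-matrix
machinery reuse it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import GeometryError, MismatchError, ParameterError
from .structure import Ensemble, PlddtProfile, ResidueKey

logger = logging.getLogger(__name__)


@dataclass
class Transform:
    """Proper rigid motion x -> R @ x + t (det R = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if R.shape != (3, 3):
            raise ParameterError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ParameterError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ParameterError("rotation must be proper (det = +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self ∘ other: apply ``other`` first."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class FlexProfile:
    """Per-residue nonnegative scalar track (RMSF in Å, or unitless AF2-score)."""

    residue_keys: list[ResidueKey]
    values: np.ndarray
    kind: str = "rmsf"  # rmsf | af2_score
    res_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if len(self.residue_keys) != len(self.values):
            raise MismatchError("residue_keys and values differ in length")
        if np.any(self.values < -1e-12):
            raise ParameterError(f"{self.kind} values must be >= 0")
        if self.kind == "af2_score" and np.any(self.values > 1 + 1e-12):
            raise ParameterError("af2_score values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ConcordanceResult:
    pcc: float
    p_value: float
    n: int


@dataclass
class RmsdSeries:
    frame_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[Transform, float]:
    """Least-squares proper superposition of paired point sets (Kabsch).

    Returns the Transform mapping ``mobile`` onto ``reference`` and the
    residual RMSD.  Reflections are never returned: the smallest singular
    direction is sign-flipped when the raw solution is improper, which is
    the optimal rotation constrained to det = +1.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ParameterError("mobile and reference must be matched (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 paired points")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    # collinear point sets leave the rotation about the line undetermined
    if S[1] < 1e-9 * max(S[0], 1.0):
        raise GeometryError("paired points are (near-)collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    transform = Transform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


def _superposed_ca_stack(ensemble: Ensemble, reference: int = 0,
                         do_superpose: bool = True) -> np.ndarray:
    """Cα coordinates of all frames, each superposed onto the reference frame."""
    ref = ensemble.frames[reference].ca_coords()
    stack = np.empty((ensemble.n_frames, ref.shape[0], 3))
    for k, frame in enumerate(ensemble.frames):
        ca = frame.ca_coords()
        if do_superpose:
            tr, _ = superpose(ca, ref)
            ca = tr.apply(ca)
        stack[k] = ca
    return stack


def rmsf(ensemble: Ensemble, atom_selection: str = "CA",
         do_superpose: bool = True) -> FlexProfile:
    """Per-residue root-mean-square fluctuation about the ensemble mean.

    ``atom_selection='CA'`` uses the Cα atom; ``'heavy'`` averages the
    per-atom RMSF over every heavy atom of the residue.  With
    ``do_superpose`` each frame is first fitted to frame 1 on all Cα, which
    removes global drift/tumbling.
    """
    if ensemble.n_frames < 2:
        raise ParameterError("RMSF needs at least 2 frames")
    if atom_selection not in ("CA", "heavy"):
        raise ParameterError("atom_selection must be 'CA' or 'heavy'")

    frame0 = ensemble.frames[0]
    transforms: list[Transform] = []
    if do_superpose:
        ref = frame0.ca_coords()
        for frame in ensemble.frames:
            tr, _ = superpose(frame.ca_coords(), ref)
            transforms.append(tr)
    else:
        transforms = [Transform.identity()] * ensemble.n_frames

    values = []
    for i, res0 in enumerate(frame0.residues):
        names = [a.name for a in res0.heavy_atoms()] if atom_selection == "heavy" else ["CA"]
        per_atom = []
        for name in names:
            coords = np.array([
                tr.apply(frame.residues[i].atom(name).coords)
                for frame, tr in zip(ensemble.frames, transforms)
            ])
            dev = coords - coords.mean(axis=0)
            per_atom.append(np.sqrt(np.mean(np.sum(dev ** 2, axis=1))))
        values.append(float(np.mean(per_atom)))
    return FlexProfile(frame0.residue_keys, np.array(values), kind="rmsf",
                       res_names=frame0.res_names)


def af2_score(plddt: PlddtProfile) -> FlexProfile:
    """Reverse min-max normalization of pLDDT into a [0, 1] flexibility score.

    AF2_i = (pLDDT_max - pLDDT_i) / (pLDDT_max - pLDDT_min), extrema taken
    over the profile itself.  A constant profile has no range; by
    convention it maps to all zeros with a warning rather than failing.
    """
    v = np.asarray(plddt.values, float)
    if len(v) == 0:
        raise ParameterError("empty pLDDT profile")
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        logger.warning("constant pLDDT profile: AF2-score undefined, returning zeros")
        scores = np.zeros_like(v)
    else:
        scores = (hi - v) / (hi - lo)
    return FlexProfile(plddt.residue_keys, scores, kind="af2_score",
                       res_names=plddt.res_names)


def pearson_concordance(a: FlexProfile, b: FlexProfile) -> ConcordanceResult:
    """Pearson r between two per-residue tracks with t-based two-sided p."""
    if a.residue_keys != b.residue_keys:
        raise MismatchError("profiles are on different residue sets")
    x = np.asarray(a.values, float)
    y = np.asarray(b.values, float)
    n = len(x)
    if n < 3:
        raise ParameterError("concordance needs at least 3 residues")
    if np.ptp(x) < 1e-15 or np.ptp(y) < 1e-15:
        raise ParameterError("correlation undefined for a constant profile")
    r, p = stats.pearsonr(x, y)
    return ConcordanceResult(pcc=float(r), p_value=float(p), n=n)


def rmsd_series(ensemble: Ensemble, reference_frame: int = 0) -> RmsdSeries:
    """Per-frame Cα RMSD to a reference frame after superposition."""
    if not 0 <= reference_frame < ensemble.n_frames:
        raise ParameterError(f"reference frame {reference_frame} out of range")
    ref = ensemble.frames[reference_frame].ca_coords()
    values = []
    for frame in ensemble.frames:
        _, r = superpose(frame.ca_coords(), ref)
        values.append(r)
    return RmsdSeries([f.frame_label for f in ensemble.frames], np.array(values))


def tail_mean(series: RmsdSeries, tail_fraction: float) -> tuple[float, float]:
    """Mean and s.d. over the trailing ceil(fraction * n) entries."""
    if not 0 < tail_fraction <= 1:
        raise ParameterError("tail_fraction must lie in (0, 1]")
    v = np.asarray(series.values, float)
    if len(v) == 0:
        raise ParameterError("empty series")
    k = int(np.ceil(tail_fraction * len(v)))
    tail = v[-k:]
    return float(tail.mean()), float(tail.std())
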