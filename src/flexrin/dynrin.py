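"""Per-frame interaction networks and ligand-contact frequency statistics.

A RIN is built for every selected frame of an ensemble (e.g. one snapshot
per nanosecond); for each ligand vertex the fraction of frames in which a
residue contacts it becomes a percentage, and the ligand's per-frame number
of polymer partners is summarized as mean ± s.d.  This is the dynamic
companion of the single-frame network: residues that anchor a cofactor show
up as high-percentage rows, transient contacts as low ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactDialect, RINGraph, build_rin, residue_class
from .errors import ParameterError
from .structure import Ensemble

# partner-count dispersion uses the population (divide-by-n) s.d.; at the
# 100-frame scale used throughout, n vs n-1 is immaterial


@dataclass
class FrequencyTable:
    """Contact frequencies of one ligand vertex across an ensemble.

    Rows are (residue key, res_name, class, percent) sorted by descending
    percent, ties by residue key.  Only residues with percent > 0 appear.
    """

    target: str
    rows: list[tuple]
    partner_count_mean: float
    partner_count_sd: float
    n_frames: int

    def percents(self) -> dict:
        return {key: pct for key, _, _, pct in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["residue", "res_name", "residue_class", "percent"]
        )


def per_frame_rins(ensemble: Ensemble, dialect: ContactDialect | None = None,
                   stride: int = 1, exclude_bonded: bool = False) -> list[RINGraph]:
    """One RIN per selected frame (frames 0, stride, 2*stride, ...)."""
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    dialect = dialect or ContactDialect()
    return [
        build_rin(frame, dialect, exclude_bonded=exclude_bonded)
        for frame in ensemble.frames[::stride]
    ]


def interaction_frequency(rins: list[RINGraph], target: str) -> FrequencyTable:
    """Percentage of frames in which each residue contacts ``target``.

    Also reports the ligand's polymer partner count per frame as
    mean ± population s.d.
    """
    if not rins:
        raise ParameterError("no networks supplied")
    first = rins[0]
    if target not in first.vertex_keys:
        raise KeyError(f"ligand vertex {target!r} absent from networks")
    ti = first.index(target)
    n_frames = len(rins)

    poly_idx = [i for i, k in enumerate(first.vertex_kinds) if k == "polymer"]
    counts = np.zeros(len(first.vertex_keys), dtype=int)
    partners_per_frame = []
    for g in rins:
        if g.vertex_keys != first.vertex_keys:
            raise ParameterError("networks have differing vertex sets")
        row = g.adjacency[ti]
        counts += row
        partners_per_frame.append(int(row[poly_idx].sum()))

    rows = []
    for i in poly_idx:
        if counts[i] == 0:
            continue
        key = first.vertex_keys[i]
        cls = first.vertex_classes[i]
        name = first.vertex_names[i] if first.vertex_names else ""
        rows.append((key, name, cls, 100.0 * counts[i] / n_frames))
    rows.sort(key=lambda r: (-r[3], r[0]))
    ppf = np.array(partners_per_frame, float)
    return FrequencyTable(
        target=target,
        rows=rows,
        partner_count_mean=float(ppf.mean()),
        partner_count_sd=float(ppf.std()),  # population sd
        n_frames=n_frames,
    )


def rank_partners(table: FrequencyTable, threshold_percent: float) -> list[tuple]:
    """Rows with percent strictly above the threshold, order preserved."""
    if not 0 <= threshold_percent <= 100:
        raise ParameterError("threshold must lie in [0, 100]")
    return [row for row in table.rows if row[3] > threshold_percent]


def ligand_report(ensemble: Ensemble, dialect: ContactDialect | None = None,
                  targets: list[str] | None = None, stride: int = 1
                  ) -> tuple[dict[str, FrequencyTable], pd.DataFrame]:
    """Frequency tables for several ligand vertices plus a residue × ligand matrix.

    The cross matrix exposes shared binders: a residue contacting two
    cofactors carries two nonzero columns.
    """
    if targets is None:
        targets = [g.label for g in ensemble.frames[0].ligands]
    rins = per_frame_rins(ensemble, dialect, stride)
    tables = {t: interaction_frequency(rins, t) for t in targets}

    residues = sorted({key for tab in tables.values() for key in tab.percents()})
    data = {
        t: [tables[t].percents().get(r, 0.0) for r in residues] for t in targets
    }
    cross = pd.DataFrame(data, index=[f"{c}:{s}" for c, s in residues])
    cross.index.name = "residue"
    return tables, cross
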