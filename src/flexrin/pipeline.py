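"""End-to-end drivers: multi-system concordance tables and complex reports.

``run_system_comparison`` reproduces the shape of a systems-comparison
table: one row per ensemble with RMSF mean ± s.d., the Pearson concordance
between RMSF and the AF2-score, its p-value, and the tail-mean RMSD.
``run_full_complex_analysis`` emits the network bundle for one
ligand-bearing ensemble: final-frame distance map, RIN edge list,
per-ligand contact-frequency tables, the residue × ligand percent matrix
and (when a confidence file with a PAE matrix is supplied) the
distance-map/PAE similarity.

All outputs are plain CSV/TSV/JSON; a manifest records config, seed and
package version so a run is reconstructible.  Data payloads are
byte-identical across reruns with the same seed; only the manifest carries
a timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contacts import ContactDialect, build_rin, distance_map, map_similarity, write_edge_list_tsv
from .dynrin import ligand_report
from .errors import FlexrinError
from .flexibility import af2_score, pearson_concordance, rmsd_series, rmsf, tail_mean
from .structure import (
    Ensemble,
    extract_plddt,
    read_confidence_json,
    read_multimodel_pdb,
    write_profile_csv,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One system: where its data lives and how to analyse it."""

    label: str
    ensemble_path: str
    confidence_json: str | None = None
    ligand_targets: list[str] = field(default_factory=list)
    dialect_mode: str = "heavy_min"
    cutoff: float | None = None
    stride: int = 1
    tail_fraction: float = 0.1
    seed: int = 0
    output_dir: str = "results"

    def dialect(self) -> ContactDialect:
        return ContactDialect(self.dialect_mode, self.cutoff)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _load_plddt(config: RunConfig, ensemble: Ensemble):
    if config.confidence_json:
        profile, pae = read_confidence_json(
            config.confidence_json, expected_length=len(ensemble.frames[0].residues)
        )
        # re-key onto the structure's residue keys
        frame = ensemble.frames[0]
        profile.residue_keys = frame.residue_keys
        profile.res_names = frame.res_names
        return profile, pae
    return extract_plddt(ensemble.frames[0]), None


def analyse_system(config: RunConfig, ensemble: Ensemble | None = None) -> dict:
    """Single-system concordance metrics (one table row)."""
    if ensemble is None:
        ensemble = read_multimodel_pdb(config.ensemble_path)
    plddt, _ = _load_plddt(config, ensemble)
    flex = rmsf(ensemble, do_superpose=True)
    score = af2_score(plddt)
    conc = pearson_concordance(flex, score)
    series = rmsd_series(ensemble, reference_frame=0)
    rmsd_mean, rmsd_sd = tail_mean(series, config.tail_fraction)
    return {
        "system": config.label,
        "n_frames": ensemble.n_frames,
        "n_residues": len(flex),
        "rmsf_mean_A": float(np.mean(flex.values)),
        "rmsf_sd_A": float(np.std(flex.values)),
        "pcc": conc.pcc,
        "p_value": conc.p_value,
        "rmsd_tail_mean_A": rmsd_mean,
        "rmsd_tail_sd_A": rmsd_sd,
        "_overlay": pd.DataFrame(
            {
                "chain": [k[0] for k in flex.residue_keys],
                "seq_id": [k[1] for k in flex.residue_keys],
                "rmsf_A": flex.values,
                "af2_score": score.values,
            }
        ),
    }


def run_system_comparison(configs: list[RunConfig], output_dir: str | Path,
                          ensembles: dict[str, Ensemble] | None = None) -> pd.DataFrame:
    """Per-system concordance table; a failing system reports its error
    without aborting the batch."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for config in configs:
        logger.info("system %s: analysing", config.label)
        try:
            row = analyse_system(
                config, (ensembles or {}).get(config.label)
            )
            overlay = row.pop("_overlay")
            overlay.to_csv(outdir / f"overlay_{config.label}.csv", index=False,
                           float_format="%.6g")
            row["error"] = ""
        except (FlexrinError, FileNotFoundError, KeyError) as exc:
            logger.warning("system %s failed: %s", config.label, exc)
            row = {"system": config.label, "error": str(exc)}
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "system_comparison.csv", index=False, float_format="%.6g")
    payload = table.drop(columns=["error"], errors="ignore").to_dict(orient="records")
    (outdir / "system_comparison.json").write_text(json.dumps(payload, indent=2, default=str))
    return table


def run_full_complex_analysis(config: RunConfig, ensemble: Ensemble | None = None) -> dict:
    """Network bundle for one ligand-bearing ensemble."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if ensemble is None:
        ensemble = read_multimodel_pdb(config.ensemble_path)
    dialect = config.dialect()
    final = ensemble.frames[-1]

    dmap = distance_map(final, dialect)
    labels = [k if isinstance(k, str) else f"{k[0]}:{k[1]}" for k in dmap.vertex_keys]
    pd.DataFrame(dmap.matrix, index=labels, columns=labels).to_csv(
        outdir / "distance_map_final.csv", float_format="%.4f"
    )
    rin = build_rin(final, dialect)
    write_edge_list_tsv(rin, dmap, outdir / "rin_edges_final.tsv")

    available = {g.label for g in final.ligands}
    wanted = config.ligand_targets or sorted(available)
    targets = [t for t in wanted if t in available]
    missing = [t for t in wanted if t not in available]
    tables, cross = ligand_report(ensemble, dialect, targets, stride=config.stride)
    for label, tab in tables.items():
        df = tab.to_frame()
        df["residue"] = [f"{k[0]}:{k[1]}" for k in df["residue"]]
        df.to_csv(outdir / f"contact_frequency_{label}.csv", index=False,
                  float_format="%.6g")
    cross.to_csv(outdir / "contact_cross_matrix.csv", float_format="%.6g")
    summary = {
        label: {
            "partner_count_mean": tab.partner_count_mean,
            "partner_count_sd": tab.partner_count_sd,
            "n_frames": tab.n_frames,
        }
        for label, tab in tables.items()
    }

    pae_similarity = None
    if config.confidence_json:
        _, pae = read_confidence_json(config.confidence_json)
        if pae is not None:
            poly = distance_map(final, dialect, include_ligands=False)
            if pae.shape[0] == poly.matrix.shape[0]:
                pae_similarity = map_similarity(poly.matrix, pae)
                (outdir / "pae_similarity.json").write_text(
                    json.dumps({"spearman_upper_triangle": pae_similarity})
                )
            else:
                missing.append("PAE (dimension mismatch)")

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "package_version": __version__,
        "seed": config.seed,
        "missing_targets": missing,
        "partner_summary": summary,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "tables": tables,
        "cross": cross,
        "pae_similarity": pae_similarity,
        "missing": missing,
        "manifest": manifest,
    }
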