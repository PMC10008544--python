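"""Confidence-flexibility concordance across the six systems.

For each system: per-residue RMSF (Cα, superposed to frame 1), the
AF2-score derived from its confidence track, their Pearson concordance
with p-value, and the tail-mean RMSD — one row per system, the layout of
a systems-comparison table.  The built-in expectation: concordance
degrades monotonically as the designed confidence noise grows, and the
noise-free system tops the table.
"""

import pandas as pd

from flexrin.pipeline import RunConfig, run_system_comparison

from common import RESULTS, SYSTEM_DESIGNS, ensure_systems


def main() -> None:
    paths = ensure_systems()
    configs = [
        RunConfig(label, str(paths[label]["pdb"]),
                  confidence_json=str(paths[label]["confidence"]))
        for label, _, _ in SYSTEM_DESIGNS
    ]
    table = run_system_comparison(configs, RESULTS)
    show = table[["system", "rmsf_mean_A", "rmsf_sd_A", "pcc", "p_value",
                  "rmsd_tail_mean_A"]]
    print(show.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
    best = table.loc[table["pcc"].idxmax(), "system"]
    print(f"\nbest concordance: {best} "
          "(the system whose confidence track carries no added noise)")
    print(f"wrote {RESULTS / 'system_comparison.csv'} and per-system overlay CSVs")


if __name__ == "__main__":
    main()
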