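"""Structure-snapshot tree across systems.

Takes three snapshots from each trajectory-like system plus snapshots of
the model population, computes the all-pairs superposed Cα RMSD matrix,
summarizes it (mean ± s.d. over pairs) and converts it to a
neighbor-joining tree in Newick form — snapshots of the same system
should cluster.
"""

import pandas as pd

from flexrin.phylo import neighbor_joining, pairwise_rmsd_matrix, write_newick
from flexrin.structure import StructureFrame, read_multimodel_pdb

from common import RESULTS, SYSTEM_DESIGNS, ensure_systems

SNAPSHOT_INDICES = (33, 66, 99)  # early/mid/late


def main() -> None:
    paths = ensure_systems()
    frames = []
    for label, _, _ in SYSTEM_DESIGNS:
        ensemble = read_multimodel_pdb(paths[label]["pdb"])
        for k, idx in enumerate(SNAPSHOT_INDICES, start=1):
            f = ensemble.frames[idx]
            frames.append(StructureFrame(f.residues, [], f"{label}-{k}"))
    dm = pairwise_rmsd_matrix(frames)
    mean, sd = dm.summary()
    pd.DataFrame(dm.matrix, index=dm.labels, columns=dm.labels).to_csv(
        RESULTS / "snapshot_rmsd_matrix.csv", float_format="%.4f")
    tree = neighbor_joining(dm)
    write_newick(tree, RESULTS / "snapshot_tree.nwk")
    print(f"{len(frames)} snapshots from {len(SYSTEM_DESIGNS)} systems")
    print(f"overall pairwise RMSD {mean:.2f} ± {sd:.2f} Å")
    print(f"wrote {RESULTS / 'snapshot_rmsd_matrix.csv'} and "
          f"{RESULTS / 'snapshot_tree.nwk'}")


if __name__ == "__main__":
    main()
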