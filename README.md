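# flexrin

Does a predicted structure's confidence track know how the protein moves?
For well-folded proteins, the per-residue confidence (pLDDT) of predicted
models anti-correlates with residue flexibility: converting it to a
flexibility score and comparing against the root-mean-square fluctuation
(RMSF) of a conformer ensemble makes that claim quantitative. `flexrin`
implements that comparison end to end, together with the ligand-aware
residue interaction networks (RINs) used to characterize cofactor and
substrate binding in reductive dehalogenase-like systems, for people who
work with ensembles of structures — trajectory snapshots or populations of
predicted models — and the ligands bound to them.

The core quantities:

* **AF2-score** — a reverse min–max normalization of pLDDT,
  `AF2_i = (pLDDT_max − pLDDT_i) / (pLDDT_max − pLDDT_min)`,
  so high score = low confidence = predicted flexibility;
* **RMSF** — `RMSF_i = sqrt(mean_t |r_i(t) − r̄_i|²)` over Cα after Kabsch
  superposition of each frame onto the first, plus the Pearson concordance
  (with t-based p-value) between the two tracks, and per-frame RMSD series;
* **RIN** — residues and whole ligand groups as vertices, an edge when the
  shortest heavy-atom distance is below 3.5 Å (strict), with the classic
  Cβ/8 Å dialect available for comparison, and Spearman similarity between
  a distance map and a predicted-aligned-error (PAE) map;
* **dynamic RIN** — one network per frame, per-ligand contact percentages
  ("residue W343 touches the cofactor in 82% of frames"-style tables) and
  partner counts mean ± s.d.;
* **ligand transfer** — graft cofactors from a holo template into a
  predicted apo model via sequence pairing + Cα Kabsch superposition, with
  a clash check;
* **snapshot trees** — all-pairs superposed Cα RMSD matrix converted to a
  neighbor-joining tree (exact on additive distances) with Newick output.

Because suitable real ensembles are rarely deposited, the package ships a
first-class synthetic generator (`flexrin.synthetic`): an idealized helical
fold, per-residue Gaussian jitter with a designed flexibility profile,
confidence tracks anti-correlated with it, and ligands whose contacts occur
in an exact prescribed fraction of frames. Every estimator can therefore be
validated against known ground truth. See `docs/methods.md` for the model,
its assumptions and its limits.

## Worked example

Generate a 100-frame synthetic complex whose cofactor touches residue 30
in 82% of frames, then analyse it:

```sh
flexrin synth --n-residues 60 --n-frames 100 --seed 1 \
        --schedule BVQ:30:0.82 --out demo
flexrin rmsf demo/ensemble.pdb --out demo/rmsf.csv
flexrin af2score demo/confidence.json --out demo/af2.csv
flexrin concordance demo/rmsf.csv demo/af2.csv
flexrin dynrin demo/ensemble.pdb --out demo/dyn
flexrin tree --from-ensemble demo/ensemble.pdb --out demo/tree.nwk
```

which prints

```
{"pcc": 0.998415607494209, "p_value": 3.4271177604651597e-74, "n": 60}
BVQ: partners 0.82 ± 0.38 over 100 frames
wrote demo/tree.nwk; pairwise RMSD 2.49 ± 0.23 Å over 100 frames
```

Reading: the flexibility score derived from the confidence track explains
the observed per-residue fluctuation almost perfectly (Pearson r ≈ 0.998 —
the generator built the confidence to be informative, and the estimator
recovers that); the ligand's designed 82% contact fraction is returned
exactly as its mean polymer partner count; and the frames are ~2.5 Å apart
pairwise, consistent with the designed jitter amplitudes.

The same machinery as a library:

```python
from flexrin import read_multimodel_pdb, extract_plddt, rmsf, af2_score, pearson_concordance

ens = read_multimodel_pdb("demo/ensemble.pdb")
conc = pearson_concordance(rmsf(ens), af2_score(extract_plddt(ens.frames[0])))
print(conc.pcc, conc.p_value)
```

## The analysis

`analysis/` contains the numbered study scripts, each a thin driver over
the package that prints what it found and writes tables under `results/`:

| script | what it does |
|---|---|
| `01_simulate_systems.py` | generates the six study systems (full complex with four scheduled ligands; four ensembles with progressively noisier confidence; a model population) |
| `02_concordance_table.py` | per-system RMSF / PCC / p / tail-RMSD table; the noise-free complex tops the ranking |
| `03_contact_networks.py` | final-frame distance map + RIN, heavy-atom vs Cβ dialect disagreement, distance-map/PAE similarity |
| `04_ligand_frequencies.py` | per-ligand contact percentages and partner counts; designed fractions are recovered exactly |
| `05_cofactor_transfer.py` | grafts the four ligand groups into a perturbed apo model and reports placement error and clashes |
| `06_ensemble_tree.py` | RMSD matrix over snapshots from all systems and its NJ tree |

Run them in order from `analysis/` (bulky intermediates go to `scratch/`).

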