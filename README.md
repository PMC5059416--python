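# percolite

Statistical confidence estimation for shotgun proteomics at desk scale:
semi-supervised rescoring of peptide-spectrum matches (PSMs), target-decoy
q-values and posterior error probabilities at PSM/peptide/protein level,
protein grouping with picked protein-level FDR, and a sample/entrapment
benchmark that audits whether those protein-level estimates can be trusted.

It is written for method developers and students of target-decoy
statistics: every estimator runs on synthetic data with known ground
truth, so the calibration claims are checked, not assumed.

## The statistics in brief

**q-values.** With targets and decoys scored on a common scale, the FDR
at a score threshold *t* is

    FDR(t) = (1 + #{decoys >= t}) / #{targets >= t}

and q(s) = min over t <= s of FDR(t), capped at 1 (no pi0 correction).
PEPs come from a binned decoy/target ratio made monotone by isotonic
regression; empirical p-values are (1 + #{decoys >= s}) / (1 + #decoys);
Fisher's method maps -2 Σ ln pᵢ onto a chi-square with 2k df.

**Rescoring.** PSMs carry a feature vector. Spectra are split into three
cross-validation folds; each fold's linear SVM starts from the best
single signed feature and iterates: targets at q <= 0.01 become
positives, all decoys negatives, refit, rescore. For very large inputs,
training runs on a random subset of whole spectra and all PSMs are
scored with the decoy-standardized average of the three classifiers.

**Protein inference.** Proteins with nested theoretical tryptic peptide
sets merge into groups; only group-unique peptides carry evidence. Four
scorers (best peptide, two-peptide rule, product of PEPs, Fisher) feed a
*picked* competition — each target group against its sequence-reversed
decoy group, better score survives — before protein-level q-values.

**Entrapment benchmark.** An entrapment database 9x the sample is built
by shuffling each tryptic peptide's residues (C-terminal residue fixed),
keeping 4% of sample peptides verbatim as shared peptides. Matches to
the entrapment part are known false positives, so the "entrapment FDR"
of the accepted list externally audits the reported decoy q-values.

## Worked example

```bash
percolite simulate --n-proteins 400 --n-spectra 5000 --seed 7 --out-dir sim
percolite rescore --pin sim/psms.pin --fasta sim/proteome.fasta --seed 7 --out-dir out
```

The manifest (`out/manifest.json`) reports:

```json
{
  "n_psms": 10000,
  "n_peptides": 6430,
  "psms_at_testFDR": 1706,
  "n_protein_groups": 400,
  "proteins_at_testFDR": 119
}
```

10,000 PSMs (one target + one decoy per spectrum) collapse to 6,430
distinct peptides; 1,706 target PSMs pass q <= 0.01 after SVM rescoring,
and 119 of the 400 protein groups are accepted at 1% protein-level FDR —
consistent with the simulation's 30% present-protein fraction (120
present proteins). The top of `out/proteins.tsv`:

```
group_id  label   method        score     q_value   n_peptides  best_peptide
SYN00396  target  best_peptide  6.470942  0.008403  16          EISYFPMTTAVHVYYYFMNPVMEDVSEYR
SYN00121  target  best_peptide  6.384968  0.008403  10          LLWPLMESTCEMTEWCLALCGVIEAGELWVWWSK
```

The calibration experiment runs end to end with:

```bash
percolite benchmark-entrapment --n-proteins 200 --n-spectra 10000 --seed 1 --out-dir bench
```

writing the entrapment/target/decoy FASTAs and `bench/calibration.tsv`
with paired (decoy FDR, entrapment FDR) points.

## Acceptance script

`scripts/acceptance.py` rebuilds the default entrapment benchmark from a
freshly simulated 100-protein sample database, digests both sides, and
reports the percentage of distinct sample peptides found verbatim in the
entrapment database:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/percolite/digest.py` — FASTA I/O, tryptic digestion
- `src/percolite/grouping.py` — protein grouping, group-unique peptides
- `src/percolite/stats.py` — q-values, PEPs, p-values, Fisher
- `src/percolite/rescore.py` — semi-supervised SVM, subset training
- `src/percolite/inference.py` — four protein scorers, picked FDR
- `src/percolite/entrapment.py` — benchmark construction and calibration
- `src/percolite/simulate.py` — seeded synthetic proteomes and PSM sets
- `src/percolite/pipeline.py`, `src/percolite/cli.py` — orchestration
- `docs/methods.md` — models, assumptions, parameter choices, limitations
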