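# episcan

Sequence-based prediction of linear B-cell epitopes in antigen protein
chains.

Antibodies recognize antigens at epitopes; predicting which residues of an
antigen sequence can form a linear (continuous) B-cell epitope guides
epitope mapping, immunodiagnostics and vaccine antigen design. `episcan`
implements a two-stage predictor for this task, aimed at computational
immunologists who have an antigen sequence plus standard per-residue
predictions (secondary structure, solvent accessibility, a PSI-BLAST
profile) and want a per-residue epitope propensity track.

## Method

**Stage 1 — fragment classification.** The input chain is cut into all
overlapping 20-mer windows. Each window is encoded as a 198-dimensional
feature vector drawn from five kinds of information and their combinations
(11 feature groups):

* predicted secondary structure (H/E/C contents, entropy, segment counts);
* predicted relative solvent accessibility RSA = ASA / ASA(Ala-X-Ala),
  residues called buried when RSA < 25%;
* a renormalized amino-acid-pair (dipeptide) antigenicity scale in (−1, 1);
* evolutionary conservation, CON = Σᵢ Pᵢ log₂(Pᵢ/P_ib) over the 20 amino
  acids, where Pᵢ is the residue's weighted observation percentage (WOP)
  from a PSI-BLAST profile divided by 100 and P_ib a background frequency;
* multi-mer similarity scores — the total count of identical substrings
  shared with known epitope and non-epitope 20-mers (top 5 per side).

Sliding sub-windows (n = 5..18) inside each 20-mer, and cross-channel
features (e.g. the mean dipeptide-scale value inside the sub-window with
the highest RSA), complete the set. An RBF-kernel SVM over standardized
features scores each window with a probability-like value in [0, 1]
(defaults C = 2⁰, γ = 2⁻⁹ for a selected-feature model; C = 2³, γ = 2⁻¹⁰
for the full 198-feature model). Features can be pruned by ranking on the
absolute biserial correlation coefficient and backward-eliminating under
cross-validated MCC.

**Stage 2 — propensity aggregation.** Every residue inherits the scores of
the 1–20 windows covering it and the multiset is collapsed by the *max*,
*average*, *median* or *distance* scheme; the default distance scheme
averages the k = 16 scores farthest from the 0.5 decision boundary.

A seeded synthetic-fixture generator fabricates every input the pipeline
consumes (fragment datasets with planted class signal, annotated chains
with embedded epitopes, dipeptide scales, WOP profiles), so the whole
system is testable without external predictors or databases.

## Worked example

```bash
episcan fixtures --seed 5 --n-epitope 25 --n-non-epitope 25 \
    --n-chains 1 --out fx/
episcan train --fragments fx/fragments.tsv \
    --channels fx/fragment_channels.tsv --scale fx/scale.tsv \
    --seed 5 --out model.joblib
episcan predict --fasta fx/chains.fasta \
    --ss-rsa fx/synthchain0_ss_rsa.tsv --wop fx/synthchain0_wop.tsv \
    --scale fx/scale.tsv --model model.joblib \
    --scheme distance --k 16 --out profile.tsv
episcan evaluate --profile profile.tsv --truth fx/synthchain0_truth.tsv
```

prints

```
residue-level AUC: 0.9623
success rate: 1.0000 (100.0% of 1 chains)
```

meaning the planted epitope residues of the synthetic chain are ranked
almost perfectly above the background residues (AUC close to 1), and in
1 of 1 chains the mean propensity over true epitope residues exceeds the
chain-wide mean (the success-rate criterion). `profile.tsv` holds one line
per residue: 1-based position, residue, propensity in [0, 1].

The same workflow runs from Python via `episcan.gen_fragment_dataset`,
`episcan.train_fragment_model` and `episcan.predict_chain`; see the module
docstrings.

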