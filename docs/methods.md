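# Methods

## Model

`episcan` scores linear B-cell epitope propensity in two stages. Stage 1
classifies every overlapping 20-residue window of an antigen chain with an
RBF-kernel support-vector machine over a 198-dimensional feature encoding.
Stage 2 assigns each residue the scores of every window that covers it
(1 at the termini up to 20 in the interior) and collapses that multiset to
a single propensity.

The underlying assumptions: linear epitopes are locally encoded (a 20-mer
carries enough signal to classify), and window-level probabilities can be
combined per residue without modelling inter-window dependence. Scores far
from the 0.5 decision boundary are treated as more reliable, which is what
the default *distance* aggregation scheme exploits.

## Feature encoding

Eleven groups, 198 features, computed per 20-mer; the canonical order
(group order below, listing order within groups, sub-window features by n
ascending with max before min, H/E/C class order, buried before exposed)
is frozen because selection manifests and model artifacts refer to feature
names.

1. **SS (8)** — H/E/C contents, SS entropy, per-class and total maximal-run
   (segment) counts.
2. **RA (33)** — buried/exposed contents and entropy, class-restricted RSA
   means, and min/max mean RSA over sub-windows of n = 5..18 residues.
3. **RP (30)** — mean and SD of the 19 overlapping-dipeptide antigenicity
   scores, plus sub-window extrema.
4. **CS (29)** — mean conservation plus sub-window extrema.
5.–10. **Combined groups (88)** — counts and channel means restricted by
   SS class, exposure or both; channel means over the longest run of each
   SS class; and cross-channel selections (mean dipeptide score inside the
   sub-window extremizing RSA or conservation).
11. **SIM (10)** — the five highest multi-mer similarity scores against an
   epitope library and a non-epitope library.

Conventions, chosen where the definitions left room and then frozen:

* **Empty selections score 0.** Class- or exposure-restricted means over
  an empty residue set (e.g. `RSA_E` with no strand residues) are 0, as
  are counts. Zero is the neutral input for a standardized SVM feature.
* **Ties go leftmost.** Longest-segment ties and extremal-sub-window ties
  resolve to the leftmost candidate, for determinism.
* **Dipeptide channel geometry.** Sub-windows are counted in residues; an
  n-residue window contributes its n−1 internal dipeptide scores. For
  residue-restricted dipeptide features (`RAAP_ss`, `RAAP_Bd/Ed`,
  `RAAP_ss_Bd/Ed`, `RAAP_max_segment_ss`) each residue carries the mean of
  the 1–2 dipeptide scores that touch it; restricted sets are generally
  non-contiguous, so a per-residue track is the only total definition.
  Whole-fragment statistics (`avg_RAAP`, `sd_RAAP`) use the raw 19-score
  sequence.
* **Entropies** are Σ p ln p over class fractions (natural log, values
  ≤ 0). The sign convention is irrelevant to the classifier.
* **Similarity counting.** `fragment_similarity` counts distinct shared
  substrings per length, implemented as one intersection of complete
  substring sets (strings of different lengths are never equal, so the
  per-length sum equals the single intersection size). A positional
  pair-counting mode (`mode="positional"`) is available; the distinct mode
  is the default as the minimal reading of "number of identical
  multi-mers". Under cross-validation a training fragment never matches
  its own library entry; exact duplicates at other positions still count.
  Sides with fewer than k members zero-pad the top-k vector.

One stated sanity property was corrected during design: the overall
channel mean is *not* always bracketed by the sliding-window extrema,
because terminal residues fall in fewer windows (values `[1, 0, 1]` with
n = 2 have window means 0.5, 0.5 but overall mean 2/3). The property tests
assert the correct statement: the extrema bracket every window mean.

## Annotation channels

* **Conservation.** CON = Σᵢ Pᵢ log₂(Pᵢ/P_ib), Pᵢ = WOP/100 used as-is
  (no renormalization of the row), 0·log 0 := 0. The background P_ib
  defaults to Robinson–Robinson amino-acid frequencies (normalized to sum
  exactly 1 at load) with a uniform-0.05 option and a 2-column TSV
  override. When a row of 20 WOP values is all zero, it is replaced by the
  average WOP vector of non-zero rows of the same residue type in the
  training set; that fallback table is built at training time and travels
  inside the model artifact. Types never observed fall back to a uniform
  5% vector.
* **Accessibility.** RSA = ASA / reference area of the residue in an
  extended Ala-X-Ala tripeptide (Ahmad-style table shipped as an
  overridable constant), clipped to [0, 1]; buried iff RSA < 0.25, the
  boundary value counting as exposed.
* **Ambiguity codes** (X/B/Z/U/J/O) are rejected by default; a lenient
  mode maps them to a configurable fallback residue for scale lookups.
* All user-facing coordinates are 1-based inclusive.

## Classifier

Features are standardized (mean/variance learned on training data only —
raw mixed-scale features degrade an RBF kernel), then fed to an RBF SVM
with libsvm's internal sigmoid calibration producing scores in [0, 1]. A
fragment is called an epitope iff its score exceeds 0.5; exactly 0.5 calls
negative (strict inequality). Defaults: C = 2⁰, γ = 2⁻⁹ for
selected-feature models, C = 2³, γ = 2⁻¹⁰ for the full 198 features. The
grid search sweeps C = 2⁻²..2⁴ and γ = 2⁻¹¹..2⁰ (84 pairs) maximizing
pooled out-of-fold MCC over seeded stratified folds, ties broken toward
the smallest C then the smallest γ.

## Feature selection

Features are ranked by mean |BCC| over the training sides of a stratified
k-fold partition, BCC = (M_e − M_ne)·√(n_e·n_ne/n)/stdev with the
population standard deviation; a zero-variance feature gets BCC 0, ties
keep canonical order. The printed normalizer √(n_e·n_ne/n) can exceed 1 in
magnitude (the textbook point-biserial divides by n); with n fixed the
ranking is identical, and only the ranking is consumed, so the formula is
kept verbatim. Backward elimination then sweeps the ascending-|BCC| list,
dropping any feature whose removal does not lower the cross-validated MCC,
and repeats full sweeps until a sweep removes nothing; one fixed seeded
fold partition is used throughout, so the procedure is deterministic and
the final MCC never falls below the initial one. `max_candidates`
optionally restricts the search to the top-m ranked features — a cost knob
for exploratory runs; the exhaustive sweep is the reference behaviour.

## Propensity aggregation

Schemes over a residue's 1–20 window scores: max; mean; median (mean of
the middle two for even counts); and the distance scheme — the mean of the
k scores farthest from 0.5 (default k = 16), using all m scores when
m < k, with |s − 0.5| ties resolved toward earlier windows. When k ≥ m the
implementation returns the plain mean directly, making the k = 20 case
bit-identical to the average scheme on interior residues. Chains shorter
than 20 residues are rejected; no padding rule is defined.

## Evaluation

Binary metrics from the pooled confusion table: accuracy, sensitivity,
specificity, precision, F-measure and MCC with the standard numerator
TP·TN − FP·FN (a legacy rendering of the formula with a plus sign is a
typo; the standard form is implemented) and MCC := 0 when any denominator
factor vanishes. AUC is the tie-corrected Mann–Whitney rank statistic;
a trapezoidal ROC integration is implemented independently and asserted
equal. The chain-level success rate is the fraction of chains whose mean
propensity over native epitope residues strictly exceeds the chain-wide
mean; equality counts as failure, chains without epitope residues are
excluded with a warning.

## Synthetic study conditions

The fixture generator fabricates every input with planted class structure
so each feature family carries real signal: epitope fragments over-sample
a hydrophilic residue set whose dipeptides score high on the generated
scale (effect `delta_raap` = 0.8); short epitope motifs are pasted into
epitope fragments with probability 0.9 (three 6-mers by default), driving
the similarity features; epitope residues are drawn more exposed
(`delta_rsa` = 0.3), more coil-biased (`delta_ss` = 0.3) and with more
concentrated WOP columns (`delta_con` = 0.5); 5% of WOP rows are zeroed to
exercise the fallback path. Sequences are i.i.d. draws from the
Robinson–Robinson background with geometric-run secondary structure;
channels are drawn jointly per residue so the combined feature groups see
correlated signal. Default problem sizes: 200 + 200 fragments and chains
of 50–80 residues — small enough that the full train→select→predict cycle
runs in seconds, large enough that held-out discrimination is stable.

What the generator does **not** emulate: real antibody–antigen binding
physics, sequence redundancy/homology structure between fragments,
realistic secondary-structure grammars, or PSI-BLAST search behaviour.
Passing the recovery tests therefore shows the pipeline extracts planted
signal of each kind end-to-end and sits at chance when classes are
exchangeable — not that any particular accuracy holds on real antigens.
With all effect sizes zero the classes are exchangeable by construction,
and held-out AUC on the null condition is asserted to lie in [0.4, 0.6].

## Known limitations

* Probability calibration uses libsvm's internal 5-fold sigmoid fit; the
  underlying solver makes scores reproducible only for a fixed seed and
  identical input order (both are fixed throughout).
* The exhaustive backward elimination over all 198 features with 10-fold
  CV is expensive (hundreds of SVM fits per sweep); tests and examples run
  it on reduced candidate sets.
* Binary fragment-level calls default to the 0.5 cutoff
  (`predict_fragments(..., cutoff=...)` overrides); no cutoff tuning is
  performed.
* Epitope boundary calling (start/stop intervals) is out of scope: the
  output is a per-residue propensity track.
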