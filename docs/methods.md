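# Methods

## Problem and model

The package predicts whether a serine or threonine residue in a
microbial protein is a phosphorylation acceptor. A site is represented
by a fixed-width peptide window of W = 2·h + 1 residues (default h =
10, W = 21) centered on the S/T; window positions beyond a protein
terminus carry the pad symbol `X`, as do non-standard residue letters
(B, J, O, U, Z), and pads contribute zero to every per-position
encoding. Positions and site tables are 1-based.

Classification is a three-stage pipeline: (1) encode windows into
numeric features, (2) rank features by a two-sample Wilcoxon rank-sum
test and keep the top k, (3) fit a random forest whose positive-class
score is the fraction of trees voting positive; calls threshold that
score at a stored cutoff. The pipeline assumes sites are exchangeable
given their windows (no protein-level effects) and that the training
site table is already homology-reduced — redundancy filtering is the
caller's responsibility.

## Encodings

* **AAC** — the fraction of each of the 20 amino acids among the
  window's non-pad positions (the center is included; pads are excluded
  from the denominator because they carry no compositional
  information). 20 features.
* **AFC** — k-spaced amino-acid pair composition: for each spacing
  k ∈ {0,1,2,3,4} and ordered symbol pair (a,b) over the 21-symbol
  alphabet (20 AA plus `X`), the count of window positions i with
  window[i] = a and window[i+k+1] = b, divided by the number of such
  pairs W−k−1. 5·21² = 2,205 features; within each k the 441 values sum
  to 1. The 21-symbol alphabet is forced by the dimension: 5·21² is the
  only factorization consistent with 2,205.
* **BE** — per-position one-hot over the 20 amino acids; pad positions
  are all-zero blocks. 20·W = 420 features.
* **AIP** — per-position physicochemical profile using 15 amino-acid
  index scales. Each scale is standardized to zero mean and unit
  variance across the 20 amino acids before use so the scales are
  commensurable; pads are 0. 15·W = 315 features. The shipped table
  (`data/aaindex15_synthetic.tsv`) carries the 15 standard index
  identifiers with best-effort reconstructions of the corresponding
  published scales (the canonical database is not redistributed here);
  after per-scale standardization only relative ordering and spread
  matter, and the table is swappable via `AAIndexEncoder(table=...)`.
* **SSF** — per-position predicted structural features (solvent
  accessible surface area; backbone torsions φ, ψ, θ, τ; secondary
  structure probabilities helix/strand/coil), sliced from a per-protein
  profile TSV; out-of-protein rows are zero. 8·W = 168 features.
* **PSSM** — per-position substitution log-odds sliced from a
  PSI-BLAST ASCII PSSM (only the log-odds block is parsed; the
  weighted-percentage block is ignored); out-of-protein rows are zero.
  20·W = 420 features.
* **PKA** — profile-based k-spaced pair composition: the windowed PSSM
  is rescaled elementwise by the logistic function 1/(1+e^(−x)), with
  pad rows forced to exactly 0 (not 0.5); the (a,b) feature at spacing
  k is Σᵢ P′[i,a]·P′[i+k+1,b] / (W−k−1). 5·20² = 2,000 features. This
  construction (logistic rescaling, product-sum, length normalization)
  is the standard profile-pair recipe used by related modification-site
  predictors; it is the least-constrained design point in the package
  and is isolated behind `encode_pka`.

The combined encoding concatenates AFC, AIP, BE, PKA in that fixed
order: 2,205 + 315 + 420 + 2,000 = 4,940 features. All flattening is
position-major; feature names carry the encoder tag, position offset
(−10…+10) and residue/scale/pair identity so selection output is
interpretable.

## Feature selection

Each feature gets a two-sided Mann–Whitney U test between the +1 and −1
classes: exact null enumeration when both classes have ≤ 20 samples and
the feature has no cross-class ties, otherwise the normal approximation
with midranks and continuity correction. Constant features get p = 1.
Features are ordered by ascending p; ties break by larger absolute
rank-biserial effect 2U/(n₁n₂) − 1, then lexicographic name, so the
ranking is deterministic and invariant to input column order. The
selected matrix keeps columns in rank order. Defaults keep the top
1,500 features for pS models and 2,100 for pT models; both are
arguments (`select_k`). No multiple-testing correction is applied —
the p-values are a ranking statistic, not inference.

Selection lives *inside* the estimator's `fit`, so cross-validation
refits it on each training fold and held-out labels cannot influence
the selected set; the test suite verifies this by showing that per-fold
selection on pure-noise features stays at chance AUC.

## Classifier and evaluation

Random forest defaults: 500 trees, √p features per split, unlimited
depth, fixed seed. The default grid for `grid_search` is
trees {100, 300, 500, 1000} × per-split features {√p, p/4}, scored by
mean stratified 5-fold CV AUC with ties broken toward fewer trees and
the smaller per-split count (making the result enumeration-order
independent). Naive Bayes, a single decision tree, an RBF-SVM and a
one-hidden-layer neural network are available behind the same
interface as baselines. The decision cutoff is a stored model field,
default 0.5.

Metrics: Ac = (TP+TN)/N, Sn = TP/(TP+FN), Sp = TN/(TN+FP),
MCC = (TP·TN − FP·FN)/√((TN+FN)(TP+FP)(TN+FP)(TP+FN)) with MCC defined
as 0 when a denominator factor vanishes. The ROC curve uses every
distinct score as a threshold; AUC is the trapezoidal area, which with
half-credit for ties equals the pairwise Mann–Whitney probability —
the suite asserts this identity exactly. Cross-validation is
stratified (per-fold class fractions within one sample of global) and
reports both per-fold and pooled out-of-fold results.

Two sweeps mirror common design questions: `window_sweep` re-extracts
and re-encodes at odd window sizes (default 7–25) and reports mean CV
AUC per size; `ratio_sweep` subsamples negatives to given
negative:positive ratios (uniformly, without replacement, seeded,
keeping all negatives with a logged warning when short) and reports
Sn/Sp/Ac/MCC/AUC per ratio.

## Enrichment analysis

`position_enrichment` compares residue usage per window offset between
positive and negative fragment sets: for each (offset, residue) cell
the foreground count is tested against the background frequency with a
two-sided exact binomial test; background frequencies are pseudocounted
(+0.5 per residue) so unseen residues cannot give p = 0; pads are
excluded from all denominators. Cells with p < α (default 0.05) are
labelled over- or under-represented by the sign of the pseudocounted
log-odds. This is a tabular two-sample-logo analysis; no graphical
logo heights are computed.

## Synthetic benchmark

The generator emulates the statistical structure the pipeline assumes,
not real proteomes. Each fragment is an independent window-length
"protein" with the candidate site at its center, centers alternating S
and T. Defaults — fixed once as the study conditions: 200 positives
and 400 negatives (the 2:1 ratio used for training), window 21,
uniform background over the 20 amino acids (real microbial backgrounds
are organism-specific and not modelled), and K/R enrichment in
positives only: K at offsets −3, −2, −1, +1, +2 with probability 0.55
and R at −6, −4, +4 with probability 0.45, mirroring the qualitative
basic-residue preference of microbial phosphosites. Synthetic PSSMs
give the observed residue a +7 log-odds bonus plus N(0, 2) noise,
rounded and clipped to ±12, which leaves per-row argmax identity above
80%; synthetic structural profiles draw non-negative ASA, uniform
torsions and Dirichlet(1,1,1) secondary-structure rows. Everything is
deterministic under the config seed.

What passing on this benchmark shows: the encoders, selector,
classifier and evaluation machinery are numerically correct and can
recover a planted positional signal of realistic strength at realistic
sample sizes. What it does not show: performance on real microbial
data, where signal is weaker, backgrounds are non-uniform, sites
cluster within proteins and homology structure matters.

## Numerical and design choices

* Exact-vs-asymptotic switch for the rank-sum test at class size 20;
  exact only without ties.
* MCC degenerate denominator → 0; all-pad fragments are rejected by
  AAC rather than returning NaN.
* Negative subsampling uses `floor(ratio · n_pos)` and preserves input
  order of the chosen negatives.
* Grid search and feature ranking have fully specified tie-breaks
  (documented above) so all results are reproducible bit-for-bit under
  one seed; the CLI derives every stage's randomness from its single
  `--seed` flag and writes a manifest (parameters + input checksums)
  next to each output.
* The benchmark sizes used by the acceptance script (600-fragment
  benchmark, 600-fragment ratio sweep, 60-fragment determinism check)
  were chosen to exercise the full default pipeline — 4,940 features,
  top-1,500 selection, 500 trees — at sample sizes where the planted
  signal is comfortably detectable.

## Known limitations

* Homology reduction, PSI-BLAST and structure prediction are out of
  scope; their outputs are parsed, not produced.
* The shipped physicochemical table is a reconstruction, not the
  canonical database export (see above); users wanting exact published
  scales should supply their own table.
* p-values from the selector are not calibrated for inference (no
  multiplicity correction), by design.
* Binary (checkpoint) PSSM formats are not supported; only the ASCII
  dialect.
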