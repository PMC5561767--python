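# Methods

## Problem and model

A self-interacting protein (SIP) forms complexes with copies of itself.
Given only a protein's sequence profile, the package predicts a binary SIP /
non-SIP label. Curated datasets for this problem are strongly imbalanced
(yeast: 710 SIPs vs 5511 non-SIPs, ≈1:7.8; human: 1441 vs 15,938), which is
the central statistical difficulty: an unweighted classifier can reach high
accuracy while recovering almost no SIPs.

The pipeline is: PSSM → LAG pooling → PCA → input scaling → weighted extreme
learning machine.

### PSSM ingestion

Profiles are PSI-BLAST `-out_ascii_pssm` files; the score matrix is the
first 20 integer columns (the log-odds block). The weighted-observed
percentage block is parsed and kept available, but PSI-BLAST's *score*
matrix is the log-odds block, and that is what the feature extractor
consumes. Column order is read from the file header, never assumed. File
positions are 1-based; all in-memory arrays are 0-based.

A single-sequence fallback profile sets row *i* to the PAM250 (Dayhoff) row
of the residue at *i* — the profile score formula with degenerate one-hot
frequencies. It carries far less information than a real profile and is
meant for smoke tests and for sequences without database hits, not as a
substitute for PSI-BLAST.

### LAG (Local Average Group)

Positions 1…L are partitioned into 20 contiguous groups with boundaries
b_g = floor(g·L/20); each group contributes the arithmetic mean of each of
the 20 residue columns, giving a 400-vector laid out as
index = (g−1)·20 + j. When 20 | L the per-group mean equals the
(20/P)-normalized group sum of the defining formula; the floor-boundary
partition with per-group means is its natural extension to other lengths
(group sizes then differ by at most one). Lengths below 20 are rejected;
lengths below 50 warn (curated datasets exclude such sequences, and the
groups degenerate to one or two positions).

### PCA

Classical PCA (centering, no variance scaling), default 400 → 300. Inside
any cross-validation or holdout split the model is fitted on the training
side only and applied to the test side; a `pca_fit_scope="all"` option
reproduces the alternative single-global-fit reading. Component signs are
fixed (largest-magnitude loading positive) so fits are deterministic, and a
requested dimension beyond the feasible rank is clamped with a warning. At
desk-scale sample sizes (n of a few hundred) the 300-dimension default
clamps to n_train − 1; the geometry check in the acceptance script uses
n = 500 so the full 300 dimensions are realized.

### Input scaling

Classifier inputs are affinely mapped to [−1, 1] using a single min/max
over the training matrix, fitted on training data only and persisted with
the model. Two choices here are deliberate:

* Scaling exists because the default activation tribas(z) = max(0, 1 − |z|)
  responds only for |z| < 1; raw LAG/PCA vectors have norms in the tens, and
  without scaling almost every hidden node saturates at 0, collapsing the
  hidden representation. Rescaling inputs to [−1, 1] is the standard ELM
  preprocessing convention.
* The scale is *global*, not per-feature. After PCA the trailing components
  are near-zero-variance noise directions; stretching each feature to
  [−1, 1] independently would amplify those directions to the magnitude of
  the leading components and bury the signal. One global range preserves
  the spectrum's relative scales.

### Weighted ELM

The hidden layer draws input weights i.i.d. uniform on [−1, 1] and biases
uniform on [0, 1] from one seeded generator recorded in the model;
activations: tribas (default), sigmoid, sin, hardlim, radbas. Output
weights solve a weighted ridge problem in closed form; the n × n ("right")
and L_h × L_h ("left") solutions are algebraically identical, and the
`auto` solver inverts the smaller matrix. With unit weights both reduce to
the unweighted ELM solution. Ties at score exactly 0 predict +1.

Weighting schemes: `none` (unit), `W1` (w_i = 1/n_class, the default), and
`W2` (W1 with the majority class further scaled by the golden ratio 0.618).
W1/W2 follow the established weighted-ELM literature; the weight of the
minority class relative to the majority equals the imbalance ratio, which
empirically trades a controlled amount of specificity for a large gain in
minority sensitivity (quantified by the acceptance script).

The kernel form stores the training inputs and solves
α = (I/C + W Ω)⁻¹ W p on the Gram matrix (linear, RBF, or the explicit
random tribas feature map, under which the linear kernel reproduces the
explicit path exactly). The dual derivation's Lagrange multipliers and
slacks are not materialized; only their closed-form consequence is.

Reference profile: tribas activation, 5000 hidden neurons, C = 100, scheme
W1. Tests and the acceptance script train with 50–200 hidden neurons and a
few hundred samples so the whole suite runs in seconds; the 5000-neuron
profile is asserted as the default configuration rather than trained, since
nothing about the closed-form solvers changes with scale.

### Evaluation

Positive class is SIP (+1). Ac, Sn = TP/(TP+FN), Sp, Pe, and MCC from the
confusion matrix; any zero denominator reports 0 and is flagged rather than
raising. ROC/AUC by threshold sweep with trapezoid integration, which
equals the Mann–Whitney pairwise statistic (tested to 1e−12 against an
explicit pairwise oracle). Cross-validation (default 5-fold) and the 1/6
holdout are stratified by default (unstratified available); aggregate rows
report mean ± population standard deviation. All splits, hidden layers and
simulations are driven by explicit seeds, and reports are byte-reproducible
under identical configuration.

## Synthetic data

The generator emulates the *statistical shape* of the benchmark, not its
biology: integer-rounded i.i.d. Gaussian PSSM entries (log-odds are small
integers), lengths uniform on 50–400 (curated sets exclude <50-residue
proteins), class imbalance 40:312 ≈ 1:7.8 matching the yeast composition,
and a class signal injected as a mean shift (+2.0 by default) on 4 of the
20 residue columns of positives — in PSSM column space, so the LAG pooling
is genuinely exercised rather than bypassed. It does not model
phylogenetic correlation between positions, domain structure, gaps, or
realistic residue composition; passing tests demonstrate the pipeline's
mechanics and its imbalance behaviour, not field performance on real
proteomes. Published benchmark accuracies require the curated datasets plus
PSI-BLAST against a reference database and are outside what synthetic data
can certify.

## Numerical choices

* Left/right β solutions agree to ~1e−12 at the sizes tested; the left
  (symmetric positive-definite) system is solved with a Cholesky-backed
  routine, the right (non-symmetric once W ≠ I) with a general solver.
* PSSM text round-trips exactly for integer scores and to 4 decimal places
  for fractional ones (the writer's declared formatting precision).
* PCA uses the full SVD solver for determinism.
* Grid search breaks ties toward the earliest grid point, in iteration
  order, and evaluates candidates only by internal CV of the training data.
* Model archives embed a SHA-256 checksum over the array payload; loading
  verifies it and refuses tampered files, so persisted models reproduce
  training-time scores bit for bit.

## Known limitations

* The pseudo-profile fallback discards all homology information; its
  predictions should be treated as a lower bound.
* Stratified splitting and population-std aggregation are conventions; both
  have flags/documentation but change reported std slightly versus
  sample-std conventions.
* Very short sequences (20–49 residues) are accepted with a warning but the
  group means then average 1–2 positions and are noisy.
* The imbalance weighting assumes the deployment class ratio resembles the
  training ratio; under a different prior the decision threshold (not the
  weights) should be recalibrated.
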