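# Methods

## The problem

Pseudouridine (Ψ) is the most common RNA modification; experimentally
mapping Ψ sites is slow, so sequence-based classifiers are used to flag
candidate sites. The unit of prediction here is a fixed, odd-length RNA
window (21 or 31 nt) centered on a uridine; the binary label says whether
that central U is pseudouridylated. `fkeerf` implements a fuzzy kernel
evidential random forest for this task: four sequence encodings are
concatenated, expanded through fuzzy-rule memberships, and classified by an
ensemble of evidential decision trees whose prediction goes through a
co-leaf kernel rather than a vote.

## Feature encodings

Four encoders, concatenated in a configurable order (default
binary, PSTNPss, NCP, PseKNC; 184 features for L = 21 with the default
PseKNC settings):

* **Binary** (4L): per-position one-hot, A→(1 0 0 0), C→(0 1 0 0),
  G→(0 0 1 0), U→(0 0 0 1).
* **NCP** (3L): per-position chemical-property triple (ring structure:
  purine = 1; functional group: amino = 1; hydrogen bond: weak = 1), so
  A→(1,1,1), C→(0,1,0), G→(1,0,0), U→(0,0,1).
* **PSTNPss** (L−2): a 64 × (L−2) table Z with
  `Z[s,t] = F⁺(s|t) − F⁻(s|t)`, the difference in relative frequency of
  trinucleotide *s* starting at position *t* between positive and negative
  *training* sequences; a sequence maps to the propensities of its own
  trinucleotides. Because Z is label-dependent it is refit inside every CV
  fold on that fold's training portion only — fitting it once on the full
  dataset leaks test labels and inflates CV scores (both protocols are
  available via `pstnpss_scope`; `fold` is the default and the honest one).
* **PseKNC** (4^k + λ): normalized overlapping k-tuple frequencies plus λ
  correlation tiers θ_n, where θ_n averages the mean squared difference of
  standardized dinucleotide physicochemical indices at sequence lag n; the
  correlation block is weighted by ω and the whole vector is divided by
  (Σf + ωΣθ), so it sums to exactly 1. Defaults: k = 2, λ = 2, ω = 0.1 and
  six standard RNA dinucleotide helical parameters (shift, slide, rise,
  tilt, roll, twist), z-scored across the 16 dinucleotides. These defaults
  are common PseKNC practice, exposed in `PseKNCConfig`; none of the
  package's correctness properties depend on the particular index values.

## Fuzzy feature expansion

The original feature space is enlarged with Takagi–Sugeno–Kang–style rule
antecedents. Features are z-scored with training-fold statistics (without
standardization, Gaussian memberships on the mixed-scale concatenation are
dominated by the encoders with the largest raw variance). Fuzzy c-means
(fuzzifier 2.0, tolerance 1e−5, ≤ 300 iterations, seeded center
initialization from distinct rows) clusters the training samples into K
rules; rule a gets per-dimension center c_j^a (membership-weighted mean)
and width σ_j^a = h × membership-weighted variance, floored at 1e−8 so
constant features stay finite. The membership weights enter these two
estimates unpowered; a `weights="powered"` flag applies the classical
u^fuzzifier weighting instead. The scale h defaults to 1.0 and is exposed.

A sample's normalized membership in rule a is the softmax over rules of
`log μ^a = Σ_j −(x_j − c_j^a)² / (2 σ_j^a)`. Two numerical notes:

* The membership is a product of ~184 per-dimension Gaussians, which
  underflows in direct form; the log-space softmax is mathematically
  identical, and a test pins the equivalence against the naive product at
  n ≤ 10 to 1e−10.
* The symmetric squared form above is what "Gaussian membership function"
  means; a non-squared variant `membership="asymmetric_exp"` (an asymmetric,
  sign-dependent exponential) is kept behind a flag for comparison only.

The expanded vector concatenates, rule by rule, μ̃^a · (1, x): K affine
copies of the standardized sample weighted by rule membership, dimension
(1 + n)K. Only antecedents are used — no TSK consequent is fitted; the
forest downstream is the discriminative stage.

## Evidential trees and the conflict criterion

Each training sample carries a mass function over the class frame
Θ = {+, −}; crisp labels become categorical masses (all mass on one
singleton). The split criterion is built from belief-function conflict:

* Jousselme distance `d_J(m_a, m_b) = sqrt(½ (m_a−m_b)ᵀ D (m_a−m_b))` with
  D the Jaccard similarity |A∩B|/|A∪B| over subset pairs (d(∅,∅) = 1 by
  convention; irrelevant in practice since ∅ never carries mass).
* Fair inclusion δ_F: the mean containment indicator over focal-element
  pairs, excluding Θ itself from both focal sets. When a mass is vacuous
  (all mass on Θ) its restricted focal set is empty and δ_F is undefined;
  this package defines it as 1, reading total ignorance as included in
  anything, so a vacuous mass conflicts with nothing (C = 0). This is an
  interpretive choice, pinned by a regression test.
* Conflict `C(m_a, m_b) = (1 − max(δ_F(a,b), δ_F(b,a))) · d_J(m_a, m_b)`.

Node impurity is the mean pairwise conflict over ordered sample pairs,
`Info(s) = ΣΣ C / (|s|² − |s|)` (0 for |s| ≤ 1), and splits maximize
`Info(s) − Σ_v (|s_v|/|s|) Info(s_v)`. For all-categorical masses C is
exactly the label-disagreement indicator, so Info reduces to the fraction
of discordant ordered pairs, computable from class counts in O(|s|); the
implementation uses this closed form as a fast path and keeps the O(|s|²)
pairwise computation for general masses. Tests assert the two paths agree
exactly and that the chosen split matches an exhaustive brute-force
maximizer on small inputs.

The criterion is stated over categorical attribute values; features here
are continuous, so standard binary threshold splits are used: candidate
thresholds are midpoints between consecutive unique values, thinned to at
most 32 quantile-spaced candidates per attribute (an exhaustive flag exists
for oracle tests). Determinism rules: a value equal to the threshold goes
left; gain ties break toward the lower attribute index, then the lower
threshold; `mtry = floor(sqrt(n))` candidate attributes are drawn per node
from a per-tree generator; `gain_tol = 1e−12`, `min_leaf_samples = 5` by
default, depth unlimited. Leaves store the average mass of their in-bag
samples and the in-bag ids.

## Forest and co-leaf kernel prediction

W trees (default 100) are grown on bootstrap resamples of size m with
replacement; each tree's generator derives from (seed, tree index), so the
forest is a pure function of data, parameters and seed. After growing each
tree, every training sample — in-bag or not — is routed through it once;
those leaf assignments back the kernel:

    K(x, x_i) = (1/W) · #{w : x and x_i reach the same leaf of tree w}
    F(x)      = Σ_i y_i K(x, x_i) / Σ_l K(x, x_l),   y_i ∈ {+1, −1}
    ŷ(x)      = sgn F(x),  with sgn(0) = +1 (pinned; the sign function is
                otherwise undefined at 0)

F is a convex combination of training labels, so F ∈ [−1, 1]; the
denominator is positive because x's leaf contains at least its own in-bag
samples. A brute-force double loop over trees × training samples is the
oracle for both K and F in tests — the implementation must equal it
exactly, no approximation.

Ablation variants are first-class: `erf` (no fuzzy expansion, no kernel;
predict by averaging the W leaf masses reached and maximizing pignistic
probability BetP(ω) = Σ_{D∋ω} m(D)/|D|, ties to the positive class),
`keerf` (kernel prediction on raw features), `fkeerf` (kernel prediction on
fuzzy-expanded features, the default). For ranking metrics the kernel
variants score with F and `erf` scores with BetP(positive).

## Evaluation protocol

Metrics follow the standard confusion-matrix definitions (SP, SN, ACC,
MCC, Precision, F1) plus AUC/AUPR computed from the continuous scores; MCC
(and other ratios) with a zero denominator are defined as 0.
Cross-validation is stratified k-fold (default 10) with seeded shuffling;
every label- or distribution-dependent stage — PSTNPss, the standardizer,
FCM, the forest — is refit per fold. Grid search covers the three
hyperparameters the method exposes for tuning (clusters K 3–10, trees W
80–220 step 20, minimum leaf size 3–10), selecting by mean CV accuracy
with MCC and then smaller W as tie-breaks.

## Synthetic data

`gen_sequences` draws uniform {A,C,G,U} windows with the center forced to
U and plants, in positives only, trinucleotides at fixed positions with
probability p. A trinucleotide (not single-base) bias makes PSTNPss the
sensitive channel while one-hot/NCP carry weaker positional signal —
qualitatively the encoder ranking seen on real Ψ data. The shipped
benchmark is L = 21, 100+100 sequences, two motif positions (starts 4 and
14, flanking the center), p = 0.85: strong enough for a comfortable
accuracy margin, small enough for full 10-fold CV of all three variants in
about a minute on one CPU. What it does **not** emulate: biological Ψ
context models, secondary structure, base composition bias, or
between-species differences — passing tests show the machinery is correct
and the pipeline detects planted positional signal, not that real-data
accuracies will match.

`gen_clusters` provides axis-aligned isotropic Gaussian blobs for FCM
recovery tests; `gen_masses` draws Dirichlet-distributed masses over
nonempty subsets (parameter 1/concentration, so high concentration gives
near-categorical draws) for belief-space property tests.

## Design choices where the design was open

* **Crisp labels as categorical masses.** Nothing else is available at
  training time; the belief machinery still pays off in the criterion's
  handling of mixed/ignorant masses and keeps the frame generic (written
  for N classes, shipped with N = 2).
* **Plain membership weights in the rule-bank estimates** (unpowered u),
  matching the estimator as commonly written; the powered variant is one
  flag away. Consequence: bank centers shrink toward the global mean
  relative to the FCM centers — harmless for the expansion, which only
  needs memberships, and covered by a structural recovery test.
* **Bootstrap size m, mtry = floor(sqrt(n))** — standard random-forest
  practice; both exposed.
* **Model JSON stores the training features and labels**, because co-leaf
  kernel prediction is defined relative to the training set; this makes
  save/load round-trips bit-exact at the cost of model size.

## Known limitations

* Kernel prediction is O(W · m) per query against the stored training set;
  this is inherent to the method, not an implementation shortcut.
* The exact PseKNC settings (k, λ, ω, index set) and fuzzy scale h used in
  prior work on the public Ψ benchmarks are not published, so accuracies on
  H_990/S_628/M_944 obtained with this package's defaults need not
  reproduce published tables; the CLI supports running those datasets when
  available.
* Trees are grown single-threaded; trees are independent given their
  generator streams, so parallelism is possible but not implemented.
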