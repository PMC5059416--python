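# Methods

## Problem setting

Shotgun proteomics identifies peptides by matching fragmentation spectra
against a protein database; statistical confidence is assigned by also
searching a reversed ("decoy") database and treating decoy matches as
draws from the incorrect-match score distribution. `percolite`
implements the statistical core of this workflow at three levels —
peptide-spectrum match (PSM), peptide, and protein group — together with
a synthetic benchmark that audits the protein-level estimates from the
outside.

## Target-decoy confidence estimation (`stats`)

For entities with scores `s` and labels target/decoy, the FDR at a
target-score threshold `t` is `(1 + #{decoys >= t}) / #{targets >= t}`,
and the q-value of a score is the minimum FDR over thresholds at or
below it, capped at 1. Design choices:

* **+1 pseudo-count** in the numerator: the standard conservative
  convention; it also keeps empirical p-values strictly positive, which
  Fisher's method requires.
* **No pi0 correction** (pi0 = 1): conservative; the decoy FDR this
  package emulates makes no such adjustment.
* **Ties**: thresholds use `>=`, so equal scores are accepted or
  rejected together, making results independent of sort order.
* **PEPs** are estimated as a binned decoy/target ratio
  (`min(1, d_i/t_i)` per equal-count score bin, default
  `n_bins = max(20, n/500)`), made monotone non-increasing in score by
  pool-adjacent-violators (isotonic) regression. This replaces the
  spline-based density estimator of the production tool family with
  something simple, monotone by construction, and directly testable.
  Below 20 targets or 20 decoys a single global bin is used.
* **Empirical p-values** are `(1 + #{decoys >= s}) / (1 + #decoys)`;
  Fisher's combination is the chi-square survival probability of
  `-2 sum(ln p)` with `2k` degrees of freedom.

## Digestion and protein grouping (`digest`, `grouping`)

Trypsin cleaves after K/R, suppressed before proline by default; with
`m` missed cleavages, every concatenation of up to `m + 1` adjacent
fragments inside the length window (default 7–50 residues) is a
theoretical peptide. Non-standard residues (B, Z, U, X) are digested
literally; I/L are not collapsed; modification annotations are stripped
before matching observed peptides to theoretical ones.

Grouping merges proteins whose theoretical peptide sets are identical or
nested (subset into its unique maximal superset), iterated to a
fixpoint. A protein whose set is a strict subset of two or more
non-nested sets is merged into *neither* — deterministic and
conservative. Targets and decoys group independently; group ids are
member accessions sorted bytewise, semicolon-joined. Only peptides
unique to one group (within their label class) carry inference
evidence. Grouping over *observed* peptide sets is also provided, solely
to reproduce the poorly calibrated shared-peptide-retaining mode.

## Semi-supervised rescoring (`rescore`)

Spectra are split into three cross-validation folds. Per fold, the
classifier is initialized with the single signed feature that passes
the most targets at `q <= q_train` (default 0.01), then iterates ten
times: score the training partition, take targets at `q <= q_train` as
positives and all decoys as negatives, refit a linear SVM
(squared-hinge, liblinear primal) with asymmetric costs. An iteration
with zero positives keeps the previous direction. Each PSM's final
score comes from the classifier whose *test* fold contained it.

* **Costs** default to `c_pos = 10`, `c_neg = 30`, exposed in
  `TrainConfig`; the production tool's nested grid search is out of
  scope, and fixed costs keep runs at desk scale and deterministic.
* **Subset training**: whole spectra are sampled without replacement
  until the requested PSM count is reached (target and decoy of a
  spectrum always travel together), the normal three-fold procedure runs
  on the subset, and *every* PSM is scored with the average of the three
  classifiers. The acknowledged train/test overlap of this scheme is
  accepted for simplicity; it is harmless at the large scales where
  subsetting is useful.
* **Score merging**: raw scores from different classifiers are not
  commensurable, so each classifier's scores are standardized by the
  decoy mean/sd of its training partition before cross-fold reporting or
  subset averaging. The choice of decoy-based standardization is this
  package's own; it is recorded in each `ScoreVector`.

## Protein inference and picked FDR (`inference`)

Peptide evidence (best PSM per distinct peptide per label) is
aggregated per group by one of four scorers: `best_peptide` (max
score), `two_peptide` (max score, but groups with fewer than two
distinct peptides at the peptide q threshold are removed),
`product_pep` (product of peptide PEPs, unscaled by protein length),
and `fisher` (combination of empirical peptide p-values; `k` counts
observed peptides only). The two-peptide rule ranks survivors by best
peptide score, keeping it comparable with the winning method.

The picked strategy pairs each target group with the decoy group whose
member set is exactly the reversed counterparts of its members; only
the better-scoring member of a pair survives, exact ties remove both
(unbiased under the null), and unpaired entries survive unchanged.
Survivors then receive protein-level q-values (lower-is-better methods
are orientation-normalized first).

## Entrapment benchmark (`entrapment`)

The benchmark concatenates a *sample* database with an *entrapment*
database built from it: each of `multiplier` (default 9) copies of each
sample protein is rebuilt from its tryptic fragments with every
fragment's residues shuffled, keeping the C-terminal residue fixed so
tryptic boundaries and digestion statistics survive. A globally chosen
`floor(shared_rate * n_peptides)` (default 4%) of distinct sample
peptides stays unshuffled in every copy, emulating shared peptides.
Shuffles retry up to 10 times on identity or collision with a sample
peptide, then accept and flag. A shuffle can still move a proline (or an
internal K/R) next to a cleavage site; this is accepted rather than
repaired, so re-digestion reproduces the source's fragment length
multiset only for proteins without such churn (~14% at these sequence
statistics) — fragment composition and boundaries at construction time
are preserved exactly, and the verbatim shared-peptide fraction measured
by re-digestion still rounds to the configured 4%.

Matches to the sample part are assumed correct, matches to the
entrapment part are known false positives; the cumulative entrapment
fraction of the ranked accepted targets is the *entrapment FDR*, and
the calibration curve pairs it with the reported decoy q-values. With
multiplier `m`, incorrect matches land in the sample part with
probability `1/(m+1)`, so the entrapment FDR undercounts true false
positives by a relative `1/m` (~11% for `m = 9`) at PSM level; at
protein level correct sample proteins conceal most strays.

## Synthetic data (`simulate`)

Random proteins use a 20-letter alphabet with K+R at 10% combined
frequency, putting the mean tryptic fragment length near 10 residues.
Each spectrum yields one target and one decoy PSM. With probability
`prop_correct` (default 0.5) a spectrum has a correct explanation: a
peptide of a "present" protein whose features are shifted by
`effect_size` (default `(3, 1, 0.5, 0, 0)` standard deviations, one
strong feature plus weaker and null ones, exchangeable correlation 0 by
default). Decoy features always come from the null distribution.

Because a real search engine reports the best of *many* target
candidates, every spectrum also carries an incorrect-candidate null
draw, and the target row is the better of (correct, incorrect) by the
most informative feature; the ground-truth sidecar records which won.
Without this, the decoy search would hold a lottery ticket the target
search lacks on correct spectra, decoys would outnumber incorrect
targets in the upper tail, and decoy q-values would be structurally
~1.5–2x conservative — a generator artifact, not a property of the
method. Decoy and incorrect-candidate draws remain exchangeable, which
is the assumption all decoy-based FDR guarantees rest on.

The calibration pipeline applies winner-take-all target-decoy
competition per spectrum before peptide collapse, matching the
production default; this keeps surviving decoy counts in line with
surviving incorrect-target counts when many spectra are correct.

What the generator does *not* emulate: fragment-spectrum physics,
retention time, intensity-dependent score distributions, homology
structure in shared peptides, or abundance-weighted peptide sampling.
A green calibration test therefore establishes that the estimators are
correct *given* exchangeable decoys, not that real data satisfies
exchangeability.

## Numerical and scale choices

* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); derived seeds use `SeedSequence` and
  stay below 2^31. Pipelines are bit-deterministic given (data, seed).
* The large-scale checks run at desk scale: 200K PSMs for
  subset-training stability and method ranking, 1,000 sample proteins /
  50K spectra per seed (seeds 1–5) for calibration — the same
  proportions as the full-scale experiments they mirror, at roughly
  1/400 the size.
* The calibration band [0.67, 1.5] is evaluated on the mean entrapment
  FDR across the five seeds at a fixed grid of decoy-q thresholds in
  [0.01, 0.1]; per-seed entrapment counts at the 1% threshold are ~10,
  so per-seed per-point ratios carry ~30% binomial noise by
  construction.

## Known limitations

* PEP estimates are step functions over score bins; they are monotone
  and consistent but coarser than density-based estimators.
* The two-peptide rule's ranking statistic and the Fisher `k` are
  underdetermined in the literature this follows; the choices above are
  fixed and documented rather than tuned.
* Entrapment construction models shared peptides as uniformly scattered
  singletons; real homology clusters shared peptides and raises the
  shared rate far above 4% in redundant databases.
* Protein-level PEPs and Bayesian (Fido-style) inference are out of
  scope.
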