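# Methods

## The classification problem

The input is a screen of compounds, each with a binary molecular fingerprint
(fixed length L, default 1024), a docking score in kcal/mol against the
androgen receptor, and — for training — a binder/non-binder label
(binder = 1 throughout). Two properties dominate the design:

* **Zero inflation.** Docking fails to produce a pose for a large fraction
  of compounds (about half in the screen this package models); those
  compounds carry the sentinel score 0, which is not a binding energy.
* **Class imbalance.** Binders are outnumbered roughly 7:1
  (205 vs 1480 in the training conditions), so accuracy alone is a poor
  guide and the metrics suite emphasises MCC, likelihood ratios and BCR.

## Building blocks

**Threshold rule.** Binder iff score ≤ t, default t = −7 kcal/mol
(approximately sub-micromolar K_d). The tie at exactly t classifies binder;
the 0 sentinel always falls above t and is a non-binder under this rule.

**Class-conditional Gaussians.** Each class's non-zero scores are summarised
by a sample mean and SD (n−1 denominator). Sentinel scores are excluded from
fitting by default (`exclude_zero=True`): including a point mass at 0 would
corrupt both means, and the model is meant to describe the posed compounds.
Classification is by density ratio with exact ties going to non-binder —
the conservative call in a screen where false positives are plentiful.
With unequal SDs the decision boundary is the root set of a quadratic in the
score, so there are at most two crossings; the tests verify the classifier
flips exactly there. The density is the standard normal pdf; a
`printed_variant` flag reproduces a corrupted rendering of the formula
(exponent denominator 2πσ² instead of 2σ²) that circulates in the
literature, for sensitivity checks only.

**Panel distances.** `avgD_Act`/`avgD_Inact` are arithmetic means of
Tanimoto (Jaccard) distances from a query fingerprint to every member of the
binder / non-binder reference panel. When the query is itself a panel member
(training-set evaluation) its own fingerprint is excluded (leave-self-out);
otherwise its zero self-distance biases the own-class average low. Two
all-zero fingerprints compare at distance 0 ("identically empty"), with a
warning at the scalar API. Distances are computed on packed bit arrays with
hardware popcounts, blockwise to bound memory; a screen of ~1700 compounds
evaluates in well under a second.

**Logistic regression.** Plain maximum likelihood via IRLS/Newton with step
halving, tolerance 1e-8 on the relative log-likelihood change, and a cap of
100 iterations. Convergence requires two consecutive sub-tolerance steps;
the second Newton step polishes the solution so the score vector (gradient)
vanishes below 1e-6 at every converged fit. No regularization is applied —
the published coefficients are unpenalized MLEs on raw descriptor scales —
but a tiny optional ridge exists as a diagnostic fallback. Complete or
quasi-complete separation (all margins correctly signed and the likelihood
saturated near 0) is detected and reported: the fit warns, sets
`converged_ = False`, and keeps the finite coefficients of the final
iterate, so cascade procedures can still produce predictions while the
diagnosis stays visible. The classification cut-off is P ≥ 0.5.

## The 13 procedures

Procedures 1–5 are the building blocks used alone (1 threshold; 2 density
ratio; 3 univariate logistic on the density ratio; 4 like 2 but sending all
zero-score compounds to non-binder; 5 panel distances). Procedures 6–13
combine them:

* 6 — threshold on non-zero scores, panel rule for the zero-score compounds;
* 7 — panel rule first; its non-binders re-judged by the threshold;
* 8 — logistic on [score, avgD_Act − avgD_Inact];
* 9 — cascade of 6, with zero-score compounds whose panel distances tie
  (|avgD_Act − avgD_Inact| ≤ 1e-12, the only unresolved case) decided by 8;
* 10 — procedures 2 and 5 when they agree, else 8;
* 11 — logistic on [score, distance difference, density ratio];
* 12 — logistic on [avgD_Act, avgD_Inact, P_act, P_inact];
* 13 — logistic on all five descriptors.

Procedure 12's feature list is an interpretation: it is defined as the
consensus model's features with the docking score (and the ratio) replaced
by the two raw densities. Procedure 3's single feature is the density
*ratio* rather than one class density — the ratio is the quantity the
Bayes rule actually thresholds. Both choices are configurable only in code;
they are recorded here because the procedure names alone underdetermine
them.

Procedure-internal logistic models are refit on the provided training set by
default. For procedure 13 a `published=True` switch substitutes the packaged
coefficients (intercept 26.169; −0.0175 score, −98.582 avgD_Act,
+66.953 avgD_Inact, +3.584 P_act, −8.594 P_inact), making it a pure function
of the descriptor vector. The Bayesian-density descriptors are raw densities
(not normalized posteriors), matching the definition of the class models.

## Metrics

From a confusion matrix (positive class = binder): SP = TN/(TN+FP),
SE = TP/(TP+FN), Acc, PPV, NPV — reported in percent; MCC; +LR = SE/(1−SP),
−LR = (1−SE)/SP and BCR = (SE+SP)/2 · (1−|SE−SP|) with SE/SP as fractions.
Degenerate denominators are explicit: a zero factor under the MCC root
reports MCC = 0 with a flag, SP = 100% makes +LR `inf`, an empty predicted
class leaves PPV/NPV as NaN. ROC AUC is the Mann–Whitney rank statistic with
midrank ties — essential here because the sentinel places a large tied mass
at score 0 — with an orientation flag for "lower score = more binder-like".

## Synthetic screen generator

`SyntheticConfig` defaults encode the study conditions: 205/1480 class
sizes, zero fraction 0.5 per class, score Gaussians N(−8.91, 1.94²) and
N(−5.97, 2.01²) kcal/mol truncated to negative values (keeping 0
unambiguous as the no-pose sentinel; the truncation is mild, cutting less
than 0.2% of either class). Fingerprints come from one Bernoulli(density)
template per class with independent per-bit flip noise. The two free
parameters were fixed once at `fp_template_density = 0.05` and
`fp_flip_prob = 0.05`, giving ~50–100 set bits per 1024-bit fingerprint —
realistic sparsity for folded circular fingerprints of drug-like molecules.
A single `default_rng(seed)` stream with documented draw order makes
datasets bit-reproducible.

What the generator does **not** emulate: real chemical space has no single
per-class template, so real within-class similarity is far lower and
heterogeneous (series of congeners, singleton scaffolds, activity cliffs).
Consequently the fingerprint-based procedures are nearly perfect on
generator output (MCC ≈ 1), where the real screen reached MCC ≈ 0.3–0.53 —
and the refit logistic stages typically sit at complete separation, which
the fitter flags. Passing end-to-end tests on synthetic data therefore
demonstrate the plumbing, the ordering of weak vs strong procedures, and the
zero-score routing, not real-world performance levels. The docking-score
margin, by contrast, is faithful: the synthetic score-only AUC (~0.59
against the ~0.589 large-n value implied by the mixture) is deliberately
modest because half of each class sits in the tied zero mass.

## Numerical choices and edge cases

* Tanimoto of two all-zero fingerprints = 1 (warned); Jaccard distance
  satisfies the triangle inequality, property-tested on random triples.
* Probabilities are clamped to [1e-15, 1−1e-15] before log-likelihoods.
* Sample SDs use ddof = 1; a class whose usable scores are identical (SD 0)
  is rejected rather than silently producing a degenerate density.
* Thirteen-row suite runs share one Bayes fit, one panel, and one descriptor
  pass; the suite on the default 1685-compound screen completes in ~1.5 s.
* CSV output uses 6 significant digits; model JSON keeps full precision.

## Known limitations

* The published evaluation-set and reference-compound predictions cannot be
  regenerated without the original docking runs and fingerprints; the
  package reproduces their summary statistics from the published confusion
  matrices instead, and validates the AUC/likelihood machinery on
  constructed data.
* One published table of secondary statistics (PPV/NPV/LR/BCR per procedure)
  is internally inconsistent with the published confusion matrices; the
  formulas here are validated against the matrices, not against that table.
* The generator's fingerprint model is intentionally simple; see above for
  what that implies about synthetic results.
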