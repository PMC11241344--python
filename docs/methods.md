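# Methods

## Problem and model

`cppmine` treats CPP recognition as binary classification of short peptide
sequences (CPP = 1, non-CPP = 0) from physicochemical descriptors, followed
by ranking of digested proteome fragments with the trained classifier. The
classifier is a stacked ensemble: three heterogeneous base learners are fit
on the training split, an L2-regularized logistic meta-learner is fit on
their out-of-fold class-1 probabilities (seeded stratified 5-fold), and the
meta-learner's probability is the model output, thresholded at 0.5 for hard
classes. The working assumption is the classical one for CPPs: membrane
penetration correlates with cationicity, hydrophobicity/amphipathicity and
related bulk sequence properties, so composition-level descriptors carry
most of the usable signal.

## Descriptor conventions

**CTD.** Each of seven attributes partitions the 20 residues into 3
classes (the canonical Dubchak-style groupings, shipped in
`cppmine/_tables.py` and verified against the CTD literature; each table is
asserted at import to cover the alphabet exactly once with no empty class).
Per partition: 3 composition fractions C_k = n_k/L; 3 transition
frequencies T_kl = (n_kl + n_lk)/(L−1) over unordered class pairs; 15
distribution percentiles — for class k with n_k members, 100·pos/L of the
member at rank max(1, ceil(f·n_k)) for f ∈ {0, .25, .50, .75, 1.0}, with an
absent class contributing five zeros. Reference CTD codes differ in the
distribution rounding and in rounding transition values to 3 decimals; both
choices are pinned here (ceil-rank, no rounding) and the test oracles use
the same convention. A length-1 peptide has no adjacent pairs, so its
transitions are defined as zeros with a warning.

**Instability index.** II = (10/L)·Σ DIWV(x_i, x_{i+1}) over the published
400-entry dipeptide weight table (taken from Biopython's ProtParam data;
Biopython's own `instability_index` is used as an independent oracle in the
tests, never as the implementation). Undefined for L = 1 (raises).

**Global descriptors.** Net charge at pH 7.0 by Henderson–Hasselbalch over
the EMBOSS pKa set (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9,
E 4.1, C 8.5, Y 10.1); isoelectric point by root bisection of the same
charge function on (0, 14), clamped to the boundary when the charge does
not change sign; aromaticity = F+W+Y fraction; aliphatic index with the
Ikai weights (A 1.0, V 2.9, I/L 3.9, ×100); hydrophobic ratio = fraction of
residues in the hydrophobicity partition's hydrophobic class (C L V I M F
W), keeping the two definitions consistent; molecular weight from average
residue masses plus one water. Census: 147 CTD + 1 instability + 8 global
= 156 columns, logged by `featurize`.

## Curation and redundancy clustering

Curation order is non-natural → length → duplicate (first occurrence kept),
which makes the operation idempotent. Redundancy reduction is greedy
incremental clustering: scan longest-first, join the first cluster whose
representative matches at ≥ the identity cutoff, else found a new cluster.
Identity is exact matches ÷ shorter-sequence length in a global alignment
scored match +1 / mismatch 0 / gap −1 (Biopython `PairwiseAligner`). This
approximates, not bit-matches, CD-HIT; when several score-optimal
alignments have different match counts the aligner's first optimum is used
(the test oracle therefore checks membership in the achievable set). By
default clustering is applied to the non-CPP class only, mirroring common
practice of diversifying the negative set while keeping every scarce
positive.

## Feature selection

Zero-variance columns are dropped, then columns are scanned in input order
and dropped when |Pearson r| > 0.9 against an already-kept column
(keep-first; deterministic by construction). The survivors are standardized
and ranked by a linear lasso on the 0/1 label with the penalty chosen by
seeded 10-fold CV over a 50-point geometric grid; nonzero-coefficient
features are kept, capped at 20 by |coefficient| (reported in original
column order). An L1 logistic variant is available behind a flag.
Standardization inside the selector makes the kept set invariant to affine
rescaling of inputs. Degenerate case: on signal-free data the CV-optimal
penalty can zero every coefficient; the selector then keeps the single
column most correlated with the label (warned) so downstream fitting has an
input.

## Ensemble defaults and tuning

Defaults (k-NN 18/Manhattan/distance-weighted; boosting 250 rounds, depth
8, learning rate 0.0567, tree booster; forest 20 trees, log2 features,
Gini; split 85:15 shuffled, seed 40; 10-fold stratified CV) are the
grid-search optima for this task. The k-NN pipeline standardizes features
internally — descriptors span fractions to Daltons and Manhattan distance
is otherwise dominated by the largest scale. `grid_search` evaluates each
grid point by seeded stratified 10-fold CV and maximizes mean precision,
breaking ties by mean accuracy then grid order — precision-first because
the intended use is selecting candidates for costly synthesis, where false
positives dominate the budget. Splits use floor(0.85·n) training rows
(2380 → 2023/357). All randomness flows from one seed; reruns are
bit-identical on the same machine (single-threaded learners).

## Mining

Digestion uses the 35 ExPASy-style cleavage-rule regexes shipped with
pyteomics (census asserted in tests; every rule validated by
fragment-reassembly). Candidates are the union of per-rule fragments of
9–35 aa, deduplicated. The composition-diversity filter is a pinned
interpretation of limiting composition diversity to 30%: greedy scan in
input order, dropping a candidate whose 20-component composition-fraction
vector is within L1 distance 0.30 of an already-kept one (0 disables).
Ranked output carries provenance (source protein, rule) and sorts by
probability with sequence as a deterministic tie-break. Missed cleavages
default to 0.

## Synthetic data

The generator draws i.i.d. residues: CPP-like class from a table enriched
in R (0.20), K (0.15), W (0.08), L (0.10) with the remaining 16 residues
sharing the rest evenly; background uniform (0.05 each); lengths uniform on
5–30; `signal_strength` linearly interpolates the CPP table toward the
background. At full signal the CPP class carries ≈ +5 net charge on
average vs ≈ 0 for background. The toy proteome embeds an optional spike
peptide preceded by a lysine and followed by a non-proline, so spikes that
end in K/R, start with a non-proline and contain no unblocked internal
tryptic site are recovered verbatim by trypsin (the generator warns
otherwise).

What passing tests show — and don't: the generator reproduces the
compositional contrast between CPPs and background but none of the motif,
positional or length structure of real CPP databases, so green tests
certify pipeline correctness and sensitivity to compositional signal, not
real-world predictive accuracy. Under the default conditions the two
classes are *not* linearly separable: the Bayes-optimal log-likelihood-ratio
classifier tops out near ROC AUC 0.98 with precision ≈ 0.93 at the 0.5
threshold on balanced classes, which bounds what any fitted model can
achieve on this benchmark; the stacked ensemble's measured ≈ 0.90/0.956
sits close to that ceiling.

## Problem sizes

Tests and the acceptance script run the benchmark at 500 peptides per
class (85:15 split), 50 lasso-recovery replicates at n = 1000 × 155
columns, oracle sweeps over 200–1000 random peptides, cleavage reassembly
over all 35 rules × 100 random proteins, and a 25-protein × 120-residue
spike-in proteome (≈ 800 candidates after filtering) — sizes chosen so the
whole suite completes in about a minute on one core while keeping every
statistical check well-powered.

## Known limitations

* Identity clustering is O(n²) pairwise alignment — fine for peptide sets
  of a few thousand, not for proteome-scale redundancy reduction.
* The diversity filter and greedy clustering depend on input order (both
  documented and deterministic, but order-sensitive by design).
* Calibration of predicted probabilities is inherited from the logistic
  meta-learner; no explicit recalibration is performed.
* The descriptor set is composition-dominated; sequence-order information
  beyond adjacent-pair transitions is not captured.
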