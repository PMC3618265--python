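# Methods

## Problem framing

A drug–target pair is classified as interacting or not from the pair's
measured binding affinity. The inhibition constant K<sub>i</sub> (nM;
lower = tighter binding) is the label source: replicate measurements
for a pair are collapsed to their median (even counts: mean of the two
central values), and a pair is positive iff median
K<sub>i</sub> < threshold, default 10 μM = 10,000 nM, with a value
exactly at the threshold counted negative. Records whose free-text
species field contains any of *rat, rabbit, bovine, sheep, calf, pig,
mouse, guinea pig, dog, undefined* (case-insensitive substring) are
excluded before aggregation to keep the set human-specific; records
with no species annotation are kept. All K<sub>i</sub> input is
canonicalized to nM; a `ki` column with a per-row `unit` column
(pM/nM/uM/mM/M) is converted explicitly, never guessed.

## Pair representation (1191 features)

**Drug block, 1024 bits.** Linear atom–bond paths of 2–7 atoms are
enumerated without atom revisits, canonicalized, and hashed into a
1024-bit array (RDKit path fingerprint, branched paths disabled; the
toolkit and parameters are recorded in the fingerprint metadata).
Exact bit positions are a property of the hash; all downstream code and
tests rely only on determinism, atom-order invariance and Tanimoto
similarity. Bond-order-insensitive canonicalization is selectable
(`use_bond_order=False`) for users who want aromaticity ignored. A
molecule with fewer than two atoms has no qualifying path and maps to
the zero vector; Tanimoto similarity of two all-zero fingerprints is
defined as 1.

**Protein block, 167 values.** For each of seven physicochemical
properties — hydrophobicity, normalized van der Waals volume, polarity,
polarizability, charge, secondary-structure propensity, solvent
accessibility — the 20 amino acids are partitioned into three groups
(the classic three-group divisions used throughout the CTD literature;
the hydrophobicity division is validated against the package's worked
example) and the sequence is rewritten over {1,2,3}. Per property:
composition (3 percentages), transition frequencies T12/T13/T23 over
the N−1 adjacent positions (3), and distribution (15): for group *g*
with n<sub>g</sub> occurrences and fraction *f* ∈ {first, 25%, 50%,
75%, 100%}, the 1-based sequence position of the k-th occurrence with
k = max(1, floor(f·n<sub>g</sub>)) (k = 1 for "first"), scaled by
100/N. This quantile rule is the one that reproduces the worked
example's printed values exactly (25%×10 → 2nd occurrence, 75%×10 →
7th, 25%×5 → 1st). A group absent from a sequence contributes five
zeros so the vector length stays fixed. The 147 CTD values are followed
by the 20 AAC values, reported as percentages so both blocks share a
scale. Non-standard residues (X, B, Z, U, gaps) are rejected by
default, naming the offending character and position; an opt-in strip
policy removes them. Internally everything is full precision;
two-decimal values appear only in display and in the reference JSON.

The pair vector is the drug block followed by the protein block;
ordering inside each block is fixed, and an index map exposes each
property's column slice for ablation.

## Classifier

Random forest: *ntree* bootstrap trees (default 600), *mtry* features
considered per split under the Gini criterion, generalization error
estimated out-of-bag, predicted probability = fraction of tree votes
for the interaction class. scikit-learn's `RandomForestClassifier`
supplies the tree machinery (its OOB estimate aggregates per-tree
probabilities over out-of-bag trees, an equivalent-in-expectation
variant of vote counting); vote-fraction prediction and the permutation
importance convention (mean accuracy drop under feature shuffling,
seeded) are fixed in this package and recorded in the model metadata.
*ntree* = 600 is kept because OOB error changes by < 0.01 between 400
and 600 trees on the synthetic benchmarks; *mtry* is tuned by scanning
5–100 in steps of 5 and picking the lowest mean OOB error over five
repeated fits, ties toward smaller values. Training uses the class
balance as-is; `class_weight="balanced"` is available but off by
default. One master seed derives all per-fit seeds.

The baseline is a mixed Naive Bayes written in-package: Bernoulli
likelihood with Laplace (x+1)/(n+2) smoothing for the binary
fingerprint bits, Gaussian with a small variance floor for the
continuous descriptors, log-space accumulation. Keeping it independent
of scikit-learn's NB classes lets it serve as a genuinely separate
comparator for the forest.

## Evaluation

Five-fold stratified cross-validation (folds fixed by seed, sizes
within one) pools out-of-fold probabilities so every pair is scored by
a model that never trained on it. auROC is trapezoidal; auPRC is
average precision; confusion summaries (TP/FN/TN/FP, Sen/Spe/Acc as
percentages) count a score ≥ threshold as a predicted positive. The
K<sub>i</sub>-threshold sweep relabels the table at each threshold
(default 10–90 μM, step 5) and re-runs CV, skipping (with a warning)
any threshold that leaves a single class. The affinity–confidence
relationship is summarized by the Pearson correlation of
log<sub>10</sub>(K<sub>i</sub>) with the out-of-fold probability,
reported signed; base 10 is the documented choice of log base. Property
ablation removes one property's 21 columns (or AAC's 20) and re-runs
CV.

## Screening and FDR calibration

Every drug × target combination is scored into a dense probability
matrix (each cell identical to a one-at-a-time prediction). The cutoff
for a target FDR level is the smallest threshold over the sorted unique
pooled-CV scores whose FDR = FP/(FP+TP) is ≤ the level — the
recall-maximizing feasible choice, found by brute-force enumeration and
verified in tests against an independent exhaustive oracle. Since
precision = 1 − FDR at any cutoff, this coincides with reading the
cutoff off the precision–recall curve. Unattainable levels are reported
as such, never clamped. Edges at or above the cutoff, minus exact
(drug_id, target_id) matches to the training table when novelty
filtering is on, are exported as SIF, GraphML (bipartite, node-type
attributes) and CSV with a node-degree summary.

## Synthetic benchmark

The generator stands in for a curated affinity extract. Targets come in
families: family *f* draws each residue from hydrophobicity group
(*f* mod 3)+1 with probability `group_bias` (default 0.5), else
uniformly — at bias 0.5 the enriched group's composition exceeds the
uniform baseline by ≈ 30 percentage points, far above sampling noise.
Drugs come in classes sharing a core substructure (benzene, piperidine,
pyridine, ...) decorated with 1–3 random chain fragments; the grammar
guarantees syntactic SMILES validity and higher within-class than
between-class Tanimoto similarity. log<sub>10</sub> K<sub>i</sub>(nM)
of a pair is Normal(affinity[class, family], noise_sd): the log-normal
form matches the natural analysis scale of binding constants and puts
labeling ambiguity where noise_sd places it relative to the 10 μM
boundary. Optional replicate records exercise median aggregation, and
an optional fraction of non-human species strings exercises the
filter.

Presets (fixed, not tuned): **strong** — 4 families × 5 targets,
4 classes × 15 drugs (1200 pairs), matched mean log<sub>10</sub>
K<sub>i</sub> = 2, mismatched = 5, noise_sd = 0.5, so essentially only
matched pairs fall under the 10 μM threshold; **null** — identical
sizes with a uniform affinity matrix at log<sub>10</sub> K<sub>i</sub>
= 4, making labels coin flips independent of all features. Sequence
lengths are uniform on 100–300 residues, typical single-domain scale.

What passing on this benchmark shows — and does not. The planted label
is a pure drug-class × target-family interaction: marginally, every
feature is independent of the label. A forest recovers it (CV auROC
≈ 0.96–0.97); Naive Bayes, blind to feature interactions by
construction, stays near chance here, which satisfies the expected
NB ≤ RF ordering in an extreme form. Real affinity data have marginal
single-feature signal, correlated replicates, heavy-tailed class sizes
and assay heterogeneity that the generator does not emulate; synthetic
results validate the machinery, not real-data accuracy. Likewise the
ablation result (any single property omitted shifts auROC by < 0.05)
reflects the redundancy of the planted family signal across descriptor
blocks.

## Numerical and design choices

* Distribution quantile k = max(1, floor(f·n<sub>g</sub>)); absent
  group → five zeros.
* AAC on the percent scale; CTD block before AAC block; properties in
  the fixed order listed above.
* Ties at the probability threshold count positive; mtry ties break
  small; top-k importance ties break by index.
* Tests compare unrounded values at 1e-9; printed two-decimal values
  use round-half-even at display only.
* Problem sizes in the test suite (ntree 600 for benchmark CV, reduced
  tree counts for plumbing tests; 1200-pair benchmarks) are chosen so
  the whole synthetic suite runs in minutes on one CPU while keeping
  the statistical margins of the assertions.

## Known limitations

* No retrieval from BindingDB/PDSP/ChEMBL/DrugBank; users supply
  tables in the documented schema.
* Fingerprint bit positions are toolkit-specific; models are not
  portable across fingerprint conventions.
* FDR calibration assumes pooled CV scores are exchangeable with
  screening scores for drugs/targets similar to the training
  distribution; screening truly novel chemotypes weakens the
  calibration.
* The species filter is a keyword heuristic, not a taxonomy mapping.
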