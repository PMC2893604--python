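# Methods

## Problem and representation

The package predicts caspase cleavage sites — the peptide bond C-terminal to
a P4–P3–P2–P1 recognition motif, P1 almost always Asp — from primary
sequence alone, and uses the predictions to build cleavage-product FASTA
databases for tandem-MS searching. A candidate site is the 1-based index of
its P1 residue; the cut falls between P1 and P1'.

Each candidate is represented by the residue window of `n_left` positions
ending at P1 and `n_right` positions after the bond, one-hot encoded: every
residue becomes a 20-element indicator block, so a (6, 4) window yields a
200-element binary vector. The residue→index table is the frozen ordering
`RESIDUE_ORDER = "VLIMAFWYGPSTCNQDEHKR"`, fixing Val at block index 0 and
Ala at index 4. Any permutation of the
remaining assignments spans the same feature space; the test suite verifies
that retraining after a random permutation leaves the ν-SVM's decision
scores identical to 1e-9 (the RBF kernel sees only pairwise distances, which
a column permutation preserves exactly) and leaves the tree learners'
predicted labels unchanged on the benchmark corpus. Bit-identical tree
*structures* under permutation are not guaranteed: scikit-learn's tie-break
RNG consumes feature indices, so the invariance claim for the randomized
learners is at the level of predictions, not internals.

Windows that would overrun a protein terminus are *skipped* during training
(keeping the training matrix free of padding artifacts) and *padded* with
all-zero blocks during proteome scanning (so near-terminal sites are still
scored). Both policies are explicit options; the defaults reflect that a
curated training set contains no truncated windows while a scan must cover
every motif position.

## Classifiers

Three base learners are provided with the optimized configurations as
defaults:

* **svm** — ν-SVC with RBF kernel, γ = 2⁻⁵·⁵ (computed, not a rounded
  decimal), ν = 0.536, stopping tolerance 1e-5, window (6, 4). Backed by
  scikit-learn's `NuSVC`, which wraps libsvm. The decision score is the
  signed margin, threshold 0.
* **random_forest** — 143 trees, 4 features considered per split, unlimited
  depth, window (12, 12) (`RandomForestClassifier`). Score = fraction of
  trees voting positive, threshold 0.5.
* **decision_tree** — a CART-style tree standing in for Weka's J48/C4.5:
  entropy splits (C4.5's information criterion), minimum 5 objects per
  leaf, binary splits (inherent to CART), window (4, 2). C4.5's
  confidence-factor error-based pruning has no exact CART equivalent;
  pruning strength is instead exposed as `ccp_alpha` (default 0), and the
  J48-only flags (confidence factor 0.285, 3 pruning folds, subtree
  raising, Laplace smoothing) are accepted and persisted as advisory
  metadata. The 3-folds setting is only meaningful under reduced-error
  pruning, which is itself disabled in the reference configuration — an
  internal inconsistency we record rather than resolve. Consequences: the
  single tree's exact splits, and therefore its headline numbers, can
  legitimately differ from a J48 implementation; its qualitative behavior
  (weakest of the three, interpretable splits) is preserved.

The **Vote** ensemble returns positive only when strictly more than half of
its members vote positive — with the default SVM+RF pair, unanimity. Each
member extracts and encodes a site with its own geometry. When a member
cannot resolve a site (window overruns a terminus under the skip policy) it
abstains, and abstentions count as negative votes: the conservative choice,
consistent with using the ensemble for precision.

All stochastic training paths take an explicit seed (default 0); the ν-SVM
solver is deterministic. `save_model`/`load_model` persist a joblib bundle
plus a JSON sidecar (algorithm, geometry, hyperparameters, library version)
and verify the format version on load.

## Training data

Positives are annotated P1 positions; negatives are drawn from Asp
positions in the same proteins that are not annotated as cut. The default
negative policy is balanced 1:1 sampling, uniform over eligible positions
under a seed — curated substrate sets are reported balanced but without a
stated selection rule, so uniform sampling is the assumption, with an
exhaustive mode (every eligible Asp) also available. Duplicate windows are
removed so every training sequence is unique. A window occurring with both
labels is contradictory — in curated data a mis-annotation, in the
synthetic corpus a background Asp whose context coincidentally equals a
planted site's; because annotated positives precede the colliding
negatives, the default policy keeps the positive and drops the later
occurrence with a warning, while `on_contradiction="error"` makes the
collision fatal for pipelines that need a clean guarantee.

Because every negative also carries Asp at P1, the P1 block is constant
across the whole training matrix and carries no split information — the
test suite asserts the decision tree's feature importances are exactly zero
there, mirroring the known behavior of interpretable trees on this design.

## Synthetic corpus

`generate_synthetic_corpus` emulates a curated cut-site collection:
background residues i.i.d. uniform over the 20 amino acids, protein lengths
uniform on 120–400, and a Poisson(1.25) number of planted sites per protein
(≈1.24 sites/protein is the density of curated collections). Each plant
writes a P4–P1 motif drawn from the three canonical recognition classes —
(W/L)EHD (inflammatory caspases 1/4/5/13), DEXD (executioner caspases
2/3/7) and (I/L/V)E(H/T)D (initiator caspases 6/8/9/10) — with default
class weights 0.25 / 0.50 / 0.25 (the DEXD class dominates curated sets).
With probability 0.6 the P1' residue is set to a small amino acid (G/A/S),
reflecting the empirical informativeness of the residue immediately after
the bond and giving classifiers learnable signal on both sides of it.
Plants keep 16 residues clear of both termini (so every grid geometry can
see them) and are re-drawn on overlap (disjoint P4–P1' footprints, bounded
retries). The generator is deterministic under its seed and can return the
drawn class of every plant for frequency audits — necessary because the
classes overlap in sequence space (LEHD belongs to two).

What the synthetic corpus does *not* emulate: real amino-acid composition
(uniform background vs. biological frequencies), sequence homology between
proteins, structural accessibility of sites, and the label noise of
literature curation. Planted motifs against a uniform background are a much
stronger signal than real substrate specificity, so benchmark accuracies
(≈0.95–1.0) sit well above what curated data supports (≈0.82–0.87); passing
the benchmark demonstrates that the pipeline recovers a known signal and
that the Vote raises precision over its members, not that these accuracy
levels transfer to real proteomes.

## Evaluation protocol

Quality measures from the confusion matrix: ACC = (TP+TN)/N,
PRC = TP/(TP+FP), FDR = FP/(TP+FP) = 1 − PRC (the per-prediction false
discovery rate, not the multiple-testing quantity), SPC = TN/(TN+FP), and
MCC. Zero-denominator conventions: PRC/FDR are NaN with an explicit flag
when TP+FP = 0; a zero MCC denominator yields MCC = 0.

Leave-one-out retrains the model N times with fixed hyperparameters,
testing each held-out sample once; per-fold hyperparameter re-optimization
is deliberately not done (hyperparameters are selected once, then assessed
— the standard reading of the protocol). A fold whose training part loses a
class (tiny datasets only) predicts the remaining class with a warning by
default.

ROC curves are built from the continuous decision scores at every distinct
threshold (sklearn's sweep with no intermediate dropping), anchored at
(0,0) and (1,1), with trapezoidal AUC; tests cross-check the AUC against an
independent Mann–Whitney pair-counting estimator including ties. The Vote
is threshold-free and appears only as a point, via the bootstrap: 10 000
replicates resample the evaluated sites with replacement (the same
resamples for every classifier, so the comparison is paired), classify at
each classifier's fixed native threshold, and report mean ± sd of
(FPR, TPR). Replicates lacking either class are skipped and tallied.
Whether the bootstrap should consume leave-one-out predictions or a
held-out split is genuinely open; the default here is LOO-derived
predictions, with the `predictions` argument exposing the choice.

The benchmark protocol (`pripper.protocols.run_benchmark`) assembles
400 + 400 balanced sites from the synthetic corpus, LOO-evaluates each
configuration, aligns the members' per-site LOO predictions on their shared
sites (different geometries drop different near-terminal/duplicate sites)
to form the Vote, and bootstraps the aligned set. 400 per class matches the
scale of curated substrate collections while keeping the ~2 400 refits of
the full three-classifier protocol to a few minutes on one CPU; the
proteome-scale digestion check uses 1 000 proteins for the same reason.

## Digestion

`digest_proteome` streams a FASTA one protein at a time (memory bounded by
the largest protein), predicts sites with any classifier or the Vote, and
writes products in one of three modes: `single_site` (each cut on its own —
consistent with substrates being cleaved at one site at a time),
`all_sites` (all cuts simultaneously; concatenating the fragments in order
reconstructs the parent exactly), and `all_combinations` (every span whose
boundaries are cuts or termini; (k+1)(k+2)/2 spans for k cuts, including
the uncut parent). Identical spans from different cut subsets are emitted
once — MS search engines dislike duplicate entries — with provenance
preserved in the header
`{parent}|frag|{start}-{end}|cut:{p1,...}|motif:{P4P3P2P1,...}` (an
invented, documented convention; the original tool's header format is not
recorded). `min_fragment_length` (default 1) filters products too short to
be useful for identification. Proteins listed in a known-sites TSV
(`id<TAB>p1,p1,...`, 1-based) bypass prediction entirely, including an
empty list, which means "do not cut". The run summary (proteins processed,
proteins with ≥1 cut, total cuts, mean cuts per cut protein) can be audited
independently by re-parsing the output headers (`summary_from_fasta`).

With no cuts predicted, every mode emits nothing for that protein unless
`include_full_sequence` is set, in which case the intact sequence is
written with a `|full|` header (in `all_combinations` with ≥1 cut the
intact span already appears as the empty-subset product).

## Input handling and edge cases

FASTA I/O goes through Biopython; ids are the first whitespace-delimited
header token, sequences are upper-cased with whitespace stripped, output
wraps at 60 columns, and read∘write is the identity on ids and sequences.
Non-standard residue codes (B, Z, X, U, O, `*`) are rejected by default —
the classifiers are trained on the 20-letter alphabet — or, in relaxed
mode, mapped to a placeholder that encodes as an uninformative all-zero
block. Known-sites files collapse duplicate positions with a warning and
report parse errors with line numbers; out-of-range positions are detected
at digestion time, when the protein length is known.

## Known limitations

* The decision tree is CART, not J48; exact reproduction of a
  J48-trained tree (and its headline numbers) is out of scope.
* Only primary sequence is used: no secondary structure, solvent
  accessibility, or disorder features, which are known to improve caspase
  site prediction.
* The synthetic benchmark bounds what the tests can show (see above);
  performance claims on real proteomes require a curated collection loaded
  through `load_training_set`.
* Grid search re-evaluates the full LOO at every cell and is intended for
  the published step-2 grids, not for large hyperparameter spaces.
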