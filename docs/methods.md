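# Methods

This note documents the models, rules, and numerical choices behind
`seqdedup`, and what the synthetic benchmark does and does not establish.

## Record model

A record is reduced to the fields duplicate detection consumes: accession,
organism, DEFINITION line, literature references, submitters, the ORIGIN
sequence, and CDS features with translations. Coordinates are 0-based
half-open internally; the 1-based inclusive flat-file convention is
converted at the parser boundary. References whose title is "Direct
Submission" (or whose journal starts with `Submitted (`) are treated as
submitter declarations, not literature; their authors form the submitter
set, and a record with no such block has *absent* submitter information
(downstream `N/A`), which is distinct from an empty set. Joined or
complement CDS locations are extracted as the concatenated, strand-corrected
exonic sequence; the simple-span slice invariant is only guaranteed for
simple forward locations. Records without an ORIGIN sequence are rejected at
parse time — a record with no sequence cannot participate in any alignment
feature, and silently admitting it would poison the missing-value semantics.

Author names are compared as set elements, so they are normalized to a
lowercase `surname,i.` canonical form (punctuation stripped, initials
dotted). This is deliberately crude: it trades linguistic fidelity for
deterministic, reproducible comparisons.

## Alignment

Two backends satisfy one contract (hit flag + HSP list ordered by E-value,
then score):

* **Internal engine** — optimal affine-gap Smith–Waterman (biotite's DP)
  with nucleotide scoring +2/−3, gap open 5, extend 2, and BLOSUM62 with
  gap 11/1 for proteins: the classic BLAST parameterisations for these
  tasks. E-values use Karlin–Altschul `E = K·m′·n′·e^(−λS)` with the
  published gapped parameters (nucleotide λ = 0.625, K = 0.41, H = 0.78;
  protein λ = 0.267, K = 0.041) and the standard iterative effective-length
  adjustment, with `m, n` sorted first so E-values are exactly symmetric
  under argument swap. Suboptimal HSPs are found by masking the best HSP's
  span with `N`/`X` (strongly negative against everything) and re-aligning;
  by default only the best HSP is computed, because no feature consumes
  more. A configurable length cap (default 20 kb) guards the quadratic DP.
* **External engine** — `blastn`/`blastp` run query-vs-subject with
  low-complexity filtering off and minimum word sizes (4 / 2), parsed from
  tabular output.

The two backends agree on hit calls and identical-base counts for related
sequences; raw E-values differ (BLAST applies sum statistics and its own
edge corrections), which only matters within a factor of a few around the
report cutoff of 10. The 0.001 significance threshold is *not* applied at
alignment time; it is a downstream feature (`Over_Threshold`), so the
alignment layer stays a neutral measurement device.

`Identity` is `num_identical / alignment_length` including gap columns
(BLAST's convention). "Best HSP" means lowest E-value, ties broken by
higher score. `AP` uses the best HSP's identical-base count by default; a
`union` mode summing non-overlapping HSPs exists as a configuration switch
but is not the default, since overlapping-HSP sums can exceed the sequence
length and the single-best definition is conservative.

## Features and missing values

The 22 features and their couplings are schema-enforced: `*_HITS == No`
implies the dependent Identity/AP/E-value are missing (not zero) and the
corresponding `*_Threshold` is `Yes` — "no significant similarity" is the
extreme of a non-significant alignment, and this convention makes the NS
subtype rule total. Only the first CDS of each record is compared: CDS–CDS
in nucleotide mode, translation–translation in protein mode. Description
text is tokenized (lowercase, alphanumeric split), stopword-filtered
against a fixed ~30-word English list shipped with the package, and
lemmatized by deterministic suffix rules ("encoding" → "encode"); the
Jaccard of two empty token sets is defined as 0.0 because empty
descriptions carry no evidence of duplication. Literature is compared on
the pooled non-direct-submission references of each record: PubMed ID sets
first (Boolean intersection), then first-journal titles, then pooled author
sets.

## Classification

* **Subtype rule** (precedence NS → ES → EF): NS iff `Over_Threshold` is
  `Yes` (strictly E > 0.001, so E = 0.001 exactly is still significant);
  otherwise ES iff Identity ≥ 0.9 and AP ≥ 0.9 (inclusive); otherwise EF.
  NS is carved out first because a non-significant alignment invalidates
  the identity evidence the ES/EF distinction relies on. ES is judged on
  whole-sequence thresholds only, not CDS-level ones.
* **Seq90 baseline**: DU iff Identity ≥ 0.9 and length ratio ≥ 0.9; a pair
  without any hit has no identity and is classified DI.
* **Learned models**: Gaussian naive Bayes, a decision tree
  (scikit-learn defaults, fixed seed; scikit-learn applies no post-pruning,
  unlike some classic tree implementations — on the balanced corpora used
  here this changes little and is recorded as the library default), and an
  RBF-kernel SVM wrapped in a min-max scaler fitted on training data only
  (`clip=True`, so out-of-range test values cannot leak information), with
  Platt-scaled probabilities for AUROC. Multi-class SVM uses libsvm's
  one-vs-one scheme. Encoding: Yes/No flags → 0/1, Submitter one-hot over
  {SAME, DIFFERENT, NA}, missing similarities imputed to 0 and missing
  E-values to the report cutoff 10 — the `Has_*` indicators retain the
  missingness signal, so imputation adds no spurious information.
  The `Meta` feature set includes Submitter alongside the description and
  literature features (it is metadata of the same provenance).

## Evaluation protocols

Cross-validation is stratified with a fixed seed (variance reduction on
balanced data; a warning and non-stratified fallback fire when a class has
fewer members than folds). Metrics are pooled across folds (micro), giving
a single confusion matrix; AUROC is one-vs-rest per class on predicted
probabilities. Learning curves subsample each fold's training split at
fractions growing geometrically from 1% to exactly 100% (growth factor
configurable, default 1.05; protocol runs here use coarser factors such as
10 to keep three decades at modest cost) and record five metrics —
accuracy, precision and recall for DU and DI — over 20 repeats with
distinct derived seeds. The ablation sweep reuses one fold assignment
across the six feature sets so differences are attributable to features,
not fold noise. Error profiles average each numeric feature over false
positives and false negatives *excluding* pairs where the feature is
missing. Relative type accuracy credits a binary model on any duplicate it
calls DU and a multi-class model on any duplicate it assigns to *some*
duplicate subtype; DI requires an exact DI prediction. Generalisation
trains on one full dataset and tests on another, over all ordered pairs
(n·(n−1) reports).

## Synthetic corpus generator

The generator emulates the phenomenology the classifier must handle, not
any real organism's duplicate-type distribution:

* sequences are uniform-random DNA, 200–500 nt by default, optionally
  (p = 0.8) hosting one valid ORF (ATG, 20–60 non-stop codons, stop) whose
  standard-code translation fills the CDS translation field;
* **ES** partners: point substitutions at 0.5%/site by default on a copy of
  the parent; **EF** partners: a contiguous fragment of 30–70% of the
  parent, lightly mutated (0.2%/site), inheriting the CDS when it lies
  inside the window; **NS** partners: an independently drawn sequence with
  *shared* metadata — detectable only through description, literature, and
  submitter evidence, which keeps the class learnable; **DI**: two
  independent records; **DI_hard**: a near-identical sequence
  (0.2%/site) with fully disjoint metadata and submitter information
  withheld on one side half the time;
* duplicate partners share the parent's description tokens (occasionally
  perturbed), its literature reference with probability 0.8, and its
  submitters with probability 0.85; these sharing rates keep metadata
  informative but imperfect.

Mutations are substitution-only by default so the ES/EF boundary is
controlled by a single parameter; indel realism is out of scope. The
generator's known limitations define what passing tests show: uniform base
composition (no isochores, repeats, or low-complexity tracts, hence
dusting never matters), clean single-ORF gene models, a closed vocabulary
with sharply disjoint "hard" metadata, and class-conditional independence
of draws. Near-perfect classifier scores on these corpora demonstrate that
the pipeline is wired correctly and that each subtype is recoverable from
the features that define it — not that comparable accuracy would be reached
on real curated collections, where metadata noise and subtype boundaries
are far messier.

## Problem sizes and numerical choices

The standard benchmark sizes are chosen so every protocol runs comfortably
on one CPU: 2,000 pairs for the separable-corpus and learning-curve
experiments, 300 balanced pairs for the baseline-contrast corpus, five
80-pair datasets for the transfer sweep, and a 320-pair mixed corpus for
binary/multi-class cross-validation. All randomness flows from one integer
seed through `numpy.random.SeedSequence`; repeated runs are bit-identical,
and generated GenBank files carry a fixed date stamp so corpora are
byte-stable. Ties in classifier probabilities are resolved by scikit-learn's
deterministic argmax ordering.
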