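# Methods

This note records the models, conventions and numerical choices behind
`barcodedb`, in the order the pipeline applies them.

## Taxonomy resolution

Accessions are mapped to taxids through a `nucl_gb.accession2taxid`-dialect
TSV and taxids to lineages through `rankedlineage.dmp` (`\t|\t`-delimited
NCBI dmp dialect). Lineages hold exactly seven ranks (kingdom, phylum, class,
order, family, genus, species) and serialize with Greengenes/QIIME prefixes
joined by `"; "`; a missing rank serializes as its bare prefix (`c__`). We do
not back-fill intermediate missing ranks from neighbouring ranks — a bare
prefix states honestly that the repository carried no label, and back-filling
would inflate label entropy at that rank. Accession lookups strip a trailing
`.N` version but outputs keep identifiers as read. When the dmp species
column is empty and the row's own name is a binomial whose first token equals
the genus, the name fills the species slot (genus-level rows keep species
missing). Resolution failure is data, not an error: unresolved accessions are
listed and excluded, and an offline supplemental accession→lineage table can
stand in for records the two tables miss.

## Similarity engine

The contaminant and mislabel filters need blastn-like best-hit search;
`barcodedb` ships its own seeded local aligner so decisions are deterministic
and self-contained.

* **Seeding.** Subjects are indexed by exact k-mers (word size 11, ACGT words
  only). Candidates for a query are subjects sharing at least one word with
  either query strand; the shared strand(s) determine which strand is
  aligned. Subjects shorter than the word size are always aligned (both
  strands), so degenerate fixtures behave sensibly. A hit that exists only
  without any shared seed word is, as in any seeded search, not found.
* **Scoring.** Affine-gap Smith–Waterman (Gotoh), match +2, mismatch −3, and
  a gap of length L costs 5 + 2·L (open charged once plus extend per gap
  column) — megablast-style defaults, all configurable. IUPAC codes on either
  side match when their base sets intersect, and an intersecting column
  counts as a match in the identity numerator.
* **Reported statistics.** identity % = matches / alignment columns;
  query coverage % = aligned query span / query length.
* **Determinism.** Traceback tie-order is pinned (local zero ≻ diagonal ≻
  vertical gap ≻ horizontal gap; gap-open ≻ gap-extend on ties), hits sort by
  (score desc, identity desc, subject id asc), and repeated runs are
  byte-identical. The test suite checks score, match count, column count and
  query span against an independent full-matrix Smith–Waterman written in
  plain Python with the same pinned conventions.

## Curation rules

* **Cull**: discard when degenerate (non-ACGT IUPAC) bases ≥ 5 **or** a
  single-base A/C/G/T run ≥ 12. Both thresholds are inclusive and
  configurable.
* **Dereplication**: groups are byte-identical sequences. `uniq` keeps the
  lexicographically smallest identifier of each (sequence, lineage) class, so
  the set of represented species is invariant; `majority` keeps one record
  per group (smallest identifier) relabeled with the modal lineage, ties
  broken by the lexicographically smallest serialized lineage. Majority mode
  emits a warning: relabeling identical sequences with the most frequent
  taxonomy can propagate mislabels for markers with insufficient divergence.
* **Decontamination**: a record is removed when its best hit against the
  contaminant set reaches identity ≥ 90 % **and** query coverage ≥ 95 %
  (both inclusive). Multiple contaminant sets are applied sequentially with
  per-set provenance.
* **Mislabel filter**: each record is searched against the full database with
  no identity/coverage floor; among its 5 best hits (self-hit included,
  counted once; fewer if fewer exist) the record's own family label must
  appear at least twice — i.e. at least one neighbour corroborates it.
  Counting the self-hit and requiring ≥ 2 is equivalent to excluding self and
  requiring ≥ 1 corroborating hit. Records with a missing family label are
  kept and reported. The sole representative of a highly divergent family
  fails the rule by construction (collateral loss); an
  `exempt_singleton_families` switch retains such records instead. Family is
  the default comparison rank: identical marker sequences are routinely
  shared across species and sometimes genera, so a stricter rank would
  discard correctly identified records.

All filters preserve input record order, are idempotent, never add records,
and append one provenance entry (stage, parameters, counts, removed
identifiers with reasons) from which the stage-count report is rebuilt.

## Amplicon restriction

Primer sites are located by an ungapped sliding alignment of the primer over
the template; indels at the primer site are not modeled, which keeps the
match-fraction threshold exactly interpretable. A site is valid when
matching positions / primer length ≥ 0.8 (IUPAC intersection on both sides);
the highest-identity (then leftmost) forward site is chosen, then the best
reverse-complemented reverse-primer site downstream of it. Both template
orientations are scanned; when both succeed, the higher combined primer
identity wins, with ties broken by the lexicographically smaller amplicon so
extraction commutes with reverse complement of the template. Primers are
trimmed from the output (the inter-primer region is what sequencing reads
cover after primer removal). Records without a valid pair, or whose region
violates optional min/max length bounds, are dropped.

## Classifier and evaluation

* **Classifier**: multinomial naive Bayes (scikit-learn) over k-mer counts,
  k = 7, additive smoothing α = 0.001 — the conventional settings of
  k-mer-based taxonomy classifiers; both configurable. Classes are the
  distinct full serialized lineages of the training set; prediction is the
  maximum-posterior class, with ties resolved to the lexicographically
  smallest class (sklearn's sorted `classes_` plus first-maximum argmax).
  Records shorter than k classify from the priors alone and are flagged.
* **Entropy**: Shannon entropy in nats over the frequency distribution of
  distinct sequence strings (sequence entropy) or of labels at a rank
  (taxonomic entropy; records missing that rank are excluded from that
  rank's distribution).
* **Per-rank scoring**: at each rank, only records with a non-missing
  expected label count. Correct prediction → TP; present-but-wrong → FP
  *and* FN; missing prediction → FN. Precision = TP/(TP+FP),
  recall = TP/(TP+FN), F = harmonic mean; a rank with no scored records
  reports `None`. The FP-and-FN convention for wrong predictions is a pinned
  choice; it makes precision and recall coincide when every record receives
  a prediction.
* **Cross-validation**: `leaked` trains and tests on the full database
  (best-case ceiling); `kfold` shuffles records by seed, splits into K = 5
  folds, trains on the remainder and classifies the fold. Before scoring,
  each test record's expected lineage is truncated at the first rank whose
  label is absent from the fold's training set — without this, taxa whose
  only record is held out would make recall meaningless. Pooled metrics sum
  TP/FP/FN over folds and are invariant to fold order.

## Synthetic fixtures

The generator emulates exactly the structure the filters assume: a random
root sequence; per-family ancestors mutated from it at the inter-family rate
(default 0.30 per site); records mutated from their family ancestor at the
intra-family rate (default 0.02); one genus per family and, by default, one
species per record (`species_per_family` collapses records onto fewer
species). Mutation is substitution-only so identity arithmetic at filter
boundaries stays exact (an indel-enabled path exists in the test oracle
checks, not the generator). Defaults (20 families × 8 records, 300 nt) give
intra-family identity ≈ 96 % and inter-family identity well below 80 %, the
regime in which family labels are recoverable from sequence similarity.

Planted artefacts: mislabels swap a record's lineage to another family's, at
most one mislabel per (true family, planted family) combination so that
planted errors are mutually independent and each one is individually
recoverable; contaminants are GC-skewed random sequences plus optional exact
copies of database records (exercising the 100 %-identity path); exact
duplicates exercise dereplication; a degenerate-base count and homopolymer
run length can be injected to create cull targets; templates can be wrapped
in primer sites with a controlled number of site mismatches. Matching
accession2taxid and rankedlineage files are emitted so resolution round-trips
with zero unresolved records, and a truth manifest names every planted
artefact.

What the fixtures do **not** emulate: real marker length and GC
distributions, indel variation, rank-dependent label sparsity, or the
scale of repository downloads. Passing tests therefore demonstrate the
correctness of the rules and bookkeeping, not classification accuracy on
real markers.

## Problem sizes and reference conditions

* Mislabel recovery: 20 replicate fixtures of 20 families × 8 records with
  10 planted mislabels (160 records each) — large enough that every family
  retains a corroborating majority, small enough to run on a laptop.
* Cross-validation comparison: the "separable" fixture is 6 families ×
  6 records with 2 species per family (3 records per species), 300 nt,
  intra 0.02 / inter 0.30, seed 0. Leaked CV reaches species-rank F = 1.0
  there; 5-fold CV is lower because sibling species within a family are only
  ≈ 4 % apart.
* The `mixed` preset (pipeline demonstrations): 10 families × 8 records plus
  4 mislabels, 2 duplicates, 5 random + 1 exact-copy contaminants, injected
  cull targets, and primer-wrapped templates.

## Known limitations

* The seeded search can miss hits that share no 11-mer with the query; for
  the ≥ 90 %-identity decisions the filters make, shared words are
  essentially guaranteed, but very short or highly degenerate queries fall
  back only against short subjects.
* The mislabel rule inherits the blind spots of its original: correlated
  errors (several relatives mislabeled the same way) corroborate each other,
  and families with a single divergent representative are collateral losses
  unless exempted.
* Amplicon extraction does not model indels or thermodynamics; a primer site
  containing an insertion is simply a non-match.
* No confidence thresholding in the classifier: predictions are always
  full-depth lineages.
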