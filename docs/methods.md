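# Methods

This note records how the pieces of `chemnorm` are defined, the defaults
they ship with, and what the synthetic-fixture experiments do and do not
demonstrate.

## The normalization pipeline

The normalizer is a deterministic, dictionary-based entity linker. It
assumes mention spans are given (by gold annotations, an external NER model,
or the built-in dictionary tagger) and assigns each one a set of MeSH
descriptor ids. Design premises:

- **Precision-ordered cascade.** Matchers run from most to least strict and
  the first stage producing at least one MeSH concept is final. Stage order:
  exact match to MeSH, relaxed match to MeSH, relaxed-plural match to MeSH,
  relaxed match to auxiliary terminologies, relaxed-plural match to
  auxiliary terminologies. For the auxiliary stages a hit only counts if it
  actually reaches MeSH through a cross-reference — an auxiliary concept
  with no MeSH mapping does not stop the cascade, since the pipeline's
  currency is MeSH ids.
- **Exact match is case-sensitive** (whitespace-trim only). The relaxed
  stage exists precisely to introduce case folding, so applying it earlier
  would collapse the two stages.
- **The alphabetic-character precondition** (a mention must contain at least
  one letter) is checked on the original mention text, before abbreviation
  expansion, because expansion is defined on mention text that passes it.
- **Abbreviation expansion** replaces maximal tokens equal to a known short
  form, in a single pass; introduced text is never re-expanded. Definitions
  are detected per document; conflict resolution (highest aggregated count;
  ties to the longer long form, then lexicographic) can be scoped to the
  document (pipeline default) or pooled over the input collection. The
  document scope is the default because a collection at desk scale is not a
  meaningful frequency prior, and because local definitions are the ones an
  author actually intends.
- **Disambiguation** intersects a multi-candidate mention's set with the ids
  that occur unambiguously (exactly one candidate) in the same document, and
  applies the intersection only when non-empty. It can only shrink candidate
  sets.
- **Hierarchy filter.** Ids whose MeSH tree numbers all fall outside the
  chemical branches are removed. The shipped policy allows prefix `D` and
  denies `D08.811` (enzymes) and `D12.776` (proteins and peptides), the two
  macromolecule subtrees that chemical-annotation practice excludes; the
  longest matching prefix wins, so finer-grained overrides can be expressed.
  The policy is configuration, not a claim about the one true chemical
  subtree set.
- **Multi-candidate output.** When disambiguation still leaves several ids,
  all survivors are emitted as a composite (serialized sorted and
  comma-joined). Real corpora contain genuine multi-id assignments, and
  inventing a further tie-break would silently discard information. A
  mention resolving to nothing serializes as `-`.
- Input identifier payloads are overwritten, not merged: normalization is
  the assignment step.

## String normalization

The relaxed mapping is: full case folding (`str.casefold`, so ß→ss keeps
the mapping invariant under case changes), then ASCII folding, then every
non-alphanumeric character becomes a space, then spaces are removed unless
both neighbours are digits (runs collapse first). Digit-flanked spaces
survive so positional locants stay separated: `5,6-EET → "5 6eet"` but
`Triphenyl Phosphate → "triphenylphosphate"`.

ASCII folding is NFKD decomposition with combining-mark removal plus an
explicit Greek transliteration table (α→alpha … ω→omega, capitals likewise,
micro sign→mu) shipped as a TSV package resource so deployments can extend
it. Characters with no mapping are dropped. Greek letters get an explicit
table because they are the dominant non-ASCII case in chemical names and
have no NFKD route to ASCII.

The conservative plural stemmer operates per token: tokens shorter than 4
characters or containing a digit are untouched; `-ies`→`-y`;
`-xes/-ses/-zes/-ches/-shes` drop `es`; otherwise a final `-s` is dropped
unless the token ends `-ss`, `-us` or `-is`. The rules are deliberately
frozen and documented here because the tests' independent reference
implementation and the production code must share one definition; the
stemmer never lengthens a token, which bounds how much it can conflate.

## Abbreviation detection

The detector implements the classic parenthetical algorithm: for each
`(SF)` with 1–12 characters, at least one letter and not a stop word, the
short form's alphanumeric characters are matched right-to-left against the
preceding text; the first character must begin a word; the long-form window
is capped at min(|SF| + 5, 2·|SF|) words. This is a stand-in with the same
input/output contract as a production abbreviation detector (Ab3P); it
lacks Ab3P's statistical precision filters, which is why a TSV import path
for external detector output exists. A known consequence of the greedy
right-to-left match: a short form like *PP* against *propyl phosphate*
matches only *phosphate* — both P's are satisfied inside one word — so such
pairs are detected with a truncated long form.

## Evaluation and agreement

Strict-span scoring matches predictions to gold one-to-one on exact
(start, end) identity; with strict boundaries the maximum matching is the
multiset intersection of span pairs, which the tests verify against a
brute-force assignment oracle. Document-level concept scoring compares the
union of identifier sets per document (composites split into members;
unresolved mentions contribute nothing) and accumulates TP/FP/FN over
documents. Zero denominators yield 0 by convention.

Agreement units: identical spans with equal id sets → exact pair; identical
spans with different id sets → mismatch-ID pair (a composite versus a
proper subset counts as mismatch); every other annotation, including each
side of a partial overlap, is one single-annotation unit. Percentages are
over the unit total and reported to one decimal. Duplicate identical spans
(which the data model's validator rejects, but the counter tolerates) pair
greedily, equal id sets first.

Pre-annotation accuracy is the composition of the two evaluations with the
final corpus as gold: mention-level strict-span P/R/F and document-level
concept-set P/R/F. The document-level definition was chosen for the id-side
report because it is the same comparison used for normalization evaluation.

## Corpus selection and splitting

- Passage-count outlier filter: threshold = mean + 3·sample SD (ddof = 1) of
  per-document passage counts; strictly longer documents are removed.
- Dissimilarity weight: 1 − cosine between the document's TF-IDF vector and
  the centroid of already-selected documents, with idf = log(N/df) against a
  caller-supplied background; empty selection or a zero vector yields
  weight 1 (maximally novel).
- Model disagreement: 1 − mean pairwise Jaccard over the models' exact span
  sets; two empty sets count as agreeing. Jaccard was chosen because it is
  symmetric, bounded and parameter-free; the notion of "disagreement
  between taggers" is otherwise open.
- Combined score: a convex combination (coefficients must sum to 1) of
  entity-presence, disagreement, dissimilarity and a uniform[0,1) random
  weight from the caller's seeded generator. No published coefficient
  values exist for this kind of scoring, so the defaults are equal weights
  and every coefficient is configuration.
- Splitting: per annotation batch, partition quotas are allocated by
  largest remainder (each cell within 1 of exact proportionality), then
  over `n_restarts` seeded shuffles the plan minimizing the summed
  Jensen–Shannon divergence (base 2, over unigram token frequencies)
  between each non-empty partition and the full corpus is kept. JSD was
  chosen as the "word distributions approximate each other" metric because
  it is symmetric and bounded. Reported p-values are two-sided Welch t-tests
  of per-article chemical-annotation counts, partition versus full corpus
  (the full corpus includes the partition; with a partition equal to the
  whole corpus the comparison is degenerate and reported as p = 1).

## The fixture generator

The generator emulates: multi-word chemical names built from disjoint
syllable pools; case, hyphen↔space, Greek-letter and plural surface
variants, each applied independently at its configured rate (defaults 0.3);
parenthetical abbreviation definitions followed by bare short-form uses;
auxiliary-terminology synonyms reaching MeSH directly or via a shared CAS
key (cross-reference present at `xref_rate`); shared synonyms planted on
concept pairs as name-level ambiguity, always accompanied in-document by an
unambiguous co-mention of the intended concept; and disease/enzyme decoy
concepts whose gold identifier set is empty. Filler text comes from a fixed
word list disjoint from all name syllables, and parentheses occur only in
definitions. Abbreviations are planted only for (name, SF) pairs the
detector provably recovers in isolation, keeping the closed world closed.

What passing the closed-world test shows: the cascade, expansion,
disambiguation and filter compose correctly over the modeled transformation
space. What it does not show: performance on real literature, which
contains novel names, out-of-vocabulary variants, genuinely unresolvable
abbreviations, nested and discontinuous mentions, and annotation noise —
none of which the generator produces. The 100% recovery figure is a
software correctness statement, not an accuracy claim.

The simulated annotator independently drops a mention, swaps its identifier
for a random different one, or shifts one boundary by a character, at the
given rates. Under drop = swap = 0.2 and no boundary shifts, expected
agreement units are 64% exact, 16% mismatch-ID, 20% single; the calibration
test checks observed percentages within three binomial standard errors.

## Problem sizes and determinism

The shipped experiments run on 50-document collections (≈ 500 mentions,
~30 concepts plus decoys) for recovery and splitting, 100 documents
(≈ 1,000 agreement units) for annotator calibration, and 10,000 random
strings for the normalization property battery; these sizes give the
binomial checks standard errors near one percentage point while the whole
suite stays in the seconds range. Every stochastic component — generation,
perturbation, splitting restarts, the random selection weight — flows from
one explicit integer seed; the pipeline itself has no randomness, and
identical inputs produce byte-identical output collections.

## Known limitations

- The abbreviation detector is a parenthetical matcher, not a trained
  system; recall on real text will trail Ab3P.
- The dictionary tagger is a greedy longest-leftmost matcher at word
  boundaries; it cannot find plural variants (it indexes at the relaxed
  level) or undefined abbreviations, and makes no contextual decisions.
- Cross-reference joins are exact string equality after trimming; no CAS
  checksum or InChI canonicalization is attempted.
- Tree-policy prefix tests are plain string prefixes on dotted tree
  numbers; policies should use full dotted segments to avoid accidental
  prefix capture.
- `normalize_collection` holds the collection in memory; very large corpora
  should be processed in batches.
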