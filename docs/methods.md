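# Methods

This note documents the statistical procedures implemented in `emadhc`,
the choices made where the method family leaves room, and what the
synthetic-data experiments do and do not demonstrate.

## Corpus filtering

Records pass a four-stage cascade, applied in order and counted per stage:

1. drop records with empty or whitespace-only text;
2. drop records whose fitting country is not on the allowed list (default:
   Australia, Canada, England, Ireland, New Zealand, United States;
   matching is case- and punctuation-insensitive, with common ISO-style
   aliases such as `US`/`NZ` resolved);
3. drop records whose whitespace-normalized text has fewer than
   `min_chars` (default 20) characters — texts of exactly 20 characters
   are kept, reading "shorter than 20" strictly;
4. cleaning: drop texts whose share of alphabetic characters among
   non-whitespace characters is below 0.5, and texts consisting of a
   single repeated character run.  An optional replacement dictionary
   applies surface-level spelling fixes without dropping records, and an
   optional language predicate can be plugged in (default: pass-through).

Manual curation of clinical text (spelling correction, nonsense removal,
language screening) is not mechanically reproducible; stage 4 is an
explicit, configurable stand-in for it, not a reconstruction.  The cascade
is idempotent, and every removed record id appears in exactly one stage's
removal list.

## Lexical table

One statement is one text unit; no sub-segmentation is performed (the
35–40-word segmenting used for long documents is deliberately absent —
these texts average ~16 words).  Tokenization lowercases, keeps alphabetic
tokens with intra-word apostrophes, and discards punctuation and
standalone digits.  Lemmatization is dictionary-based: a bundled TSV maps
surfaces to (lemma, POS class) for function words, frequent irregular
inflections, and common hearing-aid domain vocabulary; misses fall back to
an identity lemma (with trailing possessive `'s` stripped) and are tagged
by a pluggable backend.  The default backend is a closed-class stoplist:
stoplist tokens are "other" (inactive), everything else is treated as an
active open-class form.  The bundled dictionary is small by design; users
with a full tagger can inject it through the `tagger` argument.

Columns of the binary matrix are lemmas of the four active classes
(adjective, noun, adverb, verb) with raw corpus frequency ≥
`min_frequency` (default 3, counted before binarization), capped at
`max_forms` (default 30,000) by descending frequency with alphabetical
tie-break.  Cells are presence/absence; repetition within a text does not
raise a cell above 1.  Units retaining no active form are excluded from
the matrix and reported as unclassifiable.  Vocabulary accounting (total
tokens, distinct forms, hapax count) is computed over all lemmatized
tokens before any filtering, so hapax shares can be reported.

Numerals and interjections are not singled out: standalone digits never
survive tokenization, and interjections are active unless stoplisted.

## The split objective and its optimizer

For a candidate bipartition of a cluster's rows, the two sub-matrices are
summed column-wise into a 2 × V contingency table and scored by
φ² = χ²/n (n = the table's grand total, constant across candidate splits
of the same cluster; columns with zero total contribute nothing).  φ² is
bounded by 1 for two-row tables, attained when the two sides share no
forms.

The initial cut comes from a correspondence analysis of the sub-matrix:
SVD of the standardized residuals of the row/column profiles,
S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}.  Rows are ordered by first-axis
standard coordinates (sign canonicalized so the first row with a nonzero
coordinate is negative; ties broken by row position), and all n − 1
contiguous cuts are scored.  Among cuts within 1e−12 of the maximal φ²,
the most balanced cut is chosen, then the lowest cut index.  Exact ties
essentially only occur on block-separable matrices, where several block
boundaries all reach φ² = 1; preferring the balanced one keeps the
recursion from isolating a single block prematurely.  A sub-matrix with
no non-trivial axis (e.g. identical rows) is flagged degenerate and the
leaf is frozen.

Refinement is a deterministic hill climb: sweep units in ascending unit-id
order; move a unit to the other side iff that strictly increases φ²
(tolerance 1e−12) and does not empty a side; repeat until a full sweep
accepts nothing.  Accepted φ² values form a strictly increasing sequence
over a finite state space, so termination is guaranteed; the sweep order
and strict-increase rule make the result deterministic.  The CA ordering
is not recomputed between sweeps (pure hill climbing on φ²).  On random
tables with ≤ 12 units the refined φ² is validated against exhaustive
enumeration of all bipartitions: it never exceeds the global optimum and
attains it on block-separable fixtures.  Hill climbing does not guarantee
the global optimum on arbitrary tables.

## Recursion, pruning, classification rate

The root is split first; thereafter the largest splittable leaf (by unit
count, ties by creation order) is split until the requested number of
terminal leaves (default 20) exists or nothing is splittable (leaves
below 2 units, or degenerate, freeze).  Size-priority from the root on
also means the two children of the root are split before any of their
own children of comparable size.

After phase 1, leaves smaller than ⌈n_texts / n_requested⌉ are pruned:
their units become unclassified.  Pruned units are *not* merged into
sibling clusters — no merging rule is part of the method as implemented,
and the divergence from tools that consolidate clusters in a second phase
is deliberate and documented here.  The classification rate is
(units in kept leaves) / (corpus texts), with corpus texts counting both
matrix rows and unclassifiable units.  Requesting K terminal clusters of
a corpus with k < K genuine themes relies on the sub-theme splits being
small splinters; this is what the pruning threshold removes.

## Cluster profiles

For each retained form and cluster, a 2 × 2 presence × in/out table over
classified units is scored with Pearson's χ² without continuity
correction (the convention of the descending-classification literature;
it keeps scores comparable across forms).  Forms present in fewer than 2
classified units are excluded as numerically unstable.  Characteristic
words are the over-represented forms (observed in-cluster presence above
expectation) ranked by χ², top 20 by default.  Characteristic texts are
in-cluster units scored by the unweighted sum of the χ² of the
characteristic forms they contain (each form counted once per text; ties
broken by unit id), top 3 by default.  The score is not length-normalized
by default — longer statements can accumulate higher scores — and a
normalization flag divides by the number of retained forms in the unit.

## Cluster × satisfaction association

The 2 × K table (positive/negative × kept clusters) excludes unclassified
units; whether such units should enter the test is a judgment call, and
excluding them matches a definition of the test population as "classified
statements".  The test is Pearson's χ² of independence without continuity
correction, df = K − 1, upper-tail p (the omnibus χ² test is inherently
non-directional; "two-sided" labels on such tests map to this upper
tail).  Cell directions are adjusted standardized residuals (Haberman):

    z_ij = (O_ij − E_ij) / sqrt(E_ij (1 − r_i/n)(1 − c_j/n)).

The adjusted form is chosen deliberately: in any 2 × K table the two cells
of a column then have exactly equal magnitude and opposite sign, which
raw Pearson residuals only satisfy under equal row margins.  χ² equals
the sum of squared (raw) Pearson residuals, an identity the tests check.

## Synthetic corpus generator

The generator emulates the marginal shape reported for clinical
self-initiated EMA corpora:

| feature | default | rationale |
| --- | --- | --- |
| per-listener EMA count | geometric(p = 0.33) truncated to [1, 90] | median 2, IQR 1–4, long tail |
| tokens per text | negative binomial, mean 16.6, dispersion 4, ≥ 1 | ≈ 145,926 words / 8,793 texts |
| rating split | theme-level P(positive) averaging ≈ 0.39 | 39/61 positive/negative |
| country / tech-level marginals | US-dominant; premium-heavy 5-level ordinal | reported sample composition |
| latent themes | K = 7 disjoint cores of 8 lemmas | the reported theme count |
| shared pool | 400 lemmas | see below |
| mixing α | 0.8 | theme tokens dominate |

Each text draws a theme uniformly, then tokens i.i.d. from
α·uniform(core) + (1 − α)·uniform(shared).  Vocabulary lemmas are
pronounceable synthetic strings disjoint from the stoplist, so the core
algorithm is tested without lemmatizer interference; real-word corpora
exercise the lexicon module separately.  Everything is reproducible from
a single seed.

Core and shared pool sizes were calibrated against the observable
clustering behaviour of the clinical analysis this emulates: with 20
requested terminal clusters, ~7 clusters survive a threshold of
n/20 and ~97–99 % of texts are classified, i.e. splits below the theme
level peel small splinters rather than halving themes.  Small cores (high
within-theme lexical concentration) and a large, individually-rare shared
pool reproduce exactly that behaviour; small shared pools make within-
theme noise splits balanced and keepable, which over-segments the themes
and is inconsistent with the reported classification rates.  Theme rating
probabilities (0.34–0.44) are deliberately mild so the cluster ×
satisfaction association sits at trend level, as in the clinical report.

What the generator does *not* emulate: Zipfian form frequencies (uniform
pools produce almost no hapax forms, versus ~44 % of distinct forms in
real corpora), spelling errors, multiword expressions, listener-specific
style, or temporal structure.  Passing recovery tests therefore shows the
pipeline recovers clean latent lexical structure at realistic corpus
shapes; it does not certify performance on the messier lexical
distributions of real clinical text.

## Recovery experiments

On study-conditions corpora (7 themes, 2,000 texts, α = 0.8) the
end-to-end pipeline — including the 20-character filter, frequency-3
vocabulary cut and 20-cluster request — recovers the generating partition
with adjusted Rand index ≥ 0.99 across seeds (computed over classified
units; ARI = 1 exactly at α = 1).  Recovery degrades as α approaches the
uniform-mixture limit, monotonically in expectation though not
necessarily seed-by-seed.  Problem sizes throughout the test suite
(hundreds to 2,000 texts, tables up to ~12 units for exhaustive oracles)
were chosen so the full validation runs in minutes on one CPU.

## Numerical and degenerate-input conventions

- φ² guards: a side with an all-zero margin raises a degenerate-split
  error; zero-total columns are skipped.
- CA is attempted only on sub-matrices with ≥ 2 units; columns with zero
  total within a sub-cluster are dropped locally (no effect on φ²).
- Move acceptance uses a strict 1e−12 margin, so floating-point noise
  cannot cycle the hill climb; a 200-sweep cap is a safety net that is
  never reached in practice (convergence is asserted in tests).
- All tie-breaks (cut choice, sweep order, largest-leaf choice, form
  ranking, text ranking) are fixed and documented, making every run of
  the core deterministic; the only randomness in the package lives in the
  synthetic generator and derives from its seed.

## Known limitations

- The bundled lemma dictionary is a compact demonstration dictionary, not
  a full English lexicon; untagged open-class tokens default to the
  generic active class, so POS-based exclusion is only as good as the
  dictionary/stoplist coverage.
- Hill climbing optimizes each split locally; no backtracking across
  splits.
- Pruning-only consolidation can leave more clusters than the number of
  interpretable themes if sub-theme splits are large; the requested
  cluster count is an exploratory knob, as in any descending
  classification workflow.
- The χ² independence test treats statements as independent units,
  ignoring that listeners contribute multiple statements.
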