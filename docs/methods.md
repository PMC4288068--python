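# Methods

This note documents the model behind `portalcurator`, its parameter
defaults, the numerical and design choices made where the procedure was
genuinely open, what the synthetic-data generator does and does not
emulate, and the known limitations.

## The content-management model

A portal's content situation is modelled by four entities: the target
audience **A** = {a₀ … aₙ} partitioned into subgroups with similar
information needs (expressed as attributes such as level of knowledge,
age group, stage of illness, user role); the domain ontology **T** =
{t₀ … tₚ} of expert-chosen subject terms; the endorsed content **D** =
{d₀ … dₘ}; and the expert transformation **E** mapping (subgroup, term)
requirement pairs to the subset of D addressing them. E is held as a
sparse matrix — real portals populate only a small subset of A × T —
and is serialized as a JSON manifest (resources with title, authors,
ISO-8601 date, linked term labels; ontology terms with optional parent
and weight; audience attributes) beside a directory of UTF-8 text
bodies. Audience tagging of individual matrix entries is supported but
optional; untagged entries apply to every subgroup. Resource–term links
are validated on load (unknown terms, missing bodies, duplicate
identifiers, ontology parent cycles all fail fast with the offending
names).

## Query construction

Queries combine the ontology term, high-level domain terms for context,
audience attribute values, and synonyms. Expansion is one dimension per
level — level 0 the base query, level 1 one audience value at a time,
level 2 one synonym substitution at a time — so the query list grows
linearly, never combinatorially. Multi-word terms are synonym-expanded
token by token. A search *fails* when it returns fewer than
`min_results` (default 5) valid hits, a threshold the source procedure
leaves unquantified; failed queries are reconstructed by substituting
the next-ranked unused synonym for one base token at a time until all
synonyms (capped at 3 directly-related + 3 inherited per token) are
exhausted. Reconstruction keeps a history set so no query string is
ever issued twice.

The synonym provider is an interface. The bundled provider is a static
JSON dictionary (`{token: {direct: [...], inherited: [...]}}`, lists in
relevance-rank order) seeded with the palliative-care demonstration
entries; deployments with a lexical database available can substitute a
provider backed by it without touching the pipeline. Audience values
are appended as plain terms, not fielded operators, since no engine
dialect is assumed.

## Content acquisition

Backends implement `submit(query, top_k) → ranked hits`. The bundled
local-corpus backend ranks a directory of text files by tf-idf cosine
(scikit-learn vectorizer) and is the default in offline mode; a web
backend is a stub to be implemented against whichever engine a
deployment licenses. Cross-engine fusion keeps the minimum per-engine
rank per canonical URL (lowercased host, fragment and known tracking
parameters stripped, trailing slash trimmed). Misrepresentation
screening removes, in rank order so the operation is idempotent:

* **near duplicates / revisions** — character 5-shingle Jaccard ≥ 0.9
  against an already-kept document;
* **index / link-farm pages** — anchor text exceeding 60% of visible
  characters in the raw HTML;
* **search-result pages** — configurable URL pattern list.

The duplicate threshold, anchor fraction, and pattern list are this
package's choices; the source procedure names the categories but no
mechanisms. Text extraction handles HTML (lxml, with nav/header/footer/
aside/script/style/form chrome removed), XML, and plain text;
extractions under 50 characters are dropped as empty, and unsupported
content types (e.g. PDF) are skipped with a logged reason. Publication
dates are read from standard metadata tags when present, else absent.

## Term recognition

Preprocessing lowercases, strips punctuation, masks stop words (bundled
~140-word list, overridable), and applies the classic Porter stemmer
(implemented in `stemmer.py`, faithful to the original rule tables).

Candidate multi-word terms are token n-grams of 2–5 tokens whose
boundary tokens are content words and whose interior contains no stop
word except an embedded preposition between content words ("quality of
life"). This closed-class filter replaces a POS-tag-based linguistic
filter to keep the core dependency-light; the filter is a small
function and can be swapped. Candidates are keyed by stem sequence so
inflected variants collapse; the most frequent surface form is kept
for display. Frequencies count every occurrence including nested ones,
and T_a links each candidate to the longer candidates containing it.

C-value discounts a nested term's frequency by the mean frequency of
its containing candidates. NC-value adds a context factor: context
words are content tokens within ±2 tokens of a candidate occurrence,
weighted by the fraction of top-ranked candidates (top 20% by C-value)
they co-occur with — the 0.8/0.2 blend follows the established
weighting. The ontology-extended NC-value re-weights to 0.6/0.2/0.2 so
context and domain evidence contribute equally, with the ontology
factor defined here as

    factor(a) = clamp( (Σ w_equal + Σ w_partial) / (1 + n_partial), 0, 1 )

where *equal* terms have exactly the candidate's stem sequence and
*partial* terms are nested in or nest it. An exact ontology hit of
weight 1 alone therefore yields factor 1 (full +0.2 contribution),
while partial overlaps alone are damped by their count; this keeps the
factor commensurate with the [0,1] context factor. Ontology term
weights default to 1.0 and may encode hierarchy depth. Terms enter the
multi-word vector space when their extended NC-value is at or above the
corpus median (the at-or-above rule avoids dropping everything when
values tie).

## Vector spaces and benchmarking

Each document is represented over two spaces — single-word stems and
accepted multi-word terms — with weights tf · ln(N/df), then
Euclidean-normalized; vsm_m captures the semantics that the term
independence assumption of the plain VSM discards. The endorsed
resources matched to the query term are concatenated into one
benchmark pseudo-document, which passes through the same recognition
and vectorization.

Collection statistics (df, N) are computed over the analysis corpus
(candidates + benchmark) **plus the endorsed repository documents as a
background collection**. Without a background, a query that retrieves
only thematically uniform candidates drives df to N for every on-topic
term, so idf = 0 erases exactly the vocabulary the comparison needs;
the endorsed collection supplies a stable domain-level estimate of term
commonness. Vectors are still built only for the candidates and the
benchmark.

Candidates are scored by cosine against both benchmarks; a candidate
passes when the better of the two similarities reaches the threshold
(default **0.75**, configurable). Taking the max of the two spaces is a
documented choice — the source procedure does not say which space the
threshold applies to. Degenerate zero-norm vectors score 0.

## Fuzzy multi-criteria ranking

Criterion scores on the 1–10 scale, per passed candidate:

* **c1, c2** — min–max normalization of the multi- and single-word
  similarities over the passed pool (pool extrema map to 1 and 10; a
  single-candidate pool scores 10). The pool is per-query.
* **c3 (timeliness)** — clamp(1 + 9·(0.5·rank + 0.5·recency), 1, 10),
  where rank = 1 − (best_rank − 1)/(pool − 1) and recency =
  exp(−age_days/365) when a publication date exists, else 0.5. The
  half-life-style decay and the equal blend are this package's
  quantification of "search ranking coupled with publication date".
* **c4 (reliability)** — 10 × author-match strength against repository
  authors: 1.0 for a case-folded exact match, 0.8 for token Jaccard
  ≥ 0.8, else the candidate is *unknown* and scores 0 — deliberately
  below the scale so unknown-author resources sink and the expert
  intervenes.

Criterion weights are triangular fuzzy numbers in [0,1], elicited per
ontology term (YAML/JSON files keyed by term with a `_default`
fallback; a spread form (m−ρ, m, m+ρ) clamped to [0,1] is provided).
Multiple experts aggregate by component-wise geometric mean, which
requires strictly positive components. The fuzzy total is the
component-wise sum of the four score-scaled weight TFNs; reported
values are rounded to 2 decimals, full precision is kept internally.

Ranking uses the extent-analysis degree of possibility (formula in the
README). i outranks j iff e_ij = 1 and e_ji < Q, with Q = 0.9 by
default. Candidates are ordered by their number of decisive wins;
pairs the rule leaves undecided (both e = 1, or e_ji ≥ Q) fall back to
the larger modal value, then the identifier — a tie-break the source
procedure does not specify. With crisp (l = m = u) inputs the whole
scheme reduces to a plain descending sort, which the tests verify
against a numeric sort oracle. The full e-matrix is persisted for
expert inspection.

## Synthetic data

The generator emulates the evaluation setting of a curated portal:

* a repository of `n_topics` × `docs_per_topic` endorsed documents
  (defaults 20 × 10), each ~120 tokens sampled from a 50-pseudoword
  per-topic vocabulary with 2- and 3-token phrases planted exactly
  `phrase_occurrences` (3) times each, authors from a known pool, and
  dates in 2024–2026; the ontology holds each topic's phrase term plus
  single-word terms;
* a candidate corpus of 150 distractors plus enough planted-relevant
  documents for a 25% relevant fraction (50), distractors drawn from a
  disjoint token universe with decoy phrases; ground truth (topic,
  relevance, author known/unknown, date, pseudo search rank) goes to
  `labels.tsv`.

Phrase tokens are excluded from unigram sampling so planted phrase
frequencies — and hence C-values — are exact and hand-checkable.
Everything is driven by one integer seed and is byte-identical across
runs. Vocabulary disjointness guarantees near-zero cosine for
distractors; the `vocab_overlap` knob reintroduces shared vocabulary
for harder conditions.

What this does **not** emulate: natural-language syntax (so the
linguistic filter is barely exercised by fixtures — the real corpus
tests for it are hand-written), realistic author name variation, web
boilerplate beyond minimal wrappers, and the topical drift of real
search results. Passing the planted-relevance test therefore shows the
pipeline separates vocabulary-distinct content at realistic scale, not
that the 0.75 threshold is optimal for real web text.

## Problem sizes and numerics

The end-to-end property test runs 20 topics over a 200-document
endorsed repository and a 200-candidate corpus, scoring all 20 topic
benchmarks against the full corpus (~90k recognized candidate terms per
pass); termhood statistics match an independent brute-force oracle to
1e-9 on ≤5-document corpora. Cosines are clamped to [0,1] against
floating-point drift. Degenerate cases: membership functions with zero
slopes act as indicators; a zero denominator in the possibility formula
(only reachable when the modal comparison already decided) returns the
decided value; empty documents are warned about and excluded; an empty
normalization pool is an error rather than a silent default.

## Known limitations

* The linguistic filter is closed-class, not POS-based; noun-phrase
  precision on real text is accordingly lower than with a tagger.
* The web backend is an interface stub; only the local-corpus backend
  is implemented, so live-engine rank semantics are untested.
* Reliability matching is string-based; it does not resolve publisher
  aliases or organisational hierarchies.
* The usefulness quality criterion requires audience feedback and is
  intentionally not scored.
* Expert accept/reject feedback is not modelled beyond appending
  accepted candidates to the manifest.
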