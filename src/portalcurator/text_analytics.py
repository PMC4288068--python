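"""Text analytics: preprocessing, multi-word term recognition, VSM benchmarking.

This is the core of the discovery technique.  Documents are reduced to a
bag of words (stop-word removal, Porter stemming), multi-word terms are
recognized with the C-value / NC-value approach extended by a
domain-ontology factor, and every document is represented twice in a
vector space model — once over single-word stems and once over accepted
multi-word terms, since multi-word terms carry semantics that the
independence assumption of the plain VSM discards.  New documents are
scored by cosine similarity against a benchmark vector built from the
expert-endorsed resources matched to the same query term; candidates at
or above a similarity threshold (default 0.75 on the better of the two
spaces) are offered for expert review.

Termhood statistics
-------------------
For a candidate term ``a`` of length |a| tokens with corpus frequency
f(a), nested inside the set ``T_a`` of longer candidate terms:

* C-value(a) = log2|a| * f(a)                            if T_a is empty
* C-value(a) = log2|a| * (f(a) - (1/|T_a|) * sum f(b))   otherwise

* NC-value(a) = 0.8 * C-value(a) + 0.2 * sum_b f_a(b) * weight(b)
  where b ranges over context words of ``a`` and weight(b) is the share
  of top-ranked candidates that b co-occurs with.

* extended NC-value(a) = 0.6 * C-value + 0.2 * context + 0.2 * ontology
  where the ontology factor measures how strongly ``a`` appears in the
  domain ontology as an equal, nested, or nesting term — giving the
  context evidence and the domain evidence equal say.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources as _ilr

from . import stemmer
from .cm_model import OntologyTerm, RepositoryModel, resources_for_term

logger = logging.getLogger("portalcurator.text_analytics")

C_WEIGHT, CONTEXT_WEIGHT = 0.8, 0.2
EXT_C_WEIGHT, EXT_CONTEXT_WEIGHT, EXT_ONTOLOGY_WEIGHT = 0.6, 0.2, 0.2
SIMILARITY_THRESHOLD = 0.75
CONTEXT_WINDOW = 2
TOP_CANDIDATE_FRACTION = 0.2

#: prepositions tolerated inside a candidate term (noun prep noun pattern)
EMBEDDED_PREPOSITIONS = {"of", "for", "in", "on", "with", "to"}

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def load_stopwords() -> frozenset[str]:
    data = _ilr.files("portalcurator.data").joinpath("stopwords.txt")
    return frozenset(w for w in data.read_text(encoding="utf-8").split() if w)


@dataclass
class TokenizedDocument:
    identifier: str
    tokens: list[str]
    stems: list[str]
    kept_mask: list[bool]

    @property
    def kept_stems(self) -> list[str]:
        return [s for s, k in zip(self.stems, self.kept_mask) if k]


@dataclass
class CandidateTerm:
    """A recognized multi-word term candidate keyed by its stem sequence."""

    surface: tuple[str, ...]
    stems: tuple[str, ...]
    frequency: int
    nested_in: set[tuple[str, ...]] = field(default_factory=set)
    context_counts: Counter = field(default_factory=Counter)
    c_value: float = 0.0
    nc_value: float = 0.0
    extended_nc_value: float = 0.0
    ontology_factor: float = 0.0

    @property
    def length(self) -> int:
        return len(self.stems)

    @property
    def label(self) -> str:
        return " ".join(self.surface)


@dataclass
class TermVector:
    space: str  # "single" | "multi"
    weights: dict = field(default_factory=dict)

    @property
    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))


def preprocess(
    text: str, stopwords: frozenset[str] | None = None, identifier: str = ""
) -> TokenizedDocument:
    """Lowercase, strip punctuation, mask stop words, and stem.

    Emits an empty-document warning when nothing survives the stop list;
    such documents are excluded downstream.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    tokens = _TOKEN_RE.findall(text.lower())
    kept = [t not in stopwords for t in tokens]
    stems = [stemmer.stem(t) for t in tokens]
    doc = TokenizedDocument(identifier=identifier, tokens=tokens, stems=stems, kept_mask=kept)
    if tokens and not any(kept):
        logger.warning("document %r empty after stop-word removal", identifier)
    return doc


def _valid_candidate(tokens: list[str], kept: list[bool]) -> bool:
    """Linguistic filter: boundaries are content words; interior stop words
    are tolerated only as an embedded preposition between content words."""
    n = len(tokens)
    if not (kept[0] and kept[-1]):
        return False
    for i in range(1, n - 1):
        if not kept[i]:
            if tokens[i] not in EMBEDDED_PREPOSITIONS:
                return False
            if not (kept[i - 1] and kept[i + 1]):
                return False
    return True


def extract_candidates(
    corpus: list[TokenizedDocument], max_len: int = 5
) -> list[CandidateTerm]:
    """Recognize candidate multi-word terms (2..max_len tokens) in a corpus.

    Candidates are keyed by stem sequence so inflected variants collapse;
    the most frequent surface form is kept for display.  Frequencies
    count every occurrence, including occurrences nested inside longer
    candidates; the nesting relation ``T_a`` links each candidate to the
    longer recognized candidates that contain it.  Context words
    (non-stop tokens within a +/-2 token window of an occurrence) are
    accumulated for the NC-value context factor.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    freq: Counter = Counter()
    surfaces: dict[tuple[str, ...], Counter] = {}
    contexts: dict[tuple[str, ...], Counter] = {}
    for doc in corpus:
        n = len(doc.tokens)
        for length in range(2, max_len + 1):
            for start in range(0, n - length + 1):
                toks = doc.tokens[start : start + length]
                kept = doc.kept_mask[start : start + length]
                if not _valid_candidate(toks, kept):
                    continue
                key = tuple(doc.stems[start : start + length])
                freq[key] += 1
                surfaces.setdefault(key, Counter())[tuple(toks)] += 1
                ctx = contexts.setdefault(key, Counter())
                lo, hi = max(0, start - CONTEXT_WINDOW), min(n, start + length + CONTEXT_WINDOW)
                for j in list(range(lo, start)) + list(range(start + length, hi)):
                    if doc.kept_mask[j]:
                        ctx[doc.stems[j]] += 1
    candidates: dict[tuple[str, ...], CandidateTerm] = {}
    for key, f in freq.items():
        surface = surfaces[key].most_common(1)[0][0]
        candidates[key] = CandidateTerm(
            surface=surface, stems=key, frequency=f, context_counts=contexts[key]
        )
    # nesting: enumerate each candidate's contiguous sub-sequences and
    # link any that are themselves candidates (avoids a quadratic scan)
    for key in candidates:
        klen = len(key)
        for sub_len in range(2, klen):
            for i in range(klen - sub_len + 1):
                sub = key[i : i + sub_len]
                if sub in candidates:
                    candidates[sub].nested_in.add(key)
    return [candidates[k] for k in sorted(candidates)]


def c_value(term: CandidateTerm, by_stems: dict[tuple[str, ...], CandidateTerm]) -> float:
    """Termhood from length, frequency, and nested-occurrence discount."""
    if term.length < 2:
        raise ValueError("C-value is defined for multi-word terms only")
    base = math.log2(term.length)
    if not term.nested_in:
        return base * term.frequency
    nested_sum = sum(by_stems[b].frequency for b in term.nested_in)
    return base * (term.frequency - nested_sum / len(term.nested_in))


def compute_context_weights(
    candidates: list[CandidateTerm], top_fraction: float = TOP_CANDIDATE_FRACTION
) -> dict[str, float]:
    """weight(b) = share of top-ranked candidates that context word b
    co-occurs with; top-ranked = top ``top_fraction`` by C-value."""
    if not candidates:
        return {}
    ranked = sorted(candidates, key=lambda t: (-t.c_value, t.stems))
    n_top = max(1, math.ceil(top_fraction * len(ranked)))
    top = ranked[:n_top]
    counts: Counter = Counter()
    for t in top:
        for b in set(t.context_counts):
            counts[b] += 1
    return {b: c / n_top for b, c in counts.items()}


def nc_value(term: CandidateTerm, context_weights: dict[str, float]) -> float:
    """0.8 * C-value + 0.2 * sum of context-word frequencies times weights."""
    ctx = sum(f * context_weights.get(b, 0.0) for b, f in term.context_counts.items())
    return C_WEIGHT * term.c_value + CONTEXT_WEIGHT * ctx


def _stem_label(label: str) -> tuple[str, ...]:
    return tuple(stemmer.stem(t) for t in _TOKEN_RE.findall(label.lower()))


class _OntologyIndex:
    """Stemmed ontology terms indexed for O(1) overlap lookups.

    ``by_stems`` maps each term's full stem tuple to its ids;
    ``sub_index`` maps every proper contiguous sub-tuple (length >= 2)
    of a term's stems to the ids of the terms that contain it, so a
    candidate nested inside a longer ontology term is found with one
    dictionary probe.
    """

    def __init__(self, ontology: dict[str, OntologyTerm] | list[OntologyTerm]):
        terms = list(ontology.values() if isinstance(ontology, dict) else ontology)
        self.weights: list[float] = []
        self.by_stems: dict[tuple[str, ...], list[int]] = {}
        self.sub_index: dict[tuple[str, ...], list[int]] = {}
        for ot in terms:
            stems = _stem_label(ot.label)
            if not stems:
                continue
            tid = len(self.weights)
            self.weights.append(ot.weight)
            self.by_stems.setdefault(stems, []).append(tid)
            for sub_len in range(2, len(stems)):
                for i in range(len(stems) - sub_len + 1):
                    self.sub_index.setdefault(stems[i : i + sub_len], []).append(tid)

    def factor(self, cand: tuple[str, ...]) -> float:
        equal_ids = self.by_stems.get(cand, [])
        partial: set[int] = set()
        for k in range(1, len(cand)):  # ontology terms nested in the candidate
            for i in range(len(cand) - k + 1):
                partial.update(self.by_stems.get(cand[i : i + k], ()))
        partial.update(self.sub_index.get(cand, ()))  # candidate nested in a term
        partial.difference_update(equal_ids)
        equal_sum = sum(self.weights[i] for i in equal_ids)
        partial_sum = sum(self.weights[i] for i in partial)
        factor = (equal_sum + partial_sum) / (1 + len(partial))
        return min(max(factor, 0.0), 1.0)


def ontology_factor(term: CandidateTerm, ontology: dict[str, OntologyTerm] | list[OntologyTerm]) -> float:
    """Domain evidence in [0,1] for a candidate term.

    Ontology terms whose stemmed form exactly equals the candidate
    contribute their full weight; terms that are nested in or nest the
    candidate contribute with a damping that grows with the number of
    partial overlaps:

        factor = clamp( (sum w_equal + sum w_partial) / (1 + n_partial), 0, 1 )

    so an exact ontology hit of weight 1 alone yields factor 1, while
    partial overlaps alone are discounted.
    """
    return _OntologyIndex(ontology).factor(term.stems)


def nc_value_extended(
    term: CandidateTerm,
    context_weights: dict[str, float],
    ontology: dict[str, OntologyTerm] | list[OntologyTerm],
) -> float:
    """0.6 * C-value + 0.2 * context factor + 0.2 * ontology factor."""
    ctx = sum(f * context_weights.get(b, 0.0) for b, f in term.context_counts.items())
    onto = ontology_factor(term, ontology)
    term.ontology_factor = onto
    return EXT_C_WEIGHT * term.c_value + EXT_CONTEXT_WEIGHT * ctx + EXT_ONTOLOGY_WEIGHT * onto


def score_terms(
    candidates: list[CandidateTerm],
    ontology: dict[str, OntologyTerm] | list[OntologyTerm] | None = None,
) -> list[CandidateTerm]:
    """Populate c_value, nc_value, and extended_nc_value on every candidate."""
    by_stems = {t.stems: t for t in candidates}
    for t in candidates:
        t.c_value = c_value(t, by_stems)
    weights = compute_context_weights(candidates)
    index = _OntologyIndex(ontology) if ontology is not None else None
    for t in candidates:
        t.nc_value = nc_value(t, weights)
        if index is not None:
            ctx = sum(f * weights.get(b, 0.0) for b, f in t.context_counts.items())
            t.ontology_factor = index.factor(t.stems)
            t.extended_nc_value = (
                EXT_C_WEIGHT * t.c_value
                + EXT_CONTEXT_WEIGHT * ctx
                + EXT_ONTOLOGY_WEIGHT * t.ontology_factor
            )
        else:
            t.extended_nc_value = t.nc_value
    return candidates


def accept_terms(candidates: list[CandidateTerm]) -> list[CandidateTerm]:
    """Multi-word terms admitted to the multi VSM space: extended NC-value
    at or above the corpus median."""
    if not candidates:
        return []
    values = sorted(t.extended_nc_value for t in candidates)
    mid = len(values) // 2
    median = values[mid] if len(values) % 2 else 0.5 * (values[mid - 1] + values[mid])
    return [t for t in candidates if t.extended_nc_value >= median]


# ---------------------------------------------------------------------------
# Vector space model
# ---------------------------------------------------------------------------

@dataclass
class CorpusStats:
    """Collection-frequency statistics: N documents and per-term df."""

    n_docs: int
    df: dict = field(default_factory=dict)


def _count_multi_indexed(
    doc: TokenizedDocument, index: dict, lengths: list[int]
) -> Counter:
    # enumerate the document's own n-grams and look them up in the
    # accepted-term index, instead of scanning the document per term
    counts: Counter = Counter()
    stems = tuple(doc.stems)
    n = len(stems)
    for k in lengths:
        for i in range(n - k + 1):
            label = index.get(stems[i : i + k])
            if label is not None:
                counts[label] += 1
    return counts


def _count_multi(doc: TokenizedDocument, terms: list[CandidateTerm]) -> Counter:
    index = {t.stems: t.label for t in terms}
    lengths = sorted({t.length for t in terms})
    return _count_multi_indexed(doc, index, lengths)


def _doc_term_counts(
    doc: TokenizedDocument, accepted_terms: list[CandidateTerm], space: str
) -> Counter:
    if space == "single":
        return Counter(doc.kept_stems)
    if space == "multi":
        return _count_multi(doc, accepted_terms)
    raise ValueError(f"unknown space {space!r}")


def _df_from_counts(all_counts) -> dict:
    df: Counter = Counter()
    for counts in all_counts:
        for term in counts:
            df[term] += 1
    return dict(df)


def corpus_statistics(
    docs: list[TokenizedDocument], accepted_terms: list[CandidateTerm], space: str
) -> CorpusStats:
    return CorpusStats(
        n_docs=len(docs),
        df=_df_from_counts(_doc_term_counts(d, accepted_terms, space) for d in docs),
    )


def _vector_from_counts(
    counts: Counter, space: str, corpus_stats: CorpusStats, identifier: str
) -> TermVector:
    n = corpus_stats.n_docs
    weights = {}
    for term, tf in counts.items():
        df = corpus_stats.df.get(term, 0)
        if df <= 0:
            continue
        idf = math.log(n / df)
        if idf > 0:
            weights[term] = tf * idf
    norm = math.sqrt(sum(w * w for w in weights.values()))
    if norm == 0:
        logger.warning("document %r has a zero %s-space vector", identifier, space)
        return TermVector(space=space, weights={})
    return TermVector(space=space, weights={t: w / norm for t, w in weights.items()})


def build_vector(
    doc: TokenizedDocument,
    accepted_terms: list[CandidateTerm],
    space: str,
    corpus_stats: CorpusStats,
) -> TermVector:
    """tf * ln(N/df) weighting, length-normalized.

    The three classic weighting factors: term frequency within the
    document, collection frequency across the corpus (inverse, natural
    log), and Euclidean length normalization to remove long-document
    bias.  A document with no in-space mass yields a zero vector with a
    warning.
    """
    counts = _doc_term_counts(doc, accepted_terms, space)
    return _vector_from_counts(counts, space, corpus_stats, doc.identifier)


def benchmark_document(
    term: str, model: RepositoryModel, stopwords: frozenset[str] | None = None
) -> TokenizedDocument:
    """The endorsed resources matched to ``term``, converged into a single
    representative pseudo-document."""
    rids = resources_for_term(term, model)
    if not rids:
        raise ValueError(f"no endorsed resources for term {term!r}; cannot build benchmark")
    text = "\n".join(model.resources[r].text for r in sorted(rids))
    return preprocess(text, stopwords, identifier=f"benchmark:{term}")


def build_benchmark(
    term: str,
    model: RepositoryModel,
    space: str,
    accepted_terms: list[CandidateTerm],
    corpus_stats: CorpusStats,
    stopwords: frozenset[str] | None = None,
) -> TermVector:
    """VSM of the benchmark pseudo-document for ``term`` (vsm(R_q) / vsm_m(R_q))."""
    doc = benchmark_document(term, model, stopwords)
    return build_vector(doc, accepted_terms, space, corpus_stats)


def cosine_similarity(v1: TermVector, v2: TermVector) -> float:
    """cos angle between two non-negative term vectors, in [0,1]."""
    if v1.space != v2.space:
        raise ValueError(f"cannot compare spaces {v1.space!r} and {v2.space!r}")
    n1, n2 = v1.norm, v2.norm
    if n1 == 0 or n2 == 0:
        return 0.0
    small, large = (v1.weights, v2.weights) if len(v1.weights) <= len(v2.weights) else (
        v2.weights, v1.weights)
    dot = sum(w * large.get(t, 0.0) for t, w in small.items())
    return min(max(dot / (n1 * n2), 0.0), 1.0)


@dataclass
class ScoredCandidate:
    identifier: str
    sim_single: float
    sim_multi: float
    passed: bool


def score_candidates(
    candidate_ids: list[str],
    vectors_single: dict,
    vectors_multi: dict,
    benchmark_single: TermVector,
    benchmark_multi: TermVector,
    threshold: float = SIMILARITY_THRESHOLD,
) -> list[ScoredCandidate]:
    """Cosine of every candidate against both benchmarks.

    A candidate passes when the better of its two similarities reaches
    the threshold; both similarities are reported for ranking.
    """
    out = []
    for cid in candidate_ids:
        s1 = cosine_similarity(vectors_single[cid], benchmark_single)
        sm = cosine_similarity(vectors_multi[cid], benchmark_multi)
        out.append(
            ScoredCandidate(
                identifier=cid, sim_single=s1, sim_multi=sm,
                passed=max(s1, sm) >= threshold,
            )
        )
    return out


def similarity_histogram(
    scored: list[ScoredCandidate], lo: float = 0.75, hi: float = 1.0, width: float = 0.05
) -> dict[str, list[int]]:
    """Counts of candidate similarities in [lo, hi] bins, per space."""
    edges = []
    x = lo
    while x < hi - 1e-12:
        edges.append((x, min(x + width, hi)))
        x += width
    out = {"single": [0] * len(edges), "multi": [0] * len(edges)}
    for s in scored:
        for key, val in (("single", s.sim_single), ("multi", s.sim_multi)):
            for i, (a, b) in enumerate(edges):
                if a <= val < b or (i == len(edges) - 1 and val == b):
                    out[key][i] += 1
                    break
    return out


class RelevanceScorer:
    """End-to-end relevance measurement for one query term.

    Builds a joint analysis corpus from the candidate documents plus the
    benchmark pseudo-document (so both sides share term spaces and
    collection statistics), recognizes and scores multi-word terms with
    the ontology-extended NC-value, constructs single and multi VSMs,
    and scores every candidate against the benchmarks.

    The collection-frequency (idf) statistics additionally count the
    endorsed repository documents as a background collection.  Without a
    background, a query whose search returns only thematically uniform
    documents would drive the document frequency of every on-topic term
    to N and its idf to zero, erasing exactly the vocabulary the
    comparison depends on; the endorsed collection provides a stable,
    diverse estimate of how common each term is in the domain.
    ``background`` can be supplied explicitly (e.g. precomputed once
    when scoring many terms against one repository).
    """

    def __init__(
        self,
        model: RepositoryModel,
        term: str,
        stopwords: frozenset[str] | None = None,
        max_term_len: int = 5,
        threshold: float = SIMILARITY_THRESHOLD,
        background: list[TokenizedDocument] | None = None,
    ):
        self.model = model
        self.term = term
        self.stopwords = stopwords if stopwords is not None else load_stopwords()
        self.max_term_len = max_term_len
        self.threshold = threshold
        self.bench_doc = benchmark_document(term, model, self.stopwords)
        if background is None:
            background = [
                preprocess(r.text, self.stopwords, identifier=f"background:{rid}")
                for rid, r in sorted(model.resources.items())
            ]
        self.background = [d for d in background if d.kept_stems]

    def score(self, documents: list[tuple[str, str]]) -> tuple[list[ScoredCandidate], dict]:
        """``documents`` is a list of (identifier, plain text).

        Returns the scored candidates and an artifact dict with the
        recognized terms, vectors, and benchmarks for audit.
        """
        docs = [
            preprocess(text, self.stopwords, identifier=cid) for cid, text in documents
        ]
        docs = [d for d in docs if d.kept_stems]
        corpus = docs + [self.bench_doc]
        candidates = extract_candidates(corpus, self.max_term_len)
        score_terms(candidates, self.model.ontology)
        accepted = accept_terms(candidates)
        # one pass per document: term counts feed both the collection
        # statistics and the vectors, with a single shared term index
        index = {t.stems: t.label for t in accepted}
        lengths = sorted({t.length for t in accepted})
        counts_s = {d.identifier: Counter(d.kept_stems) for d in corpus}
        counts_m = {
            d.identifier: _count_multi_indexed(d, index, lengths) for d in corpus
        }
        # idf statistics over the analysis corpus plus the endorsed
        # background collection (df counted there too; vectors are not)
        bg_s = [Counter(d.kept_stems) for d in self.background]
        bg_m = [_count_multi_indexed(d, index, lengths) for d in self.background]
        n_total = len(corpus) + len(self.background)
        stats_s = CorpusStats(n_total, _df_from_counts(list(counts_s.values()) + bg_s))
        stats_m = CorpusStats(n_total, _df_from_counts(list(counts_m.values()) + bg_m))
        bid = self.bench_doc.identifier
        bench_s = _vector_from_counts(counts_s[bid], "single", stats_s, bid)
        bench_m = _vector_from_counts(counts_m[bid], "multi", stats_m, bid)
        vecs_s = {
            d.identifier: _vector_from_counts(
                counts_s[d.identifier], "single", stats_s, d.identifier
            )
            for d in docs
        }
        vecs_m = {
            d.identifier: _vector_from_counts(
                counts_m[d.identifier], "multi", stats_m, d.identifier
            )
            for d in docs
        }
        scored = score_candidates(
            [d.identifier for d in docs], vecs_s, vecs_m, bench_s, bench_m, self.threshold
        )
        artifacts = {
            "candidates": candidates,
            "accepted_terms": accepted,
            "vectors_single": vecs_s,
            "vectors_multi": vecs_m,
            "benchmark_single": bench_s,
            "benchmark_multi": bench_m,
        }
        return scored, artifacts
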