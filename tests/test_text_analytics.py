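"""Preprocessing, termhood statistics, vector spaces, and benchmarking.

The termhood checks compare the implementation against a brute-force
oracle written here from the documented rules with plain exhaustive
loops — no shared code with the scoring path beyond the tokenizer
output it consumes.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict

import pytest

from portalcurator.cm_model import OntologyTerm
from portalcurator import stemmer
from portalcurator.text_analytics import (
    CorpusStats,
    RelevanceScorer,
    TermVector,
    accept_terms,
    build_benchmark,
    build_vector,
    c_value,
    corpus_statistics,
    cosine_similarity,
    extract_candidates,
    load_stopwords,
    nc_value,
    nc_value_extended,
    ontology_factor,
    preprocess,
    score_candidates,
    score_terms,
)

STOPWORDS = load_stopwords()
PREPOSITIONS = {"of", "for", "in", "on", "with", "to"}


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_termhood(docs, ontology=None, max_len=5):
    """Exhaustive reimplementation of the termhood statistics.

    Enumerates every qualifying n-gram occurrence, computes C-value,
    context weights, NC-value, and the ontology-extended NC-value with
    nothing but literal loops over the documented formulas.
    """
    occurrences = defaultdict(list)  # stems -> [(doc index, start, length)]
    for di, d in enumerate(docs):
        for length in range(2, max_len + 1):
            for i in range(len(d.tokens) - length + 1):
                toks = d.tokens[i : i + length]
                kept = d.kept_mask[i : i + length]
                if not (kept[0] and kept[-1]):
                    continue
                ok = True
                for j in range(1, length - 1):
                    if not kept[j] and (
                        toks[j] not in PREPOSITIONS or not (kept[j - 1] and kept[j + 1])
                    ):
                        ok = False
                        break
                if ok:
                    occurrences[tuple(d.stems[i : i + length])].append((di, i, length))
    freq = {a: len(v) for a, v in occurrences.items()}

    cval = {}
    for a in freq:
        containing = [
            b
            for b in freq
            if len(b) > len(a)
            and any(b[i : i + len(a)] == a for i in range(len(b) - len(a) + 1))
        ]
        if containing:
            discount = sum(freq[b] for b in containing) / len(containing)
            cval[a] = math.log2(len(a)) * (freq[a] - discount)
        else:
            cval[a] = math.log2(len(a)) * freq[a]

    context = {a: Counter() for a in freq}
    for a, positions in occurrences.items():
        for di, i, length in positions:
            d = docs[di]
            window = list(range(max(0, i - 2), i)) + list(
                range(i + length, min(len(d.tokens), i + length + 2))
            )
            for j in window:
                if d.kept_mask[j]:
                    context[a][d.stems[j]] += 1

    ranked = sorted(freq, key=lambda a: (-cval[a], a))
    n_top = max(1, math.ceil(0.2 * len(ranked)))
    top = ranked[:n_top]
    cw = Counter()
    for a in top:
        for b in set(context[a]):
            cw[b] += 1
    context_weights = {b: c / n_top for b, c in cw.items()}

    ncval = {
        a: 0.8 * cval[a]
        + 0.2 * sum(f * context_weights.get(b, 0.0) for b, f in context[a].items())
        for a in freq
    }

    extended = {}
    onto_factor = {}
    if ontology is not None:
        stemmed = [
            (tuple(stemmer.stem(t) for t in ot.label.lower().split()), ot.weight)
            for ot in ontology
        ]
        for a in freq:
            equal_sum, partial_sum, n_partial = 0.0, 0.0, 0
            for os_, w in stemmed:
                if os_ == a:
                    equal_sum += w
                elif len(os_) < len(a) and any(
                    a[i : i + len(os_)] == os_ for i in range(len(a) - len(os_) + 1)
                ):
                    partial_sum += w
                    n_partial += 1
                elif len(os_) > len(a) and any(
                    os_[i : i + len(a)] == a for i in range(len(os_) - len(a) + 1)
                ):
                    partial_sum += w
                    n_partial += 1
            factor = min(max((equal_sum + partial_sum) / (1 + n_partial), 0.0), 1.0)
            onto_factor[a] = factor
            ctx = sum(f * context_weights.get(b, 0.0) for b, f in context[a].items())
            extended[a] = 0.6 * cval[a] + 0.2 * ctx + 0.2 * factor
    return freq, cval, ncval, extended, onto_factor


TOY_TEXTS = [
    "sentinel node biopsy guides sentinel node staging decisions",
    "sentinel node biopsy results inform adjuvant therapy choice",
    "adjuvant therapy reduces recurrence risk after surgery",
    "node biopsy procedure explained for sentinel node biopsy patients",
    "therapy choice depends on staging and recurrence risk",
]


@pytest.fixture
def toy_corpus():
    return [preprocess(t, STOPWORDS, identifier=f"d{i}") for i, t in enumerate(TOY_TEXTS)]


class TestPreprocess:
    def test_stop_words_masked_and_stems_kept(self):
        doc = preprocess("The care of the patient", STOPWORDS)
        assert set(doc.kept_stems) == {"care", "patient"}

    def test_inflected_forms_collapse_to_one_stem(self):
        doc = preprocess("caring cared cares", STOPWORDS)
        assert set(doc.stems) == {"care"}

    def test_parallel_arrays_same_length(self):
        doc = preprocess("Palliative care, explained simply!", STOPWORDS)
        assert len(doc.tokens) == len(doc.stems) == len(doc.kept_mask)

    def test_all_stop_words_warns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            doc = preprocess("the of and", STOPWORDS, identifier="empty-doc")
        assert doc.kept_stems == []
        assert any("empty" in r.message for r in caplog.records)


class TestStemmer:
    @pytest.mark.parametrize(
        "word,expected",
        [
            ("caresses", "caress"), ("ponies", "poni"), ("cats", "cat"),
            ("agreed", "agre"), ("plastered", "plaster"), ("motoring", "motor"),
            ("hopping", "hop"), ("falling", "fall"), ("filing", "file"),
            ("happy", "happi"), ("relational", "relat"), ("rational", "ration"),
            ("adjustable", "adjust"), ("effective", "effect"),
        ],
    )
    def test_classic_vocabulary(self, word, expected):
        assert stemmer.stem(word) == expected


class TestCandidateExtraction:
    def test_nested_term_counted_with_its_own_frequency(self):
        text = " ".join(["palliative care team meets daily"] * 3)
        corpus = [preprocess(text, STOPWORDS, "d0")]
        cands = {c.label: c for c in extract_candidates(corpus)}
        assert cands["palliative care team"].frequency == 3
        assert cands["palliative care"].frequency == 3
        assert any(
            len(b) == 3 for b in cands["palliative care"].nested_in
        )

    def test_stop_word_only_corpus_yields_nothing(self):
        corpus = [preprocess("the of and to in", STOPWORDS, "d0")]
        assert extract_candidates(corpus) == []

    def test_boundary_stop_words_excluded_preposition_allowed_inside(self):
        corpus = [preprocess("quality of life matters", STOPWORDS, "d0")]
        labels = {c.label for c in extract_candidates(corpus)}
        assert "quality of life" in labels
        assert not any(lbl.startswith("of ") or lbl.endswith(" of") for lbl in labels)

    def test_recognizes_phrases_from_an_endorsed_style_resource(self, toy_model):
        """Multi-word terms of the kind a specialist resource contains
        ('palliative care team', 'palliative care specialist') are found."""
        corpus = [
            preprocess(r.text, STOPWORDS, r.identifier)
            for r in toy_model.resources.values()
        ]
        labels = {c.label for c in extract_candidates(corpus)}
        assert "palliative care team" in labels
        assert "palliative care specialist" in labels
        assert "palliative care" in labels


class TestCValue:
    def test_non_nested_closed_forms(self):
        corpus = [preprocess("alpha beta", STOPWORDS, "d0")]
        c = extract_candidates(corpus)[0]
        by = {c.stems: c}
        assert c_value(c, by) == pytest.approx(1.0)  # log2(2) * 1

        text = " ".join(["one two three four"] * 5)
        corpus = [preprocess(text, STOPWORDS, "d0")]
        cands = {c.label: c for c in extract_candidates(corpus, max_len=4)}
        by = {c.stems: c for c in cands.values()}
        quad = cands["one two three four"]
        # the 4-gram spans repeats too: frequency counts every occurrence
        assert c_value(quad, by) == pytest.approx(math.log2(4) * quad.frequency)

    def test_single_word_rejected(self):
        from portalcurator.text_analytics import CandidateTerm

        t = CandidateTerm(surface=("one",), stems=("one",), frequency=1)
        with pytest.raises(ValueError):
            c_value(t, {t.stems: t})

    def test_matches_brute_force_on_toy_corpus(self, toy_corpus):
        cands = score_terms(extract_candidates(toy_corpus))
        _freq, cval, _nc, _ext, _of = brute_force_termhood(toy_corpus)
        assert set(cval) == {c.stems for c in cands}
        for c in cands:
            assert c.c_value == pytest.approx(cval[c.stems], abs=1e-9)

    def test_adding_containing_occurrence_never_raises_nested_c_value(self):
        """Monotonicity: an extra occurrence of a containing term cannot
        increase the nested term's C-value."""
        base = ["sentinel node biopsy is standard", "sentinel node imaging works"]
        more = base + ["sentinel node biopsy repeated"]

        def cv(texts, label):
            corpus = [preprocess(t, STOPWORDS, str(i)) for i, t in enumerate(texts)]
            cands = {c.label: c for c in score_terms(extract_candidates(corpus))}
            return cands[label]

        before, after = cv(base, "sentinel node"), cv(more, "sentinel node")
        # frequency gain is exactly cancelled or exceeded by the discount
        gain = after.c_value - before.c_value
        freq_gain = math.log2(2) * (after.frequency - before.frequency)
        assert gain <= freq_gain + 1e-9


class TestNCValue:
    def test_empty_context_is_pure_c_value_share(self):
        corpus = [preprocess("alpha beta", STOPWORDS, "d0")]
        cands = score_terms(extract_candidates(corpus))
        c = cands[0]
        assert nc_value(c, {}) == pytest.approx(0.8 * c.c_value)

    def test_context_contribution_is_linear_in_weights(self, toy_corpus):
        cands = score_terms(extract_candidates(toy_corpus))
        c = max(cands, key=lambda t: sum(t.context_counts.values()))
        w1 = {b: 0.25 for b in c.context_counts}
        w2 = {b: 0.50 for b in c.context_counts}
        base = 0.8 * c.c_value
        assert nc_value(c, w2) - base == pytest.approx(2 * (nc_value(c, w1) - base))

    def test_matches_brute_force_on_toy_corpus(self, toy_corpus):
        cands = score_terms(extract_candidates(toy_corpus))
        _freq, _cval, ncval, _ext, _of = brute_force_termhood(toy_corpus)
        for c in cands:
            assert c.nc_value == pytest.approx(ncval[c.stems], abs=1e-9)


class TestExtendedNCValue:
    ONTOLOGY = [
        OntologyTerm("sentinel node biopsy"),
        OntologyTerm("adjuvant therapy"),
        OntologyTerm("staging"),
    ]

    def test_no_ontology_overlap_reduces_to_c_plus_context(self, toy_corpus):
        cands = score_terms(extract_candidates(toy_corpus), [OntologyTerm("unrelated term")])
        for c in cands:
            ctx_part = c.extended_nc_value - 0.6 * c.c_value
            nc_ctx_part = c.nc_value - 0.8 * c.c_value
            assert ctx_part == pytest.approx(nc_ctx_part, abs=1e-9)
            assert c.ontology_factor == 0.0

    def test_exact_ontology_match_contributes_full_weight(self):
        corpus = [preprocess("adjuvant therapy helps", STOPWORDS, "d0")]
        cands = {c.label: c for c in score_terms(extract_candidates(corpus), self.ONTOLOGY)}
        c = cands["adjuvant therapy"]
        assert c.ontology_factor == pytest.approx(1.0)

    def test_matches_brute_force_with_ontology(self, toy_corpus):
        cands = score_terms(extract_candidates(toy_corpus), self.ONTOLOGY)
        _f, _c, _n, extended, onto = brute_force_termhood(toy_corpus, self.ONTOLOGY)
        for c in cands:
            assert c.ontology_factor == pytest.approx(onto[c.stems], abs=1e-9)
            assert c.extended_nc_value == pytest.approx(extended[c.stems], abs=1e-9)

    def test_partial_overlap_equals_exhaustive_rule(self):
        """'palliative care team' against an ontology holding 'palliative
        care' (weight 1): one partial overlap, damped to 1/2."""
        corpus = [preprocess("palliative care team helps", STOPWORDS, "d0")]
        cands = {c.label: c for c in extract_candidates(corpus)}
        f = ontology_factor(cands["palliative care team"], [OntologyTerm("palliative care")])
        assert f == pytest.approx(0.5)


class TestVectors:
    def test_unique_term_single_doc_corpus_gives_zero_vector(self, caplog):
        doc = preprocess("solitary token here", STOPWORDS, "only")
        stats = corpus_statistics([doc], [], "single")
        with caplog.at_level("WARNING"):
            v = build_vector(doc, [], "single", stats)
        assert v.weights == {} and v.norm == 0.0

    def test_vectors_are_unit_norm(self, toy_corpus):
        stats = corpus_statistics(toy_corpus, [], "single")
        for doc in toy_corpus:
            v = build_vector(doc, [], "single", stats)
            if v.weights:
                assert v.norm == pytest.approx(1.0)

    def test_weights_equal_spreadsheet_tf_idf_on_four_doc_corpus(self):
        texts = [
            "apple banana apple",
            "banana cherry",
            "apple cherry cherry date",
            "date banana",
        ]
        docs = [preprocess(t, STOPWORDS, f"d{i}") for i, t in enumerate(texts)]
        stats = corpus_statistics(docs, [], "single")
        v0 = build_vector(docs[0], [], "single", stats)
        # hand arithmetic: N=4; df(apple)=2, df(banana)=3
        w_apple = 2 * math.log(4 / 2)
        w_banana = 1 * math.log(4 / 3)
        norm = math.hypot(w_apple, w_banana)
        assert v0.weights["appl"] == pytest.approx(w_apple / norm)
        assert v0.weights["banana"] == pytest.approx(w_banana / norm)

    def test_benchmark_of_single_resource_equals_its_own_vector(self, toy_model):
        doc2 = preprocess(toy_model.resources["r2"].text, STOPWORDS, "r2")
        context = [preprocess("unrelated filler words about gardening", STOPWORDS, "x")]
        stats = corpus_statistics(context + [doc2], [], "single")
        bench = build_benchmark("reviews", toy_model, "single", [], stats)
        own = build_vector(doc2, [], "single", stats)
        assert bench.weights == pytest.approx(own.weights)

    def test_benchmark_support_is_union_of_disjoint_resources(self, toy_model):
        docs = [
            preprocess(toy_model.resources[r].text, STOPWORDS, r) for r in ("r1", "r3")
        ]
        filler = [preprocess("totally different filler content", STOPWORDS, "x")]
        stats = corpus_statistics(filler + docs, [], "single")
        bench = build_benchmark("palliative care", toy_model, "single", [], stats)
        supports = set()
        for d in docs:
            supports |= set(build_vector(d, [], "single", stats).weights)
        assert set(bench.weights) <= supports

    def test_benchmark_scale_invariant_to_duplicated_text(self, toy_model):
        """k concatenated copies of one document normalize to the same
        vector as a single copy."""
        from portalcurator.cm_model import ContentMatrix, RepositoryModel, Resource

        text = toy_model.resources["r2"].text
        for k in (1, 3):
            res = Resource("dup", "dup", text * k, linked_terms={"reviews"})
            matrix = ContentMatrix()
            matrix.add("reviews", "dup")
            model = RepositoryModel(
                resources={"dup": res},
                ontology=toy_model.ontology,
                audience=[],
                matrix=matrix,
            )
            doc = preprocess(text * k, STOPWORDS, "dup")
            filler = [preprocess("filler words entirely elsewhere", STOPWORDS, "x")]
            stats = corpus_statistics(filler + [doc], [], "single")
            vec = build_benchmark("reviews", model, "single", [], stats)
            if k == 1:
                reference = vec
        assert vec.weights == pytest.approx(reference.weights)


class TestCosine:
    def test_identical_vectors(self):
        v = TermVector("single", {"a": 0.6, "b": 0.8})
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity(
            TermVector("single", {"a": 1.0}), TermVector("single", {"b": 1.0})
        ) == pytest.approx(0.0)

    def test_closed_form_overlap(self):
        v1 = TermVector("single", {"a": 1.0, "b": 1.0})
        v2 = TermVector("single", {"a": 1.0})
        assert cosine_similarity(v1, v2) == pytest.approx(1 / math.sqrt(2))

    def test_zero_vector_yields_zero(self):
        assert cosine_similarity(
            TermVector("single", {}), TermVector("single", {"a": 1.0})
        ) == 0.0

    def test_mismatched_spaces_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(TermVector("single", {"a": 1}), TermVector("multi", {"a": 1}))

    def test_symmetric_bounded_scale_invariant_on_random_vectors(self):
        import random

        rng = random.Random(13)
        for _ in range(50):
            v1 = TermVector("single", {f"t{i}": rng.random() for i in rng.sample(range(20), 6)})
            v2 = TermVector("single", {f"t{i}": rng.random() for i in rng.sample(range(20), 6)})
            s12 = cosine_similarity(v1, v2)
            assert 0.0 <= s12 <= 1.0
            assert s12 == pytest.approx(cosine_similarity(v2, v1))
            k = 0.1 + 5 * rng.random()
            scaled = TermVector("single", {t: k * w for t, w in v1.weights.items()})
            assert cosine_similarity(scaled, v2) == pytest.approx(s12)


class TestScoring:
    def test_candidate_identical_to_benchmark_passes_at_one(self, toy_model):
        bench_text = " ".join(
            toy_model.resources[r].text for r in ("r1", "r3")
        )
        scorer = RelevanceScorer(toy_model, "palliative care", STOPWORDS)
        scored, _ = scorer.score(
            [("same", bench_text), ("other", "gardening soil compost advice tips mulch")]
        )
        by = {s.identifier: s for s in scored}
        assert by["same"].sim_single == pytest.approx(1.0)
        assert by["same"].passed
        assert max(by["other"].sim_single, by["other"].sim_multi) < 0.25
        assert not by["other"].passed

    def test_constructed_pool_passes_exactly_the_planted_subset(self, toy_model):
        """With 5 near-benchmark candidates and 15 distractors, exactly
        the 5 pass the 0.75 threshold (construction oracle)."""
        import random

        rng = random.Random(3)
        bench_words = []
        for r in ("r1", "r3"):
            bench_words += toy_model.resources[r].text.lower().replace(".", "").split()
        distract_vocab = [f"zz{i}" for i in range(30)]
        documents = []
        for i in range(5):
            words = [rng.choice(bench_words) for _ in range(80)]
            documents.append((f"rel{i}", " ".join(words)))
        for i in range(15):
            words = [rng.choice(distract_vocab) for _ in range(80)]
            documents.append((f"dis{i}", " ".join(words)))
        scorer = RelevanceScorer(toy_model, "palliative care", STOPWORDS)
        scored, _ = scorer.score(documents)
        passed = {s.identifier for s in scored if s.passed}
        assert passed == {f"rel{i}" for i in range(5)}

    def test_accept_terms_median_rule(self):
        from portalcurator.text_analytics import CandidateTerm

        cands = []
        for i, v in enumerate([1.0, 2.0, 3.0, 4.0]):
            t = CandidateTerm(surface=(f"w{i}", "x"), stems=(f"w{i}", "x"), frequency=1)
            t.extended_nc_value = v
            cands.append(t)
        kept = {t.extended_nc_value for t in accept_terms(cands)}
        assert kept == {3.0, 4.0}  # median 2.5, at-or-above rule
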