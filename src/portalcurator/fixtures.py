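"""Synthetic repositories, candidate corpora, and the worked ranking example.

Everything the pipeline consumes can be generated here offline and
seed-deterministically: an endorsed repository of topic-tagged documents
with planted multi-word phrases, known authors and publication dates;
and a candidate corpus mixing planted-relevant documents (which share a
topic's vocabulary and phrases) with distractors drawn from a disjoint
token universe, together with ground-truth labels.

Document text is sampled from per-topic unigram distributions with the
planted phrases inserted at fixed intervals, so phrase frequencies —
and hence C-values — are controllable and hand-checkable.  Topic
vocabularies are mutually disjoint pseudoword sets, which guarantees
near-zero cosine between a distractor and any benchmark; vocabulary
overlap between topics can be reintroduced via ``vocab_overlap`` for
harder test conditions.
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field
from pathlib import Path

from .cm_model import (
    AudienceAttribute,
    ContentMatrix,
    OntologyTerm,
    RepositoryModel,
    Resource,
    save_repository,
)
from .fuzzy_ranking import TFN

_SYLLABLES = [
    "ba", "be", "bi", "bo", "bu", "da", "de", "di", "do", "du",
    "fa", "fe", "fi", "fo", "fu", "ga", "ge", "gi", "go", "gu",
    "ka", "ke", "ki", "ko", "ku", "la", "le", "li", "lo", "lu",
    "ma", "me", "mi", "mo", "mu", "na", "ne", "ni", "no", "nu",
    "pa", "pe", "pi", "po", "pu", "ra", "re", "ri", "ro", "ru",
    "sa", "se", "si", "so", "su", "ta", "te", "ti", "to", "tu",
    "va", "ve", "vi", "vo", "vu", "za", "ze", "zi", "zo", "zu",
]

DEFAULT_AUTHOR_POOL = [
    "Cancer Council Australia",
    "National Breast Cancer Centre",
    "Mayo Clinic Staff",
    "J Smith",
    "A Nguyen",
    "Peter MacCallum Institute",
]

DEFAULT_AUDIENCE = [
    AudienceAttribute("level of knowledge", ("basic", "scientific", "experiences")),
    AudienceAttribute("age group", ("young", "middle-aged", "old")),
    AudienceAttribute("stage of illness", ("early", "recurrent", "advanced")),
    AudienceAttribute("user role", ("friend", "partner", "child")),
]


@dataclass
class CorpusSpec:
    """Study conditions for one synthetic repository / candidate corpus."""

    n_topics: int = 20
    terms_per_topic: int = 2
    docs_per_topic: int = 10
    n_distractors: int = 150
    planted_multiword_terms: dict[int, list[str]] = field(default_factory=dict)
    author_pool: list[str] = field(default_factory=lambda: list(DEFAULT_AUTHOR_POOL))
    date_range: tuple[str, str] = ("2024-01-01", "2026-01-01")
    seed: int = 0
    vocab_size: int = 50
    doc_length: int = 120
    phrase_occurrences: int = 3
    vocab_overlap: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_topics", "terms_per_topic", "docs_per_topic", "n_distractors"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _make_words(rng: random.Random, n: int, used: set[str]) -> list[str]:
    """n distinct pseudowords not already in ``used``."""
    out: list[str] = []
    while len(out) < n:
        word = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(3, 4)))
        if word not in used:
            used.add(word)
            out.append(word)
    return out


def _topic_vocabularies(spec: CorpusSpec, rng: random.Random) -> tuple[list[list[str]], list[str]]:
    """Per-topic vocabularies (optionally overlapping) plus the disjoint
    distractor universe."""
    used: set[str] = set()
    vocabs = [_make_words(rng, spec.vocab_size, used) for _ in range(spec.n_topics)]
    if spec.vocab_overlap > 0 and spec.n_topics > 1:
        n_shared = int(spec.vocab_overlap * spec.vocab_size)
        shared = _make_words(rng, n_shared, used)
        for vocab in vocabs:
            vocab[:n_shared] = shared
    distractor_vocab = _make_words(rng, max(spec.vocab_size * 2, 1), used)
    return vocabs, distractor_vocab


def _topic_phrases(spec: CorpusSpec, vocabs: list[list[str]]) -> dict[int, list[str]]:
    """Planted multi-word phrases per topic: from the spec when given,
    else one 2-gram and one 3-gram built from the topic vocabulary."""
    phrases: dict[int, list[str]] = {}
    for k, vocab in enumerate(vocabs):
        if spec.planted_multiword_terms.get(k):
            phrases[k] = list(spec.planted_multiword_terms[k])
        else:
            phrases[k] = [f"{vocab[0]} {vocab[1]}", f"{vocab[0]} {vocab[1]} {vocab[2]}"]
    return phrases


def _make_text(
    rng: random.Random, vocab: list[str], phrases: list[str], length: int, occurrences: int
) -> str:
    """Unigram-sampled text with each phrase inserted ``occurrences`` times
    at evenly spaced positions.

    Phrase tokens are excluded from the unigram sampling so planted
    phrase frequencies are exact, which keeps C-values hand-checkable.
    """
    phrase_tokens = {t for p in phrases for t in p.split()}
    sample_vocab = [w for w in vocab if w not in phrase_tokens] or list(vocab)
    tokens = [rng.choice(sample_vocab) for _ in range(length)]
    inserts: list[list[str]] = []
    for phrase in phrases:
        inserts.extend([phrase.split()] * occurrences)
    if inserts:
        step = max(len(tokens) // len(inserts), 1)
        out: list[str] = []
        idx = 0
        for i, tok in enumerate(tokens):
            if i % step == 0 and idx < len(inserts):
                out.extend(inserts[idx])
                idx += 1
            out.append(tok)
        while idx < len(inserts):
            out.extend(inserts[idx])
            idx += 1
        tokens = out
    # sentence-ish lines for readability of the plain-text fixture
    lines = [" ".join(tokens[i : i + 12]) for i in range(0, len(tokens), 12)]
    return ".\n".join(lines) + ".\n"


def _random_date(rng: random.Random, date_range: tuple[str, str]) -> _dt.date:
    start = _dt.date.fromisoformat(date_range[0])
    end = _dt.date.fromisoformat(date_range[1])
    return start + _dt.timedelta(days=rng.randint(0, max((end - start).days, 0)))


def _unknown_author(rng: random.Random) -> str:
    return f"{rng.choice('abcdefghij').upper()} {''.join(rng.choice(_SYLLABLES) for _ in range(3)).title()}"


def build_repository_model(spec: CorpusSpec) -> RepositoryModel:
    """The in-memory repository for ``spec`` (see :func:`generate_repository`)."""
    rng = random.Random(spec.seed)
    vocabs, _ = _topic_vocabularies(spec, rng)
    phrases = _topic_phrases(spec, vocabs)
    ontology: dict[str, OntologyTerm] = {}
    topic_terms: dict[int, list[str]] = {}
    for k, vocab in enumerate(vocabs):
        labels = [phrases[k][0]]
        labels += vocab[3 : 3 + max(spec.terms_per_topic - 1, 0)]
        topic_terms[k] = labels
        for label in labels:
            ontology[label] = OntologyTerm(label=label, weight=1.0)
    resources: dict[str, Resource] = {}
    matrix = ContentMatrix()
    for k in range(spec.n_topics):
        for j in range(spec.docs_per_topic):
            rid = f"repo-t{k:03d}-d{j:03d}"
            text = _make_text(
                rng, vocabs[k], phrases[k], spec.doc_length, spec.phrase_occurrences
            )
            linked = set(topic_terms[k][: 1 + (j % max(spec.terms_per_topic, 1))])
            resources[rid] = Resource(
                identifier=rid,
                title=f"Endorsed resource {rid}",
                text=text,
                authors=[rng.choice(spec.author_pool)] if spec.author_pool else [],
                publication_date=_random_date(rng, spec.date_range),
                linked_terms=linked,
            )
            for term in linked:
                matrix.add(term, rid)
    model = RepositoryModel(
        resources=resources, ontology=ontology, audience=list(DEFAULT_AUDIENCE), matrix=matrix
    )
    model.validate()
    return model


def generate_repository(spec: CorpusSpec, out_dir: str | Path) -> RepositoryModel:
    """Write the synthetic endorsed repository to ``out_dir`` and return it.

    The output (manifest + text bodies) is byte-identical across runs
    with the same spec.
    """
    model = build_repository_model(spec)
    save_repository(model, out_dir)
    return model


@dataclass(frozen=True)
class CandidateLabel:
    doc_id: str
    topic: int  # -1 for distractors
    relevant: bool
    author_known: bool
    author: str
    date: _dt.date
    pseudo_rank: int


def generate_candidates(
    spec: CorpusSpec, out_dir: str | Path, relevant_fraction: float = 0.25
) -> list[CandidateLabel]:
    """Write a candidate corpus (one .txt per document) plus ground truth.

    The corpus holds ``spec.n_distractors`` distractor documents and
    enough planted-relevant documents (spread round-robin over topics)
    to make up ``relevant_fraction`` of the total.  Relevant documents
    reuse their topic's vocabulary and planted phrases; distractors draw
    from the disjoint distractor universe with their own decoy phrases.
    Ground truth goes to ``labels.tsv`` in the same directory.
    """
    if not (0.0 <= relevant_fraction <= 1.0):
        raise ValueError("relevant_fraction must lie in [0, 1]")
    rng = random.Random(spec.seed + 1)
    vocab_rng = random.Random(spec.seed)
    vocabs, distractor_vocab = _topic_vocabularies(spec, vocab_rng)
    phrases = _topic_phrases(spec, vocabs)
    decoy_phrases = [
        f"{distractor_vocab[0]} {distractor_vocab[1]}",
        f"{distractor_vocab[2]} {distractor_vocab[3]} {distractor_vocab[4]}",
    ]
    if relevant_fraction >= 1.0:
        n_relevant, n_distractors = spec.n_distractors, 0
    else:
        n_distractors = spec.n_distractors
        n_relevant = round(n_distractors * relevant_fraction / (1.0 - relevant_fraction))
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    labels: list[CandidateLabel] = []
    entries: list[tuple[str, str, int, bool]] = []  # id, text, topic, relevant
    for i in range(n_relevant):
        k = i % max(spec.n_topics, 1)
        text = _make_text(rng, vocabs[k], phrases[k], spec.doc_length, spec.phrase_occurrences)
        entries.append((f"cand-rel-{i:04d}", text, k, True))
    for i in range(n_distractors):
        lo = rng.randrange(0, max(len(distractor_vocab) - spec.vocab_size, 1))
        sub_vocab = distractor_vocab[lo : lo + spec.vocab_size]
        text = _make_text(rng, sub_vocab, decoy_phrases, spec.doc_length, 1)
        entries.append((f"cand-dis-{i:04d}", text, -1, False))
    ranks = list(range(1, len(entries) + 1))
    rng.shuffle(ranks)
    for (doc_id, text, topic, relevant), rank_ in zip(entries, ranks):
        known = rng.random() < 0.5
        author = rng.choice(spec.author_pool) if (known and spec.author_pool) else _unknown_author(rng)
        date = _random_date(rng, spec.date_range)
        (root / f"{doc_id}.txt").write_text(text, encoding="utf-8")
        labels.append(
            CandidateLabel(
                doc_id=doc_id, topic=topic, relevant=relevant,
                author_known=known and bool(spec.author_pool),
                author=author, date=date, pseudo_rank=rank_,
            )
        )
    with open(root / "labels.tsv", "w", encoding="utf-8") as fh:
        fh.write("doc_id\ttopic\trelevant\tauthor_known\tauthor\tdate\tpseudo_rank\n")
        for lab in labels:
            fh.write(
                f"{lab.doc_id}\t{lab.topic}\t{int(lab.relevant)}\t{int(lab.author_known)}"
                f"\t{lab.author}\t{lab.date.isoformat()}\t{lab.pseudo_rank}\n"
            )
    return labels


def load_labels(path: str | Path) -> list[CandidateLabel]:
    labels = []
    with open(Path(path), encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            doc_id, topic, rel, known, author, date, rank_ = line.rstrip("\n").split("\t")
            labels.append(
                CandidateLabel(
                    doc_id=doc_id, topic=int(topic), relevant=bool(int(rel)),
                    author_known=bool(int(known)), author=author,
                    date=_dt.date.fromisoformat(date), pseudo_rank=int(rank_),
                )
            )
    return labels


def worked_example() -> dict:
    """The hand-checkable demonstration of the fuzzy ranking arithmetic.

    Three candidate resources found for the ontology term "reviews",
    with criterion scores already normalized to the 1-10 scale, the
    elicited criterion-weight TFNs for the terms "palliative care" and
    "reviews", the synonym dictionary used to expand the palliative-care
    query, and the reference outputs of every ranking step (weighted
    cells, fuzzy totals, pairwise comparison scores, final order) for
    verification.
    """
    weights = {
        "palliative care": {
            "c1": TFN(0.50, 0.70, 0.90),
            "c2": TFN(0.30, 0.50, 0.70),
            "c3": TFN(0.40, 0.60, 0.70),
            "c4": TFN(0.40, 0.50, 0.60),
        },
        "reviews": {
            "c1": TFN(0.60, 0.70, 0.90),
            "c2": TFN(0.60, 0.70, 0.90),
            "c3": TFN(0.10, 0.30, 0.40),
            "c4": TFN(0.40, 0.60, 0.90),
        },
    }
    scores = {
        "R1": (7.50, 5.50, 4.10, 6.90),
        "R2": (5.40, 9.20, 8.70, 0.0),
        "R3": (8.50, 4.70, 6.80, 7.20),
    }
    synonyms = {
        "palliative": {
            "direct": ["alleviative", "preventative", "lenitive"],
            "inherited": ["curative", "remedial", "therapeutic"],
        },
        "care": {
            "direct": ["aid", "attention", "tending"],
            "inherited": ["work", "action", "procedure"],
        },
    }
    expected = {
        "weighted_cells": {
            "R1": [(4.50, 5.25, 6.75), (3.30, 3.85, 4.95), (0.41, 1.23, 1.64), (2.76, 4.14, 6.21)],
            "R2": [(3.24, 3.78, 4.86), (5.52, 6.44, 8.28), (0.87, 2.61, 3.48), (0.0, 0.0, 0.0)],
            "R3": [(5.10, 5.95, 7.65), (2.82, 3.29, 4.23), (0.68, 2.04, 2.72), (2.88, 4.32, 6.48)],
        },
        "weighted_sums": {
            "R1": (10.97, 14.47, 19.55),
            "R3": (11.48, 15.60, 21.08),
        },
        "e_values": {
            ("R3", "R1"): 1.0,
            ("R3", "R2"): 1.0,
            ("R1", "R2"): 1.0,
            ("R1", "R3"): 0.88,
        },
        "order": ["R3", "R1", "R2"],
        "audience": ["basic", "scientific", "experiences", "young", "middle-aged", "old"],
        "domain_terms": ["breast cancer", "breast carcinoma"],
    }
    return {"weights": weights, "scores": scores, "synonyms": synonyms, "expected": expected}
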