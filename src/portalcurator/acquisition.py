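"""Content search, result merging, misrepresentation filtering, text extraction.

Each constructed query is run against one or more search backends; the
per-engine ranked hits are merged into one distinct set (minimum rank
kept per canonical URL), downloaded pages are screened for
misrepresentations — near-duplicate revisions, link-farm index pages,
pages generated by other search engines — and the survivors are
converted to whitespace-normalized plain text for the analytics phase.

The bundled local-corpus backend scores a directory of text files with
tf-idf cosine ranking, which keeps the whole pipeline runnable and
testable with no network access; a web backend is an interface stub to
be implemented against whichever engines a deployment licenses.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol
from urllib.parse import parse_qsl, urlencode, urlsplit, urlunsplit

from lxml import etree, html as lxml_html

logger = logging.getLogger("portalcurator.acquisition")

#: query parameters that only track campaigns and never change content
TRACKING_PARAMS = {
    "utm_source", "utm_medium", "utm_campaign", "utm_term", "utm_content",
    "fbclid", "gclid", "ref", "mc_cid", "mc_eid",
}

#: URL substrings that identify pages generated by other search engines
SERP_URL_PATTERNS = [
    "/search?", "google.", "bing.", "duckduckgo.", "search.yahoo.",
    "/results?", "ask.com/web",
]

MIN_EXTRACTED_CHARS = 50
NEAR_DUPLICATE_JACCARD = 0.9
INDEX_PAGE_ANCHOR_FRACTION = 0.6


class SearchError(RuntimeError):
    """All configured backends failed for a query."""


@dataclass(frozen=True)
class SearchHit:
    url: str
    rank: int
    engine: str
    retrieved_at: _dt.datetime | None = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        parts = urlsplit(self.url)
        if not parts.scheme or not (parts.netloc or parts.path):
            raise ValueError(f"syntactically invalid url: {self.url!r}")


@dataclass
class CandidateDocument:
    """A discovered document after extraction, ready for text analytics."""

    identifier: str
    source_url: str
    text: str
    best_rank: int
    publication_date: _dt.date | None = None
    authors: list[str] = field(default_factory=list)
    query: str = ""

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"candidate {self.identifier!r} has empty text")
        if self.best_rank < 1:
            raise ValueError("best_rank must be >= 1")


class SearchBackend(Protocol):
    """Interface a search engine adapter must provide."""

    name: str

    def submit(self, query: str, top_k: int) -> list[SearchHit]: ...


class LocalCorpusBackend:
    """Offline backend: tf-idf cosine ranking over a directory of .txt files.

    Emulates a search engine for development and testing; hit URLs use
    the ``file://`` scheme so the rest of the pipeline is unchanged.
    """

    def __init__(self, corpus_dir: str | Path, name: str = "local"):
        self.name = name
        self.corpus_dir = Path(corpus_dir)
        self._paths = sorted(self.corpus_dir.glob("*.txt"))
        self._texts = [p.read_text(encoding="utf-8") for p in self._paths]
        self._vectorizer = None
        self._matrix = None
        if self._texts:
            from sklearn.feature_extraction.text import TfidfVectorizer

            self._vectorizer = TfidfVectorizer()
            self._matrix = self._vectorizer.fit_transform(self._texts)

    def submit(self, query: str, top_k: int) -> list[SearchHit]:
        if self._vectorizer is None:
            return []
        qv = self._vectorizer.transform([query])
        scores = (self._matrix @ qv.T).toarray().ravel()
        order = [i for i in scores.argsort()[::-1] if scores[i] > 0][:top_k]
        return [
            SearchHit(url=self._paths[i].resolve().as_uri(), rank=pos + 1, engine=self.name)
            for pos, i in enumerate(order)
        ]


class WebBackendStub:
    """Placeholder for a live engine adapter; always raises.

    A deployment implements ``submit`` against its licensed search API.
    """

    name = "web-stub"

    def submit(self, query: str, top_k: int) -> list[SearchHit]:
        raise SearchError("web backend not configured; use --offline with a local corpus")


def search(query: str, backends: list[SearchBackend], top_k: int = 20) -> list[SearchHit]:
    """Run one query on every backend; tolerate individual backend failures.

    Raises :class:`SearchError` only when every backend fails, which
    marks the query as failed so the recurrence can reconstruct it.
    """
    if not backends:
        raise ValueError("at least one backend must be configured")
    hits: list[SearchHit] = []
    failures = 0
    for backend in backends:
        try:
            hits.extend(backend.submit(query, top_k))
        except Exception as exc:
            failures += 1
            logger.warning("backend %s failed for %r: %s", backend.name, query, exc)
    if failures == len(backends):
        raise SearchError(f"all backends failed for query {query!r}")
    return hits


def canonicalize_url(url: str) -> str:
    """Canonical form: lowercase host, no fragment, no tracking params,
    trailing slash trimmed from non-root paths."""
    parts = urlsplit(url)
    query = urlencode(
        [(k, v) for k, v in parse_qsl(parts.query, keep_blank_values=True)
         if k.lower() not in TRACKING_PARAMS]
    )
    path = parts.path
    if path.endswith("/") and path != "/":
        path = path.rstrip("/")
    return urlunsplit((parts.scheme.lower(), parts.netloc.lower(), path, query, ""))


def merge_and_dedup(hits: list[SearchHit]) -> list[SearchHit]:
    """One hit per canonical URL, keeping the best (minimum) rank; output
    re-sorted by kept rank, ties by URL for determinism."""
    best: dict[str, SearchHit] = {}
    for hit in hits:
        key = canonicalize_url(hit.url)
        if key not in best or hit.rank < best[key].rank:
            best[key] = replace(hit, url=key)
    return sorted(best.values(), key=lambda h: (h.rank, h.url))


def _shingles(text: str, k: int = 5) -> set[str]:
    norm = " ".join(text.lower().split())
    if len(norm) < k:
        return {norm} if norm else set()
    return {norm[i : i + k] for i in range(len(norm) - k + 1)}


def shingle_jaccard(a: str, b: str, k: int = 5) -> float:
    """Character k-shingle Jaccard similarity; the near-duplicate signal."""
    sa, sb = _shingles(a, k), _shingles(b, k)
    if not sa and not sb:
        return 1.0
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


def anchor_text_fraction(raw_html: str) -> float:
    """Fraction of visible characters inside <a> elements (link density)."""
    try:
        root = lxml_html.fromstring(raw_html)
    except (etree.ParserError, ValueError):
        return 0.0
    total = len("".join(root.itertext()).strip())
    if total == 0:
        return 0.0
    anchor = sum(len(a.text_content()) for a in root.iter("a"))
    return min(anchor / total, 1.0)


def is_serp_url(url: str, patterns: list[str] | None = None) -> bool:
    low = url.lower()
    return any(p in low for p in (patterns or SERP_URL_PATTERNS))


def filter_misrepresentations(
    docs: list[CandidateDocument],
    raw_html: dict[str, str] | None = None,
    jaccard_threshold: float = NEAR_DUPLICATE_JACCARD,
    anchor_threshold: float = INDEX_PAGE_ANCHOR_FRACTION,
    serp_patterns: list[str] | None = None,
) -> list[CandidateDocument]:
    """Drop misrepresented pages, logging a reason code per removal.

    Removal reasons: ``near_duplicate`` (character-shingle Jaccard with
    an earlier-ranked survivor at or above the threshold — a revision of
    the same page), ``index_page`` (anchor text dominates the raw HTML,
    when HTML is available), ``serp`` (URL matches a search-result-page
    pattern).  Earlier (better) ranked documents win ties, so the
    operation is idempotent.
    """
    raw_html = raw_html or {}
    kept: list[CandidateDocument] = []
    for doc in sorted(docs, key=lambda d: (d.best_rank, d.identifier)):
        if is_serp_url(doc.source_url, serp_patterns):
            logger.info("dropped %s: serp", doc.identifier)
            continue
        html_src = raw_html.get(doc.identifier)
        if html_src is not None and anchor_text_fraction(html_src) > anchor_threshold:
            logger.info("dropped %s: index_page", doc.identifier)
            continue
        dup_of = next(
            (k for k in kept if shingle_jaccard(doc.text, k.text) >= jaccard_threshold),
            None,
        )
        if dup_of is not None:
            logger.info("dropped %s: near_duplicate of %s", doc.identifier, dup_of.identifier)
            continue
        kept.append(doc)
    return kept


def _normalize_ws(text: str) -> str:
    return "\n".join(
        " ".join(line.split()) for line in text.splitlines() if line.strip()
    ).strip()

#: HTML elements whose text is boilerplate rather than body prose
_BOILERPLATE_TAGS = {"nav", "header", "footer", "aside", "script", "style", "form", "noscript"}


def extract_text(raw: bytes | str, content_type: str) -> str | None:
    """Convert a fetched document to boilerplate-stripped plain text.

    Supported types: HTML (chrome elements removed), XML (all text
    nodes), and plain text (identity modulo whitespace normalization).
    Unsupported types, undecodable bytes, and extractions shorter than
    ``MIN_EXTRACTED_CHARS`` yield ``None`` with a logged reason, and the
    document is dropped.
    """
    ctype = content_type.split(";")[0].strip().lower()
    if isinstance(raw, bytes):
        try:
            text = raw.decode("utf-8")
        except UnicodeDecodeError:
            text = raw.decode("utf-8", errors="replace")
    else:
        text = raw
    if ctype in {"text/plain", "plain"}:
        out = _normalize_ws(text)
    elif ctype in {"text/html", "application/xhtml+xml", "html"}:
        try:
            root = lxml_html.fromstring(text)
        except (etree.ParserError, ValueError):
            logger.info("extraction failed: unparseable html")
            return None
        for tag in _BOILERPLATE_TAGS:
            for el in root.findall(f".//{tag}"):
                el.drop_tree()
        out = _normalize_ws(" ".join(root.itertext()))
    elif ctype in {"text/xml", "application/xml", "xml"}:
        try:
            root = etree.fromstring(text.encode("utf-8"))
        except etree.XMLSyntaxError:
            logger.info("extraction failed: unparseable xml")
            return None
        out = _normalize_ws(" ".join(root.itertext()))
    else:
        logger.info("extraction skipped: unsupported content type %r", content_type)
        return None
    if len(out) < MIN_EXTRACTED_CHARS:
        logger.info("extraction dropped: under %d characters", MIN_EXTRACTED_CHARS)
        return None
    return out


_META_DATE_RE = re.compile(
    r'(?:article:published_time|datePublished|publication_date)["\']?\s*(?:content=|:)\s*["\']?'
    r"(\d{4}-\d{2}-\d{2})",
    re.IGNORECASE,
)


def extract_publication_date(raw_html: str) -> _dt.date | None:
    """Publication date from standard metadata tags, when present."""
    m = _META_DATE_RE.search(raw_html)
    if m:
        try:
            return _dt.date.fromisoformat(m.group(1))
        except ValueError:
            return None
    return None
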