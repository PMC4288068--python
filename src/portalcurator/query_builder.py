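"""Multi-dimensional search-query construction with synonym expansion.

Queries are assembled from two specific dimensions — the ontology term
being explored and the audience attribute values — and two generic ones:
high-level domain terms that give the search its background context, and
synonyms of the term's tokens that diversify coverage.  Query
construction and content search are recurrent: a query whose search
returns too few valid results is reconstructed by substituting the next
unused synonym for one of its tokens.

Synonyms come from a pluggable provider.  The bundled provider is a
static JSON dictionary mapping each token to ranked "direct" synonyms
(same synset) and "inherited" ones (via hypernyms); a lexical-database
provider can be substituted where one is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources as _ilr
from pathlib import Path


class ProviderError(RuntimeError):
    """The synonym provider could not be reached; expansion is skipped."""


class StaticSynonymProvider:
    """Synonyms from a JSON file: {token: {direct: [...], inherited: [...]}}.

    Lists are ordered by relevance rank (most relevant first), mirroring
    a sense-frequency ordering.
    """

    def __init__(self, table: dict[str, dict[str, list[str]]]):
        self.table = table

    @classmethod
    def from_file(cls, path: str | Path) -> "StaticSynonymProvider":
        return cls(json.loads(Path(path).read_text(encoding="utf-8")))

    @classmethod
    def bundled(cls) -> "StaticSynonymProvider":
        """The dictionary shipped with the package (palliative-care demo entries)."""
        data = _ilr.files("portalcurator.data").joinpath("synonyms_static.json")
        return cls(json.loads(data.read_text(encoding="utf-8")))

    def synonyms(self, token: str) -> list[tuple[str, str]]:
        entry = self.table.get(token.lower())
        if entry is None:
            return []
        out = [(s, "direct") for s in entry.get("direct", [])]
        out += [(s, "inherited") for s in entry.get("inherited", [])]
        return [(s, tag) for s, tag in out if s.lower() != token.lower()]


def fetch_synonyms(
    token: str,
    provider: StaticSynonymProvider,
    direct_cap: int = 3,
    inherited_cap: int = 3,
) -> list[tuple[str, str]]:
    """Ranked (synonym, relation) pairs for a single word.

    Synonyms are ordered by the provider's sense-relevance rank with the
    token itself excluded; at most ``direct_cap`` same-synset and
    ``inherited_cap`` hypernym-derived entries are kept.
    """
    if " " in token.strip():
        raise ValueError(f"fetch_synonyms expects a single word, got {token!r}")
    try:
        ranked = provider.synonyms(token)
    except Exception as exc:  # pragma: no cover - defensive wrapper
        raise ProviderError(str(exc)) from exc
    direct = [p for p in ranked if p[1] == "direct"][:direct_cap]
    inherited = [p for p in ranked if p[1] == "inherited"][:inherited_cap]
    return direct + inherited


@dataclass
class QuerySpec:
    """Everything needed to emit the expansion ladder for one ontology term."""

    base_term: str
    domain_terms: list[str] = field(default_factory=list)
    audience_values: list[str] = field(default_factory=list)
    synonym_sets: dict[str, list[str]] = field(default_factory=dict)
    expansion_level: int = 0
    used_synonyms: dict[str, int] = field(default_factory=dict)
    substitutions: dict[str, str] = field(default_factory=dict)
    exhausted: bool = False
    issued: set[str] = field(default_factory=set)

    @property
    def current_term(self) -> str:
        """The base term with the active synonym substitutions applied."""
        return " ".join(
            self.substitutions.get(t, t) for t in self.base_term.lower().split()
        )

    @property
    def current_query(self) -> str:
        return build_base_query(self.current_term, self.domain_terms)

    def __post_init__(self) -> None:
        if not self.base_term.strip():
            raise ValueError("base_term must be non-empty")


@dataclass(frozen=True)
class SearchOutcome:
    """Result-count summary used to decide whether a search failed."""

    query: str
    n_results: int
    min_results: int = 5

    @property
    def failed(self) -> bool:
        return self.n_results < self.min_results


def build_base_query(term: str, domain_terms: list[str]) -> str:
    """The level-0 query: the ontology term followed by the domain context."""
    if not term.strip():
        raise ValueError("term must be non-empty")
    parts = [term.strip()] + [d.strip() for d in domain_terms if d.strip()]
    return " ".join(parts).lower()


def expand_queries(spec: QuerySpec, max_level: int) -> list[str]:
    """Emit the duplicate-free expansion ladder up to ``max_level``.

    Level 0 is the base query.  Level 1 appends audience attribute values
    one at a time.  Level 2 substitutes synonyms for base-term tokens,
    one substitution per query.  One dimension is added per level, so
    the list grows linearly, never combinatorially.
    """
    if max_level < 0:
        raise ValueError("max_level must be >= 0")
    base = build_base_query(spec.base_term, spec.domain_terms)
    queries: list[str] = [base]
    if max_level >= 1:
        for value in spec.audience_values:
            queries.append(f"{base} {value.lower()}")
    if max_level >= 2:
        tokens = spec.base_term.lower().split()
        for tok in tokens:
            for syn in spec.synonym_sets.get(tok, []):
                substituted = [syn.lower() if t == tok else t for t in tokens]
                queries.append(build_base_query(" ".join(substituted), spec.domain_terms))
    seen: set[str] = set()
    out: list[str] = []
    for q in queries:
        if q not in seen:
            seen.add(q)
            out.append(q)
    return out


def reconstruct_failed_query(spec: QuerySpec, failure: SearchOutcome) -> QuerySpec:
    """Rebuild a failed query by substituting the next unused synonym.

    Tokens of the original base term are tried in order; for each, the
    next not-yet-used synonym (most relevant first) replaces that single
    token while the others keep their original form.  When every synonym
    of every token has been consumed the spec is returned unchanged with
    ``exhausted`` set, signalling the caller to stop the recurrence.  The
    same query string is never issued twice.
    """
    if not failure.failed:
        return spec
    tokens = spec.base_term.lower().split()
    issued = set(spec.issued) | {failure.query}
    used = dict(spec.used_synonyms)
    for tok in tokens:
        syns = spec.synonym_sets.get(tok, [])
        idx = used.get(tok, 0)
        while idx < len(syns):
            subs = {tok: syns[idx].lower()}
            candidate_tokens = [subs.get(t, t) for t in tokens]
            candidate = build_base_query(" ".join(candidate_tokens), spec.domain_terms)
            idx += 1
            if candidate not in issued:
                used[tok] = idx
                return replace(
                    spec,
                    used_synonyms=used,
                    substitutions=subs,
                    issued=issued | {candidate},
                    expansion_level=spec.expansion_level + 1,
                )
        used[tok] = idx
    return replace(spec, used_synonyms=used, issued=issued, exhausted=True)
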