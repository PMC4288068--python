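"""Content-management model: audience, ontology, repository, and the expert matrix.

A curated health-information portal is modelled by four entities: a target
audience A partitioned into subgroups with similar information needs, a
domain ontology T of expert-chosen subject terms, the set D of endorsed
content resources, and the expert transformation E mapping (audience
subgroup, term) requirement pairs to the subset of D that addresses them.
E is stored sparsely — actual information requirements are typically a
strict subset of the full A x T product.

The on-disk form is a JSON manifest (resources with metadata, ontology
terms, audience attributes) beside a directory of UTF-8 plain-text bodies
keyed by resource identifier.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path


class ValidationError(ValueError):
    """Raised when a repository violates a model invariant."""


class LookupError_(KeyError):
    """Raised when a term or resource is not present in the model."""


@dataclass(frozen=True)
class AudienceAttribute:
    """A named audience dimension with its finite set of values."""

    name: str
    values: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValidationError(f"audience attribute {self.name!r} has no values")
        if len(set(self.values)) != len(self.values):
            raise ValidationError(f"audience attribute {self.name!r} has duplicate values")


@dataclass(frozen=True)
class OntologyTerm:
    """A subject term from the domain ontology.

    ``weight`` expresses the term's importance within the ontology (for
    instance derived from its hierarchical position); it feeds the
    ontology factor of the extended NC-value.
    """

    label: str
    parent: str | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        label = " ".join(self.label.split())
        if not label:
            raise ValidationError("ontology term label empty after normalization")
        object.__setattr__(self, "label", label)
        if self.weight < 0:
            raise ValidationError(f"ontology term {label!r} has negative weight")


@dataclass
class Resource:
    """An endorsed repository document with its metadata and term links."""

    identifier: str
    title: str
    text: str
    authors: list[str] = field(default_factory=list)
    publication_date: _dt.date | None = None
    linked_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValidationError(f"resource {self.identifier!r} has empty text")


@dataclass
class ContentMatrix:
    """Sparse expert matrix E: (audience subgroup, term) -> resource ids.

    The audience component may be ``None`` for links that an expert made
    at the term level without restricting the subgroup.
    """

    entries: dict[tuple[str | None, str], set[str]] = field(default_factory=dict)

    def add(self, term: str, resource_id: str, audience: str | None = None) -> None:
        self.entries.setdefault((audience, term), set()).add(resource_id)


@dataclass
class RepositoryModel:
    """The loaded and validated content-management model."""

    resources: dict[str, Resource]
    ontology: dict[str, OntologyTerm]
    audience: list[AudienceAttribute]
    matrix: ContentMatrix

    def validate(self) -> None:
        for key_audience, term in self.matrix.entries:
            if term not in self.ontology:
                raise ValidationError(f"matrix entry references unknown term {term!r}")
            for rid in self.matrix.entries[(key_audience, term)]:
                if rid not in self.resources:
                    raise ValidationError(
                        f"matrix entry for term {term!r} references unknown resource {rid!r}"
                    )
        for res in self.resources.values():
            for term in res.linked_terms:
                if term not in self.ontology:
                    raise ValidationError(
                        f"resource {res.identifier!r} linked to term {term!r} "
                        "absent from the ontology"
                    )
        # parent links must be acyclic
        for label in self.ontology:
            seen = {label}
            cur = self.ontology[label].parent
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"ontology parent cycle through {label!r}")
                seen.add(cur)
                cur = self.ontology[cur].parent if cur in self.ontology else None


def _parse_date(value: str | None) -> _dt.date | None:
    if not value:
        return None
    return _dt.date.fromisoformat(value)


def load_repository(path: str | Path, format: str = "json") -> RepositoryModel:
    """Load a repository from disk and validate every model invariant.

    ``format='json'`` expects ``manifest.json`` plus a ``texts/`` directory
    of ``<id>.txt`` bodies.  ``format='csv+textdir'`` expects
    ``resources.csv`` (one row per resource: id, title, authors
    ';'-separated, date, terms ';'-separated), ``ontology.csv`` and the
    same ``texts/`` directory; audience attributes are JSON-only.
    """
    root = Path(path)
    if not root.exists():
        raise FileNotFoundError(f"repository path does not exist: {root}")
    if format == "json":
        manifest_path = root / "manifest.json"
        if not manifest_path.exists():
            raise FileNotFoundError(f"missing manifest: {manifest_path}")
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
        ontology = {
            t["label"]: OntologyTerm(
                label=t["label"], parent=t.get("parent"), weight=float(t.get("weight", 1.0))
            )
            for t in manifest.get("ontology", [])
        }
        audience = [
            AudienceAttribute(name=a["name"], values=tuple(a["values"]))
            for a in manifest.get("audience", [])
        ]
        resources: dict[str, Resource] = {}
        for entry in manifest.get("resources", []):
            rid = entry["id"]
            if rid in resources:
                raise ValidationError(f"duplicate resource identifier {rid!r}")
            text_path = root / "texts" / f"{rid}.txt"
            if not text_path.exists():
                raise FileNotFoundError(f"missing text body for resource {rid!r}: {text_path}")
            resources[rid] = Resource(
                identifier=rid,
                title=entry.get("title", rid),
                text=text_path.read_text(encoding="utf-8"),
                authors=list(entry.get("authors", [])),
                publication_date=_parse_date(entry.get("date")),
                linked_terms=set(entry.get("terms", [])),
            )
    elif format == "csv+textdir":
        ontology = {}
        with open(root / "ontology.csv", newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                ontology[row["label"]] = OntologyTerm(
                    label=row["label"],
                    parent=row.get("parent") or None,
                    weight=float(row.get("weight") or 1.0),
                )
        audience = []
        resources = {}
        with open(root / "resources.csv", newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                rid = row["id"]
                if rid in resources:
                    raise ValidationError(f"duplicate resource identifier {rid!r}")
                text_path = root / "texts" / f"{rid}.txt"
                resources[rid] = Resource(
                    identifier=rid,
                    title=row.get("title", rid),
                    text=text_path.read_text(encoding="utf-8"),
                    authors=[a for a in (row.get("authors") or "").split(";") if a],
                    publication_date=_parse_date(row.get("date")),
                    linked_terms={t for t in (row.get("terms") or "").split(";") if t},
                )
    else:
        raise ValueError(f"unknown repository format {format!r}")

    matrix = ContentMatrix()
    for res in resources.values():
        for term in res.linked_terms:
            matrix.add(term, res.identifier)
    model = RepositoryModel(resources=resources, ontology=ontology, audience=audience, matrix=matrix)
    model.validate()
    return model


def save_repository(model: RepositoryModel, path: str | Path) -> None:
    """Serialize a model to the JSON manifest + text-directory layout."""
    root = Path(path)
    (root / "texts").mkdir(parents=True, exist_ok=True)
    manifest = {
        "resources": [
            {
                "id": r.identifier,
                "title": r.title,
                "authors": r.authors,
                "date": r.publication_date.isoformat() if r.publication_date else None,
                "terms": sorted(r.linked_terms),
            }
            for r in sorted(model.resources.values(), key=lambda r: r.identifier)
        ],
        "ontology": [
            {"label": t.label, "parent": t.parent, "weight": t.weight}
            for t in sorted(model.ontology.values(), key=lambda t: t.label)
        ],
        "audience": [{"name": a.name, "values": list(a.values)} for a in model.audience],
    }
    (root / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    for r in model.resources.values():
        (root / "texts" / f"{r.identifier}.txt").write_text(r.text, encoding="utf-8")


def resources_for_term(
    term: str, model: RepositoryModel, audience: str | None = None
) -> set[str]:
    """Resource identifiers endorsed for ``term`` (R_q for a query term).

    With ``audience`` given, only matrix entries tagged with that subgroup
    (or untagged entries) contribute; without it the union over all
    subgroups is returned.
    """
    if term not in model.ontology:
        raise LookupError_(f"term {term!r} not in ontology")
    out: set[str] = set()
    for (aud, t), rids in model.matrix.entries.items():
        if t != term:
            continue
        if audience is not None and aud is not None and aud != audience:
            continue
        out |= rids
    return out


def term_resource_histogram(matrix: ContentMatrix) -> list[tuple[str, int]]:
    """Per-term endorsed-resource counts, descending (ties lexicographic).

    This is the long-tail profile a curated repository typically shows:
    a few heavily-populated headline topics and many sparsely covered
    specific ones.
    """
    counts: dict[str, int] = {}
    for (_aud, term), rids in matrix.entries.items():
        counts[term] = counts.get(term, 0) + len(rids)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
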