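"""Shared fixtures: a small in-memory repository and generated corpora."""

from __future__ import annotations

import datetime as dt

import pytest

from portalcurator.cm_model import (
    AudienceAttribute,
    ContentMatrix,
    OntologyTerm,
    RepositoryModel,
    Resource,
)


@pytest.fixture
def toy_model() -> RepositoryModel:
    """Three endorsed resources over two ontology terms."""
    ontology = {
        "palliative care": OntologyTerm("palliative care"),
        "reviews": OntologyTerm("reviews"),
    }
    resources = {
        "r1": Resource(
            identifier="r1",
            title="Palliative care overview",
            text=(
                "The palliative care team supports patients. "
                "A palliative care specialist explains treatment options. "
                "Palliative care improves comfort for patients and family."
            ),
            authors=["Cancer Council Australia"],
            publication_date=dt.date(2025, 3, 1),
            linked_terms={"palliative care"},
        ),
        "r2": Resource(
            identifier="r2",
            title="Review of therapies",
            text=(
                "This review summarises recent therapy trials. "
                "Reviews of evidence guide clinical practice decisions."
            ),
            authors=["J Smith"],
            publication_date=dt.date(2024, 7, 15),
            linked_terms={"reviews"},
        ),
        "r3": Resource(
            identifier="r3",
            title="Care at home",
            text=(
                "Home based palliative care requires coordination. "
                "The palliative care team visits weekly to review symptoms."
            ),
            authors=["National Breast Cancer Centre"],
            publication_date=dt.date(2025, 1, 10),
            linked_terms={"palliative care"},
        ),
    }
    matrix = ContentMatrix()
    for res in resources.values():
        for term in res.linked_terms:
            matrix.add(term, res.identifier)
    audience = [
        AudienceAttribute("level of knowledge", ("basic", "scientific", "experiences")),
        AudienceAttribute("age group", ("young", "middle-aged", "old")),
    ]
    model = RepositoryModel(
        resources=resources, ontology=ontology, audience=audience, matrix=matrix
    )
    model.validate()
    return model
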