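"""Fuzzy multi-criteria ranking of discovered content.

Four quality criteria are measured for every candidate that passed the
relevance threshold: c1 relevance from the multi-word similarity, c2
relevance from the single-word similarity, c3 timeliness from search
rank and publication date, and c4 reliability from author/publisher
validation against the endorsed repository.  (A fifth quality, the
usefulness of a resource to its audience, needs audience feedback and is
deliberately not scored.)  Because how much each criterion matters
varies with the ontology term under review — timeliness matters little
for a settled review topic, a lot for treatment news — the criterion
weights are elicited from domain experts as triangular fuzzy numbers
(TFNs), multiple experts being combined by component-wise geometric
mean.

A TFN M = (l, m, u), l <= m <= u, has the piecewise-linear membership

    mu(x) = (x - l)/(m - l)   on [l, m]
            (u - x)/(u - m)   on [m, u]
            0                 elsewhere

Each crisp criterion score a (normalized to 1-10) is multiplied into its
weight TFN, the four weighted TFNs are summed component-wise, and the
resulting per-candidate fuzzy totals are compared pairwise by the
degree of possibility that one exceeds another:

    e_ij = 1                                          if m_i >= m_j
           0                                          if l_j >= u_i
           (l_j - u_i) / ((m_i - u_i) - (m_j - l_j))  otherwise

Candidate i outranks j iff e_ij = 1 and e_ji < Q, with Q a fixed
fraction below 1 (0.9 by default).
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

DEFAULT_Q = 0.9
CRITERIA = ("c1", "c2", "c3", "c4")


class ElicitationError(ValueError):
    """Invalid expert weight input (e.g. non-positive component)."""


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """(l, m, u): smallest possible, most promising, largest possible."""

    l: float
    m: float
    u: float

    def __post_init__(self) -> None:
        if not (self.l <= self.m <= self.u):
            raise ValueError(f"TFN requires l <= m <= u, got {(self.l, self.m, self.u)}")

    def scale(self, k: float) -> "TriangularFuzzyNumber":
        if k < 0:
            raise ValueError("scale factor must be non-negative")
        return TriangularFuzzyNumber(self.l * k, self.m * k, self.u * k)

    def __add__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        return TriangularFuzzyNumber(self.l + other.l, self.m + other.m, self.u + other.u)

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (round(self.l, ndigits), round(self.m, ndigits), round(self.u, ndigits))


TFN = TriangularFuzzyNumber


def membership(ftn: TFN, x: float) -> float:
    """The TFN's membership function evaluated at x."""
    if x < ftn.l or x > ftn.u:
        return 0.0
    if x == ftn.m:
        return 1.0
    if x < ftn.m:
        return (x - ftn.l) / (ftn.m - ftn.l) if ftn.m > ftn.l else 1.0
    return (ftn.u - x) / (ftn.u - ftn.m) if ftn.u > ftn.m else 1.0


def weight_from_spread(m: float, rho: float) -> TFN:
    """Expert weight (m - rho, m, m + rho), clamped to [0, 1]."""
    if rho < 0:
        raise ValueError("spread must be >= 0")
    return TFN(max(m - rho, 0.0), min(max(m, 0.0), 1.0), min(m + rho, 1.0))


@dataclass(frozen=True)
class ExpertWeight:
    criterion: str
    term: str
    ftn: TFN
    expert: str = "expert-1"

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if not (0.0 <= self.ftn.l and self.ftn.u <= 1.0):
            raise ElicitationError("weight TFN components must lie in [0, 1]")


def aggregate_expert_weights(weights: list[ExpertWeight]) -> TFN:
    """Component-wise geometric mean of one (criterion, term)'s elicitations."""
    if not weights:
        raise ValueError("at least one expert weight required")
    if len(weights) == 1:
        return weights[0].ftn
    for w in weights:
        if w.ftn.l <= 0 or w.ftn.m <= 0 or w.ftn.u <= 0:
            raise ElicitationError(
                "geometric aggregation needs strictly positive components"
            )
    n = len(weights)
    gm = lambda vals: math.exp(sum(math.log(v) for v in vals) / n)  # noqa: E731
    return TFN(
        gm([w.ftn.l for w in weights]),
        gm([w.ftn.m for w in weights]),
        gm([w.ftn.u for w in weights]),
    )


@dataclass(frozen=True)
class CriterionScores:
    """Crisp per-criterion scores on the 1-10 scale.

    Reliability is 0 (below the scale) for unknown authors, so that
    such resources sink in the ranking and the expert intervenes.
    """

    relevance_multi: float
    relevance_single: float
    timeliness: float
    reliability: float

    def __post_init__(self) -> None:
        for name in ("relevance_multi", "relevance_single", "timeliness"):
            v = getattr(self, name)
            if not (1.0 <= v <= 10.0):
                raise ValueError(f"{name} must lie in [1, 10], got {v}")
        if self.reliability != 0.0 and not (1.0 <= self.reliability <= 10.0):
            raise ValueError("reliability must be 0 or in [1, 10]")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.relevance_multi, self.relevance_single, self.timeliness, self.reliability)


def _minmax_to_scale(value: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return 10.0
    return 1.0 + 9.0 * (value - lo) / (hi - lo)


def author_match_strength(authors: list[str], known_authors: set[str]) -> float:
    """Direct validation of author/publisher names against the repository.

    1.0 for a case-folded exact match, 0.8 for a strong token overlap
    (Jaccard >= 0.8), else 0.0 (unknown).
    """
    known_folded = {a.casefold().strip() for a in known_authors}
    known_tokens = [set(a.casefold().split()) for a in known_authors]
    best = 0.0
    for author in authors:
        a = author.casefold().strip()
        if not a:
            continue
        if a in known_folded:
            return 1.0
        toks = set(a.split())
        for kt in known_tokens:
            union = toks | kt
            if union and len(toks & kt) / len(union) >= 0.8:
                best = max(best, 0.8)
    return best


def compute_criterion_scores(
    sim_multi: float,
    sim_single: float,
    best_rank: int,
    publication_date: _dt.date | None,
    authors: list[str],
    known_authors: set[str],
    pool_sim_multi: tuple[float, float],
    pool_sim_single: tuple[float, float],
    pool_size: int,
    today: _dt.date | None = None,
) -> CriterionScores:
    """Normalize the raw quality measures of one candidate to the 1-10 scale.

    c1 and c2 min-max normalize the two cosine similarities over the
    passed-candidate pool (``pool_sim_*`` are that pool's (min, max)).
    c3 blends the inverse search rank with recency, where recency decays
    as exp(-age_days/365) and defaults to 0.5 when no date is known.
    c4 is 10 x the author-match strength (clamped into [1, 10]) for
    known authors and 0 for unknown ones.
    """
    if pool_size < 1:
        raise ValueError("normalization pool must be non-empty")
    c1 = _minmax_to_scale(sim_multi, *pool_sim_multi)
    c2 = _minmax_to_scale(sim_single, *pool_sim_single)
    rank_component = 1.0 if pool_size == 1 else 1.0 - (best_rank - 1) / (pool_size - 1)
    rank_component = min(max(rank_component, 0.0), 1.0)
    if publication_date is not None:
        age_days = max(((today or _dt.date.today()) - publication_date).days, 0)
        recency = math.exp(-age_days / 365.0)
    else:
        recency = 0.5
    c3 = min(max(1.0 + 9.0 * (0.5 * rank_component + 0.5 * recency), 1.0), 10.0)
    strength = author_match_strength(authors, known_authors)
    c4 = 0.0 if strength == 0.0 else min(max(10.0 * strength, 1.0), 10.0)
    return CriterionScores(
        relevance_multi=min(max(c1, 1.0), 10.0),
        relevance_single=min(max(c2, 1.0), 10.0),
        timeliness=c3,
        reliability=c4,
    )


def weighted_score(score: float, weight: TFN) -> TFN:
    """One criterion's contribution: the crisp score scaled into the weight TFN."""
    if score < 0:
        raise ValueError("criterion score must be >= 0")
    return weight.scale(score)


def weighted_sum(scores: CriterionScores, weights: dict[str, TFN]) -> TFN:
    """Component-wise sum of the four weighted criterion TFNs."""
    missing = [c for c in CRITERIA if c not in weights]
    if missing:
        raise ValueError(f"missing weights for criteria: {missing}")
    total = TFN(0.0, 0.0, 0.0)
    for criterion, score in zip(CRITERIA, scores.as_tuple()):
        total = total + weighted_score(score, weights[criterion])
    return total


def degree_of_possibility(si: TFN, sj: TFN) -> float:
    """e_ij: the degree of possibility that fuzzy total si >= sj."""
    if si.m >= sj.m:
        return 1.0
    if sj.l >= si.u:
        return 0.0
    denom = (si.m - si.u) - (sj.m - sj.l)
    if denom == 0:
        return 0.0  # si.m < sj.m here, so possibility collapses
    return (sj.l - si.u) / denom


def rank(
    resources: list[tuple[str, TFN]], q_threshold: float = DEFAULT_Q
) -> tuple[list[str], dict[tuple[str, str], float]]:
    """Order candidates by the pairwise degree-of-possibility rule.

    i outranks j iff e_ij = 1 and e_ji < Q.  Candidates are sorted by
    their number of decisive wins; pairs left undecided by the rule
    (e_ij = 1 and e_ji >= Q) fall back to the larger modal value, then
    the identifier.  The full e-matrix is returned for expert
    inspection.
    """
    if not resources:
        raise ValueError("rank requires at least one resource")
    if not (0.0 < q_threshold < 1.0):
        raise ValueError("Q must be a fraction strictly between 0 and 1")
    ids = [rid for rid, _ in resources]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate resource identifiers")
    ftns = dict(resources)
    ematrix: dict[tuple[str, str], float] = {}
    for i in ids:
        for j in ids:
            ematrix[(i, j)] = degree_of_possibility(ftns[i], ftns[j]) if i != j else 1.0
    wins = {i: 0 for i in ids}
    for i in ids:
        for j in ids:
            if i != j and ematrix[(i, j)] == 1.0 and ematrix[(j, i)] < q_threshold:
                wins[i] += 1
    order = sorted(ids, key=lambda i: (-wins[i], -ftns[i].m, i))
    return order, ematrix


# ---------------------------------------------------------------------------
# Weight elicitation files
# ---------------------------------------------------------------------------

def load_weights(path: str | Path) -> dict[str, dict[str, TFN]]:
    """Load per-term criterion weights from a YAML or JSON elicitation file.

    Layout: {term: {c1: [l, m, u], ..., c4: [l, m, u]}, "_default": {...}}.
    A list of such mappings (one per expert) is aggregated criterion-wise
    by geometric mean.
    """
    p = Path(path)
    raw = p.read_text(encoding="utf-8")
    data = json.loads(raw) if p.suffix == ".json" else yaml.safe_load(raw)
    experts = data if isinstance(data, list) else [data]
    terms: set[str] = set()
    for sheet in experts:
        terms |= set(sheet)
    out: dict[str, dict[str, TFN]] = {}
    for term in terms:
        out[term] = {}
        for criterion in CRITERIA:
            elicited = [
                ExpertWeight(
                    criterion=criterion,
                    term=term,
                    ftn=TFN(*[float(x) for x in sheet[term][criterion]]),
                    expert=f"expert-{k}",
                )
                for k, sheet in enumerate(experts, 1)
                if term in sheet and criterion in sheet[term]
            ]
            if elicited:
                out[term][criterion] = aggregate_expert_weights(elicited)
    return out


def weights_for_term(table: dict[str, dict[str, TFN]], term: str) -> dict[str, TFN]:
    """Weights for ``term``, falling back to the ``_default`` entry."""
    if term in table:
        return table[term]
    if "_default" in table:
        return table["_default"]
    raise KeyError(f"no weights elicited for term {term!r} and no _default entry")
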