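# portalcurator

Automated content discovery and ranking for expert-curated health
information portals.

## The problem

Curated health portals (breast-cancer information services, heart-health
sites, and the like) live or die by their content management: a domain
expert must continuously find new online resources that are relevant to
a well-defined audience, reliable, and current — against an exponential
stream of new web content. `portalcurator` implements an intelligent
discovery technique that leverages what such a portal already has: an
**expert-endorsed content repository** aligned to a **domain ontology**
of subject terms and an **audience profile**. The endorsed content
serves as a benchmark against which newly discovered documents are
measured, so the expert reviews a short ranked list instead of raw
search results.

## The method

The pipeline runs in four phases per ontology term *t*:

1. **Query construction.** Multi-dimensional queries are assembled from
   the specific dimensions (the term, audience attribute values) and
   generic dimensions (high-level domain terms, synonyms of the term's
   tokens, token-by-token). Failed searches are reconstructed by
   substituting the next-ranked unused synonym; the same query is never
   issued twice.
2. **Content search.** Each query runs on one or more search backends;
   results are merged per canonical URL (best rank kept), screened for
   misrepresentations (near-duplicate revisions by character-shingle
   Jaccard, link-farm index pages by anchor density, search-result
   pages by URL pattern), and converted to plain text. A local-corpus
   backend makes the whole pipeline runnable offline.
3. **Text analytics.** After stop-word removal and Porter stemming,
   multi-word terms are recognized with the C-value/NC-value approach
   extended by domain-ontology evidence. For a candidate term *a* of
   length |a| with corpus frequency *f(a)*, nested in the set *T_a* of
   longer candidates:

       C-value(a) = log2|a| · f(a)                              (T_a = ∅)
       C-value(a) = log2|a| · ( f(a) − (1/|T_a|) Σ_{b∈T_a} f(b) )

       NC-value(a)     = 0.8·C-value(a) + 0.2·(context factor)
       ext-NC-value(a) = 0.6·C-value(a) + 0.2·(context) + 0.2·(ontology)

   Each document is then represented twice in a vector space model —
   over single-word stems and over accepted multi-word terms — with
   tf·ln(N/df) weights, length-normalized. The endorsed resources
   matched to *t* are converged into one benchmark pseudo-document,
   giving benchmark vectors vsm(R_q) and vsm_m(R_q); candidates whose
   cosine against a benchmark reaches **0.75** pass to ranking.
4. **Fuzzy multi-criteria ranking.** Four quality criteria — relevance
   from the multi-word similarity (c1) and single-word similarity (c2),
   timeliness from search rank and publication date (c3), reliability
   from author/publisher validation against the repository (c4) — are
   normalized to 1–10. Because the importance of each criterion varies
   by term, the weights are elicited from experts as triangular fuzzy
   numbers *w = (l, m, u)* (multiple experts aggregated by geometric
   mean). Each candidate's fuzzy total is S_r = Σ_c a_cr·w_c, and
   candidates are ordered by the pairwise degree of possibility

       e_ij = 1                                      if m_i ≥ m_j
              0                                      if l_j ≥ u_i
              (l_j − u_i) / ((m_i − u_i) − (m_j − l_j))  otherwise

   with *i* outranking *j* iff e_ij = 1 and e_ji < Q (default Q = 0.9).

See `docs/methods.md` for the assumptions, parameter defaults, and
design choices in detail.

## Worked example

The standalone ranking entry point reproduces the demonstration
ranking of three candidate resources for the term *reviews*, from their
normalized criterion scores and the elicited weights:

```bash
$ cat scores.tsv
id	c1	c2	c3	c4
R1	7.50	5.50	4.10	6.90
R2	5.40	9.20	8.70	0
R3	8.50	4.70	6.80	7.20

$ portalcurator rank --scores scores.tsv --weights weights.yaml --term reviews
rank	id	sum_l	sum_m	sum_u
1	R3	11.48	15.60	21.08
2	R1	10.97	14.47	19.55
3	R2	9.63	12.83	16.62

e-matrix (row beats column):
	R1	R2	R3
R1	1.00	1.00	0.88
R2	0.78	1.00	0.65
R3	1.00	1.00	1.00
```

Reading: R3's fuzzy total (11.48, 15.60, 21.08) fully dominates the
other two (e_31 = e_32 = 1 while e_13 = 0.88 and e_23 = 0.65 stay below
Q = 0.9), R1 beats R2, and R2 — whose reliability is zero because its
author is unknown to the repository — ranks last for expert scrutiny.

A full offline discovery run on generated fixtures:

```bash
portalcurator fixtures generate-repository --out repo --topics 5 --seed 1
portalcurator fixtures generate-candidates --out cands --topics 5 --seed 1
portalcurator discover --config run.yaml          # see docs/methods.md
```

Every intermediate artifact (queries, hits, recognized terms, vectors,
similarity scores, the e-matrix, and the final ranking) is persisted
per term so the domain expert can audit each phase.

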