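"""Gene Ontology over-representation analysis.

Annotations are first closed under the true-path rule (a gene annotated to
a term is annotated to all its ancestors), then each term with at least one
study hit is tested with a one-sided hypergeometric (Fisher exact upper
tail) against the background population.  Terms with p below ``alpha``
(default 0.01, on raw p-values) are reported sorted by p-value, each with
its gene ratio — study hits divided by all population genes annotated to
the term.

An EASE-style variant (one subtracted from the hit count before the tail
probability, as reported by the DAVID web service) is available via
``method="ease"``; plain Fisher is the default.  Benjamini-Hochberg
adjustment is available via ``correction="bh"`` but is off by default,
matching a raw p < alpha criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .errors import DomainError
from .formats import Annotation, Ontology

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentTerm:
    term_id: str
    p_value: float
    study_hits: int
    study_size: int
    term_population_count: int
    population_size: int
    hit_genes: frozenset[str]

    @property
    def gene_ratio(self) -> float:
        """Study hits / all population genes annotated to the term."""
        return self.study_hits / self.term_population_count


@dataclass
class EnrichmentReport:
    contrast_name: str
    direction: str
    alpha: float
    terms: list[EnrichmentTerm] = field(default_factory=list)
    n_dropped: int = 0  # study genes outside the population

    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]


def propagate_annotations(ontology: Ontology, annotation: Annotation) -> Annotation:
    """Close a direct annotation under is_a ancestry (true-path rule).

    Idempotent: propagating an already-closed annotation changes nothing.
    """
    closure: dict[str, set[str]] = {}
    ancestor_cache: dict[str, set[str]] = {}
    for gene, terms in annotation.direct.items():
        full = set(terms)
        for term in terms:
            if term not in ancestor_cache:
                ancestor_cache[term] = ontology.ancestors(term)
            full |= ancestor_cache[term]
        closure[gene] = full
    return Annotation(
        {g: frozenset(t) for g, t in closure.items()}, annotation.population
    )


def hypergeometric_p(
    study_hits: int, study_size: int, term_count: int, population: int
) -> float:
    """Upper-tail P(X >= study_hits) for X hypergeometric.

    X counts term-annotated genes in a draw of ``study_size`` genes from a
    population of ``population`` genes of which ``term_count`` carry the
    annotation.
    """
    if not 0 <= study_hits <= study_size <= population:
        raise DomainError(
            f"need 0 <= hits({study_hits}) <= study({study_size}) "
            f"<= population({population})"
        )
    if not 0 <= term_count <= population:
        raise DomainError(
            f"term_count({term_count}) outside [0, population({population})]"
        )
    return float(hypergeom.sf(study_hits - 1, population, term_count, study_size))


def enrich(
    study: set[str],
    annotation: Annotation,
    ontology: Ontology,
    alpha: float = 0.01,
    *,
    contrast_name: str = "",
    direction: str = "",
    method: str = "fisher",
    correction: str | None = None,
    propagated: bool = False,
) -> EnrichmentReport:
    """Test every term with >= 1 study hit for over-representation.

    Study genes outside the background population are dropped with a logged
    count.  Terms with zero study hits are not tested (they cannot be
    enriched and would only inflate the test count).  Set
    ``propagated=True`` if ``annotation`` is already closed under ancestry.
    """
    if method not in ("fisher", "ease"):
        raise DomainError(f"unknown method {method!r}")
    if correction not in (None, "bh"):
        raise DomainError(f"unknown correction {correction!r}")
    if not propagated:
        annotation = propagate_annotations(ontology, annotation)

    study = set(study)
    dropped = study - set(annotation.population)
    if dropped:
        logger.warning(
            "%d study gene(s) outside the population dropped (%s)",
            len(dropped), contrast_name or "unnamed contrast",
        )
    study &= set(annotation.population)
    report = EnrichmentReport(contrast_name, direction, alpha,
                              n_dropped=len(dropped))
    if not study:
        logger.warning("empty study set after filtering; empty report")
        return report

    population_size = len(annotation.population)
    study_size = len(study)

    term_pop: dict[str, int] = {}
    term_hits: dict[str, set[str]] = {}
    for gene, terms in annotation.direct.items():
        in_study = gene in study
        for term in terms:
            term_pop[term] = term_pop.get(term, 0) + 1
            if in_study:
                term_hits.setdefault(term, set()).add(gene)

    results = []
    for term, hits in term_hits.items():
        k = len(hits)
        tested_k = max(k - 1, 0) if method == "ease" else k
        p = hypergeometric_p(tested_k, study_size, term_pop[term],
                             population_size)
        results.append(EnrichmentTerm(
            term_id=term,
            p_value=p,
            study_hits=k,
            study_size=study_size,
            term_population_count=term_pop[term],
            population_size=population_size,
            hit_genes=frozenset(hits),
        ))

    if correction == "bh":
        order = np.argsort([r.p_value for r in results], kind="stable")
        m = len(results)
        adj = np.empty(m)
        prev = 1.0
        for rank_from_last, idx in enumerate(order[::-1]):
            rank = m - rank_from_last
            prev = min(prev, results[idx].p_value * m / rank)
            adj[idx] = prev
        for r, q in zip(results, adj):
            r.p_value = float(q)

    kept = [r for r in results if r.p_value < alpha]
    kept.sort(key=lambda r: (r.p_value, r.term_id))
    report.terms = kept
    return report
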