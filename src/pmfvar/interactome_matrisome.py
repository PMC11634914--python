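"""Interaction compendium, heart-enhancement categorization and enrichment.

For every query protein (a gene hit by a candidate variant) a compendium of
known physical interactors is assembled from a BioGRID-like edge table
(restricted to physical, multi-validated edges: >= 2 distinct supporting
publications) unioned with a reference-interactome pair list (systematic
yeast-two-hybrid screens, exempt from the multi-validation bar since each
pair derives from one screen publication).  Interactors are then annotated
with cardiomyocyte staining intensity and matrisome membership, and two
questions are asked:

* do the query genes concentrate in particular matrisome divisions or
  families? (Pearson chi-square of observed category counts against the
  matrisome-wide background proportions), and
* do their interactors over-represent heart-enhanced proteins (high or
  medium cardiomyocyte staining)? (upper-tail hypergeometric test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import (
    GeneAnnotation,
    InteractionEdge,
    InteractionSource,
    MatrisomeDivision,
    Staining,
)

logger = logging.getLogger("pmfvar")

#: Staining classes that qualify an interactor as heart-enhanced.
DEFAULT_HEART_RULE = frozenset({Staining.HIGH, Staining.MEDIUM})

#: Minimum distinct publications for a BioGRID physical edge to count as
#: multi-validated.
MIN_PUBLICATIONS = 2


@dataclass
class Interactor:
    symbol: str
    source: InteractionSource
    n_supporting_publications: int
    staining: Staining = Staining.MISSING
    matrisome_division: MatrisomeDivision = MatrisomeDivision.NON_MATRISOME
    matrisome_category: str = "none"


@dataclass
class Compendium:
    """Per-query-protein interactor sets with provenance and annotations."""

    interactors: dict[str, dict[str, Interactor]] = field(default_factory=dict)

    def partners(self, protein: str) -> dict[str, Interactor]:
        return self.interactors.get(protein.upper(), {})

    def all_partner_symbols(self) -> set[str]:
        out: set[str] = set()
        for partners in self.interactors.values():
            out |= set(partners)
        return out


def build_compendium(edges: list[InteractionEdge], query_proteins,
                     annotations: dict[str, GeneAnnotation] | None = None,
                     min_publications: int = MIN_PUBLICATIONS) -> Compendium:
    """Assemble qualifying interactors for each query protein.

    BioGRID edges qualify when physical with >= ``min_publications``
    distinct publications; pair-list (reference interactome) edges always
    qualify.  Self-loops are dropped.  A query protein with no qualifying
    edge gets an empty set — a valid, reportable outcome.
    """
    annotations = annotations or {}
    queries = {q.strip().upper() for q in query_proteins}
    comp = Compendium({q: {} for q in queries})
    n_self = 0
    for e in edges:
        if e.is_self_loop:
            n_self += 1
            continue
        if e.source is InteractionSource.BIOGRID:
            if e.experimental_system_type != "physical":
                continue
            if e.n_supporting_publications < min_publications:
                continue
        for query, partner in ((e.protein_a, e.protein_b), (e.protein_b, e.protein_a)):
            if query not in queries:
                continue
            ann = annotations.get(partner)
            existing = comp.interactors[query].get(partner)
            if existing is not None:
                existing.n_supporting_publications = max(
                    existing.n_supporting_publications, e.n_supporting_publications)
                continue
            comp.interactors[query][partner] = Interactor(
                symbol=partner,
                source=e.source,
                n_supporting_publications=e.n_supporting_publications,
                staining=ann.cardiomyocyte_staining if ann else Staining.MISSING,
                matrisome_division=ann.matrisome_division if ann else MatrisomeDivision.NON_MATRISOME,
                matrisome_category=ann.matrisome_category if ann else "none",
            )
    if n_self:
        logger.info("dropped %d self-loop edge(s) during compendium build", n_self)
    return comp


def heart_enhanced_interactions(compendium: Compendium, protein: str,
                                rule: frozenset = DEFAULT_HEART_RULE) -> tuple[set[str], int]:
    """Interactors of ``protein`` whose cardiomyocyte staining qualifies as
    heart-enhanced; also returns the count of partners with missing
    staining annotation (excluded, but tallied)."""
    partners = compendium.partners(protein)
    enhanced = {s for s, it in partners.items() if it.staining in rule}
    n_missing = sum(1 for it in partners.values() if it.staining is Staining.MISSING)
    return enhanced, n_missing


@dataclass(frozen=True)
class EnrichmentResult:
    test: str            # chisq_division | chisq_family | hypergeom_heart
    observed: dict
    expected: dict
    statistic: float | None
    p_value: float


def chisq_category_test(observed_genes: dict[str, str],
                        background_table: dict[str, tuple[MatrisomeDivision, str]] | dict[str, str],
                        axis: str) -> EnrichmentResult:
    """Pearson chi-square of observed category counts vs background
    proportions from the matrisome table.

    ``axis`` is ``division`` (core matrisome vs matrisome-associated) or
    ``family`` (basement membranes, collagens, ECM glycoproteins, ECM
    regulators, secreted factors, ...).  Expected counts are background
    proportion x total observed; zero-background categories are dropped
    with a warning, expected counts below 5 raise a small-sample warning.
    """
    if axis not in ("division", "family"):
        raise ValueError("axis must be 'division' or 'family'")
    bg_counts: dict[str, int] = {}
    for cat in background_table.values():
        bg_counts[cat] = bg_counts.get(cat, 0) + 1
    obs_counts: dict[str, int] = {}
    for cat in observed_genes.values():
        obs_counts[cat] = obs_counts.get(cat, 0) + 1
    dropped = [c for c in obs_counts if c not in bg_counts]
    for c in dropped:
        logger.warning("category %r absent from background; dropped from chi-square", c)
        obs_counts.pop(c)
    categories = sorted(bg_counts)
    total_obs = sum(obs_counts.get(c, 0) for c in categories)
    if total_obs == 0 or len(categories) < 2:
        return EnrichmentResult(f"chisq_{axis}", obs_counts, dict(bg_counts), None, 1.0)
    total_bg = sum(bg_counts[c] for c in categories)
    observed = np.array([obs_counts.get(c, 0) for c in categories], dtype=float)
    expected = np.array([bg_counts[c] / total_bg * total_obs for c in categories])
    if np.any(expected < 5):
        logger.warning("chi-square expected count below 5; p-value approximate")
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    dof = len(categories) - 1
    p = float(stats.chi2.sf(statistic, dof))
    return EnrichmentResult(
        f"chisq_{axis}",
        dict(zip(categories, observed.astype(int))),
        dict(zip(categories, expected)),
        statistic, p,
    )


def hypergeom_enrichment(k: int, K: int, n: int, N: int) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation test, P(X >= k).

    N annotated background proteins of which K are heart-enhanced; n drawn
    interactors of which k are heart-enhanced.  Computed through the
    survival function of scipy's hypergeometric distribution (log-space
    internals), so the far tail is exact to double precision.
    """
    for name, value in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(value, (int, np.integer)) or value < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if k > min(K, n) or n > N or K > N:
        raise ValueError("need k <= min(K, n) and n, K <= N")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
    p = min(p, 1.0)
    return EnrichmentResult(
        "hypergeom_heart",
        {"k": k, "n": n},
        {"K": K, "N": N},
        None, p,
    )


def heart_enrichment_test(compendium: Compendium,
                          annotations: dict[str, GeneAnnotation],
                          rule: frozenset = DEFAULT_HEART_RULE) -> EnrichmentResult:
    """Protein-level heart-enhancement enrichment for the whole query set.

    Background N = proteins carrying a staining annotation; K = those
    heart-enhanced; n = distinct compendium interactors within the
    background; k = heart-enhanced interactors.
    """
    background = {g for g, a in annotations.items()
                  if a.cardiomyocyte_staining is not Staining.MISSING}
    K = sum(1 for g in background
            if annotations[g].cardiomyocyte_staining in rule)
    drawn = compendium.all_partner_symbols() & background
    k = sum(1 for g in drawn if annotations[g].cardiomyocyte_staining in rule)
    return hypergeom_enrichment(k, K, len(drawn), len(background))
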