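"""Biological-relevance checks for significant triplets.

A statistically significant triplet is called biologically relevant when
(i) its pair genes X and Y share an enriched annotation term — they take
part in the same biological process — and (ii) the switch gene reaches
both pair members through short paths in the mutual-information network
(filled in by :mod:`triwi.grn`).

Enrichment uses the right-tailed hypergeometric test per term, restricted
to deep terms (level > 6 by default; shallow ontology terms are too
generic to be informative), with BH correction across the tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .annotations import AnnotationCatalog
from .errors import InputError
from .liquid_association import BinSpec, TripletScore, adjust_pvalues, mla_score

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    term_id: str
    term_name: str
    level: int
    overlap: int
    query_size: int
    term_size: int
    universe_size: int
    p_raw: float
    p_bh: float
    overlap_genes: tuple[str, ...] = ()


@dataclass
class RelevanceVerdict:
    """Combined relevance call for one triplet."""

    triplet: TripletScore
    coenriched: bool = False
    supporting_terms: tuple[str, ...] = ()
    grn_supported: bool | None = None
    grn_mediators: dict = field(default_factory=dict)
    grn_reason: str | None = None

    @property
    def overall(self) -> bool:
        return bool(self.coenriched and self.grn_supported)


@dataclass
class ConditionalCorrelationProfile:
    """Per-bin pair correlation and Z range for one triplet."""

    z_ranges: list[tuple[float, float]]
    correlations: list[float]
    z_means: list[float]
    sizes: list[int]

    @property
    def r_low(self) -> float:
        return self.correlations[0]

    @property
    def r_mid(self) -> float:
        if len(self.correlations) != 3:
            raise InputError("r_mid is defined for M=3 profiles")
        return self.correlations[1]

    @property
    def r_high(self) -> float:
        return self.correlations[-1]

    def mla(self) -> float:
        """MLA recomputed from the stored per-bin summaries."""
        return float(np.mean([r * zb for r, zb in zip(self.correlations, self.z_means)]))


def enrich(
    query_genes,
    catalog: AnnotationCatalog,
    min_level: int = 7,
    alpha_bh: float = 0.05,
) -> list[EnrichmentRecord]:
    """Right-tailed hypergeometric enrichment over deep terms.

    Tests every term with level >= min_level and at least one query gene;
    returns the records whose BH-adjusted p falls below ``alpha_bh``
    (``alpha_bh=1.0`` returns every tested term), sorted by p.
    """
    query = frozenset(query_genes)
    if not query:
        raise InputError("enrichment query is empty")
    stray = query - catalog.universe
    if stray:
        raise InputError(f"query genes outside the catalog universe: {sorted(stray)[:5]}")
    N = len(catalog.universe)
    n_query = len(query)
    tested = []
    for tid in sorted(catalog.terms):
        term = catalog.terms[tid]
        if term.level < min_level:
            continue
        overlap = query & term.genes
        if not overlap:
            continue
        # P(X >= overlap) for X ~ Hypergeom(N, |term|, |query|)
        p = float(stats.hypergeom.sf(len(overlap) - 1, N, len(term.genes), n_query))
        tested.append((tid, term, overlap, min(p, 1.0)))
    if not tested:
        return []
    p_bh = adjust_pvalues([t[3] for t in tested], method="bh")
    records = [
        EnrichmentRecord(
            term_id=tid, term_name=term.name, level=term.level,
            overlap=len(overlap), query_size=n_query, term_size=len(term.genes),
            universe_size=N, p_raw=p, p_bh=float(q),
            overlap_genes=tuple(sorted(overlap)),
        )
        for (tid, term, overlap, p), q in zip(tested, p_bh)
    ]
    if alpha_bh < 1.0:
        records = [r for r in records if r.p_bh < alpha_bh]
    records.sort(key=lambda r: (r.p_raw, r.term_id))
    logger.info("enrichment: %d terms tested, %d pass BH < %g",
                len(tested), len(records), alpha_bh)
    return records


def coenrichment_check(
    triplet: TripletScore,
    enrichment: list[EnrichmentRecord],
    catalog: AnnotationCatalog,
) -> RelevanceVerdict:
    """Is there an enriched term containing both pair genes of the triplet?"""
    supporting = [
        r.term_id for r in enrichment
        if {triplet.x_gene, triplet.y_gene} <= catalog.terms[r.term_id].genes
    ]
    return RelevanceVerdict(
        triplet=triplet,
        coenriched=bool(supporting),
        supporting_terms=tuple(sorted(supporting)),
    )


def conditional_correlations(x, y, z, binspec: BinSpec) -> ConditionalCorrelationProfile:
    """Per-bin Pearson correlation of (X, Y) with the Z range of each bin.

    For M=3 the extreme bins are exposed as ``r_low`` and ``r_high`` — the
    conditional correlations of the pair in the low/high switch-gene state.
    """
    z = np.asarray(z, dtype=float)
    mla, bins = mla_score(x, y, z, binspec)
    ranges = []
    for idx in binspec.bin_indices:
        ranges.append((float(z[idx].min()), float(z[idx].max())))
    return ConditionalCorrelationProfile(
        z_ranges=ranges,
        correlations=[b.rho for b in bins],
        z_means=[b.z_bar for b in bins],
        sizes=[b.size for b in bins],
    )
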