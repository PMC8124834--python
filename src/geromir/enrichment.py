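"""Over-representation statistics for geromiR and hallmark sets.

The statistic is the upper-tail hypergeometric probability: drawing a
hit list of size ``n`` uniformly from a universe of ``N`` identifiers of
which ``K`` belong to the category, the p-value is ``P(X >= k)`` for the
observed overlap ``k``.  Categories may overlap (a miRNA annotated to
several hallmarks counts once per hallmark); Benjamini-Hochberg adjusted
values are reported for information while ranking uses the raw p.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .catalog import GeromiRCatalog, HALLMARKS, hallmark_members

__all__ = [
    "EnrichmentResult",
    "set_enrichment",
    "hallmark_enrichment",
    "permutation_null",
    "enrichment_frame",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation of one category."""

    category_id: str
    k: int  # hits in category
    K: int  # category size in population
    n: int  # hit-list size
    N: int  # population size
    p_value: float
    bh_q: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"{self.category_id}: k out of range")
        if self.K > self.N or self.n > self.N:
            raise ValueError(f"{self.category_id}: category/hits exceed population")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"{self.category_id}: p-value out of (0, 1]")


def set_enrichment(
    hits: Iterable[str],
    category: Iterable[str],
    population: Iterable[str],
    category_id: str = "set",
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of ``hits`` against ``category``.

    Both sets must be contained in ``population``.  ``p = P(X >= k)``;
    an empty overlap gives p = 1 exactly.
    """
    hits, category, population = set(hits), set(category), set(population)
    if not hits <= population:
        raise ValueError(f"hits outside population: {sorted(hits - population)[:5]}")
    if not category <= population:
        raise ValueError(
            f"category outside population: {sorted(category - population)[:5]}"
        )
    k = len(hits & category)
    K, n, N = len(category), len(hits), len(population)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(category_id, k, K, n, N, min(p, 1.0))


def hallmark_enrichment(
    down_geromirs: Iterable[str],
    platform_catalog: GeromiRCatalog,
    population_size: int | None = None,
) -> list[EnrichmentResult]:
    """Rank the hallmarks of aging by over-representation in a hit list.

    One result per hallmark with K = on-platform hallmark members and
    n = |hits|.  The population defaults to the on-platform catalog
    itself; pass ``population_size`` (e.g. the number of miRNAs tested
    on the platform) to test against the platform-wide universe instead
    -- the ranking is sensitive to this choice.  Results are sorted by
    ascending p, ties broken by descending k then category name.
    """
    hits = set(down_geromirs)
    catalog_names = platform_catalog.on_platform_names
    if not hits <= catalog_names:
        raise ValueError(
            f"hits outside platform catalog: {sorted(hits - catalog_names)[:5]}"
        )
    N = len(catalog_names) if population_size is None else int(population_size)
    if N < len(catalog_names):
        raise ValueError("population_size smaller than the on-platform catalog")
    n = len(hits)
    results = []
    for hm in HALLMARKS:
        members = hallmark_members(platform_catalog, hm) & catalog_names
        k = len(hits & members)
        p = float(hypergeom.sf(k - 1, N, len(members), n))
        results.append(
            EnrichmentResult(hm.name, k, len(members), n, N, min(p, 1.0))
        )
    qs = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    results = [replace(r, bh_q=float(q)) for r, q in zip(results, qs)]
    return sorted(results, key=lambda r: (r.p_value, -r.k, r.category_id))


def enrichment_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        (r.category_id, r.k, r.K, r.n, r.N, r.p_value, r.bh_q, rank)
        for rank, r in enumerate(results, start=1)
    ]
    return pd.DataFrame(
        rows,
        columns=["category_id", "k", "K", "n", "N", "p_value", "bh_q", "rank"],
    )


def permutation_null(
    observed_k: int,
    hits_size: int,
    category: Iterable[str],
    population: Iterable[str],
    reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Empirical tail probability of >= ``observed_k`` category hits.

    Draws ``reps`` uniform random subsets of size ``hits_size`` from the
    population and applies add-one smoothing,
    ``(#exceedances + 1) / (reps + 1)``.  Serves as an independent
    Monte-Carlo check of :func:`set_enrichment`.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a usable null")
    population = sorted(set(population))
    category = set(category)
    if not category <= set(population):
        raise ValueError("category outside population")
    n_pop = len(population)
    if hits_size > n_pop:
        raise ValueError("hits_size exceeds population size")
    member = np.fromiter((p in category for p in population), dtype=bool, count=n_pop)
    if hits_size == 0:
        exceed = reps if observed_k <= 0 else 0
        return (exceed + 1) / (reps + 1)
    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(reps, int(2e7 // max(n_pop, 1))))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        # uniform subsets: take the first hits_size positions of random orders
        keys = rng.random((m, n_pop))
        idx = np.argpartition(keys, hits_size - 1, axis=1)[:, :hits_size]
        ks = member[idx].sum(axis=1)
        exceed += int((ks >= observed_k).sum())
        done += m
    return (exceed + 1) / (reps + 1)
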