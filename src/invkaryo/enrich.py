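"""Gene-set enrichment of the inversion interval against the genomic background.

Each annotation term is tested with a 2x2 Fisher's exact test (genes inside
vs outside the inversion, carrying vs not carrying the term) and the
two-sided p-values are adjusted by Benjamini-Hochberg step-up FDR at
alpha = 0.05. Two-sided p uses the point-probability convention: the sum of
hypergeometric probabilities of tables (at fixed margins) no more likely
than the observed one. The term universe is all annotated genes; terms are
tested once each and no ontology-graph propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentRecord:
    term_id: str
    category: str
    a: int  # inversion genes with the term
    b: int  # inversion genes without
    c: int  # background genes with the term
    d: int  # background genes without
    odds_ratio: float
    p_two_sided: float
    q_bh: float = float("nan")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for the table [[a, b], [c, d]].

    OR = (a d)/(b c); 0/0 margins give p = 1. A zero denominator yields an
    infinite OR (flagged by the caller via the raw cells).
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table entries must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    if b * c == 0:
        # zero cell: infinite when the cross product is positive, undefined 0/0
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def term_enrichment(annotations: pd.DataFrame, ci_gene_set,
                    alpha: float = 0.05):
    """Fisher/BH enrichment of every term in the inversion gene set.

    ``annotations`` carries one row per (gene_id, term_id) with a category
    column; rows with term_id '.' keep termless genes in the universe.
    Returns (records sorted by q, significant subset, per-category counts of
    significant terms).
    """
    ci_gene_set = set(ci_gene_set)
    if not ci_gene_set:
        raise ValueError("empty inversion gene set")
    universe = set(annotations["gene_id"])
    outside = universe - ci_gene_set
    missing = ci_gene_set - universe
    if missing:
        raise ValueError(f"inversion genes absent from annotation universe: "
                         f"{sorted(missing)[:5]}...")
    n_ci = len(ci_gene_set)
    n_bg = len(outside)

    real = annotations[annotations["term_id"] != "."]
    records = []
    for (term, category), sub in real.groupby(["term_id", "category"], sort=True):
        genes = set(sub["gene_id"])
        a = len(genes & ci_gene_set)
        c = len(genes) - a
        if a + c == 0:
            continue
        odds, p = fisher_exact_2x2(a, n_ci - a, c, n_bg - c)
        records.append(
            EnrichmentRecord(term_id=term, category=category, a=a, b=n_ci - a,
                             c=c, d=n_bg - c, odds_ratio=odds, p_two_sided=p)
        )
    if not records:
        return [], [], {}
    q = bh_fdr([r.p_two_sided for r in records])
    for r, qi in zip(records, q):
        r.q_bh = float(qi)
    records.sort(key=lambda r: (r.q_bh, r.p_two_sided, r.term_id))
    significant = [r for r in records if r.q_bh <= alpha and r.odds_ratio > 1]
    per_category = {}
    for r in significant:
        per_category[r.category] = per_category.get(r.category, 0) + 1
    return records, significant, per_category


def enrichment_table(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in records],
            "category": [r.category for r in records],
            "a": [r.a for r in records],
            "b": [r.b for r in records],
            "c": [r.c for r in records],
            "d": [r.d for r in records],
            "odds_ratio": [r.odds_ratio for r in records],
            "p_two_sided": [r.p_two_sided for r in records],
            "q_bh": [r.q_bh for r in records],
        }
    )
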