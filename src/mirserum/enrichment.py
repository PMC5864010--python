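"""miRNA target mapping and pathway-term enrichment.

Candidate miRNAs are mapped to their experimentally validated gene targets
(union over the set, deduplicated) and the resulting gene list is scored
against pathway terms by the upper-tail hypergeometric test over a declared
background of size N:

    raw p = P(X >= k),  X ~ Hypergeom(N, K, n)

with k hits among the n query genes for a term of K members.  The ``ease``
variant discounts one hit (k-1), the conservative convention of DAVID's
modified Fisher score.  Fold enrichment is FE = (k/n)/(K/N) and the family
of term p-values is Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import TargetMap, TermMap, ValidationError
from .differential import CandidateSet

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    term: str
    hit_genes: set[int]
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p_raw: float
    p_fdr: float
    significant: bool


def map_targets(candidates, target_map: TargetMap) -> set[int]:
    """Union of validated gene targets over the candidate miRNAs.

    Accepts a :class:`CandidateSet` or any iterable of miRNA names; miRNAs
    without a mapping are logged, shared targets are counted once.
    """
    if isinstance(candidates, CandidateSet):
        names = [f for f, _ in candidates.members]
    else:
        names = list(candidates)
    genes: set[int] = set()
    unmapped = []
    for m in names:
        g = target_map.genes_of(m)
        if not g:
            unmapped.append(m)
        genes |= g
    if unmapped:
        logger.info("%d candidate miRNAs have no mapped targets: %s", len(unmapped), unmapped)
    return genes


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """FE = (k/n) / (K/N); zero when the overlap is empty."""
    if k == 0 or n == 0:
        return 0.0
    return (k / n) / (K / N)


def enrich_terms(
    genes: set[int],
    term_map: TermMap,
    alpha: float = 0.05,
    variant: str = "hypergeometric",
) -> list[EnrichmentResult]:
    """Score every term of the map against a query gene set.

    Results are sorted ascending by FDR-adjusted p (raw p, then term name,
    as tie-breaks); ``significant`` flags FDR p < alpha.
    """
    if variant not in ("hypergeometric", "ease"):
        raise ValueError(f"variant must be 'hypergeometric' or 'ease', got {variant!r}")
    N = term_map.background_size
    genes = {int(g) for g in genes}
    n = len(genes)
    if n > N:
        raise ValidationError(f"query size n={n} exceeds background N={N}")

    terms = sorted(term_map.terms)
    rows = []
    for term in terms:
        members = term_map.terms[term]
        K = len(members)
        if K > N:
            raise ValidationError(f"term {term!r} larger than background ({K} > {N})")
        hits = genes & members
        k = len(hits)
        if k == 0:
            p_raw = 1.0
        else:
            k_eff = k - 1 if variant == "ease" else k
            # P(X >= k_eff) with X ~ Hypergeom(N, K, n)
            p_raw = float(stats.hypergeom.sf(k_eff - 1, N, K, n))
        rows.append((term, hits, k, K, min(max(p_raw, 0.0), 1.0)))

    p_raws = np.array([r[4] for r in rows])
    if len(p_raws):
        _, p_fdr, _, _ = multipletests(p_raws, method="fdr_bh")
        p_fdr = np.maximum(p_fdr, p_raws)  # adjusted p never below raw p
    else:
        p_fdr = p_raws
    results = [
        EnrichmentResult(
            term=term,
            hit_genes=hits,
            k=k,
            n=n,
            K=K,
            N=N,
            fold_enrichment=fold_enrichment(k, n, K, N),
            p_raw=praw,
            p_fdr=float(pf),
            significant=bool(pf < alpha),
        )
        for (term, hits, k, K, praw), pf in zip(rows, p_fdr)
    ]
    results.sort(key=lambda r: (r.p_fdr, r.p_raw, r.term))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular report mirroring the published schema."""
    return pd.DataFrame(
        {
            "Term": [r.term for r in results],
            "Gene IDs": [", ".join(str(g) for g in sorted(r.hit_genes)) for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "Fold Enrichment": [r.fold_enrichment for r in results],
            "FDR p-value": [r.p_fdr for r in results],
        }
    )


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    enrichment_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
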