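"""GO over-representation: hypergeometric test with BH FDR control.

Term sizes are counted against the background; terms larger than 2000
background genes are omitted (too general to be informative) and, for the
biological-process ontology only, terms smaller than 10 are omitted (too
specific and largely redundant). Both bounds are strict. No ontology-graph
propagation is performed: term membership is taken as given by the
annotation file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ConfigurationError, DataIntegrityError
from .io import AnnotationSet

ENRICHMENT_COLUMNS = ["term", "aspect", "k", "K", "n", "N", "p", "q", "significant"]


@dataclass(frozen=True)
class EnrichmentConfig:
    """Term-size filters, FDR threshold and background definition."""

    max_term_size: int = 2000  # exclusive: keep terms with size <= 2000
    min_term_size_bp: int = 10  # exclusive: drop BP terms with size < 10
    fdr_threshold: float = 0.05
    background_mode: str = "screened"  # or "annotated_genome"
    bh_scope: str = "aspect"  # or "pooled"

    def validate(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ConfigurationError(f"fdr_threshold must be in (0, 1), got {self.fdr_threshold}")
        if self.min_term_size_bp >= self.max_term_size:
            raise ConfigurationError(
                f"min_term_size_bp ({self.min_term_size_bp}) must be below "
                f"max_term_size ({self.max_term_size})"
            )
        if self.background_mode not in ("screened", "annotated_genome"):
            raise ConfigurationError(f"invalid background_mode {self.background_mode!r}")
        if self.bh_scope not in ("aspect", "pooled"):
            raise ConfigurationError(f"invalid bh_scope {self.bh_scope!r}")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws).

    The probability that a size-``n`` draw from ``N`` genes, ``K`` of
    which carry the annotation, contains ``k`` or more annotated genes.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def go_enrich(
    hit_genes,
    background_genes,
    annotations: AnnotationSet,
    config: EnrichmentConfig | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of GO terms among hit genes.

    Background defaults to the screened universe restricted to annotated
    genes (``background_mode="screened"``); ``"annotated_genome"`` uses
    every annotated gene instead. BH adjustment is applied within each
    aspect separately by default. Returns one row per tested term, sorted
    by p ascending.
    """
    config = config or EnrichmentConfig()
    config.validate()
    hits = {g.upper() for g in hit_genes}
    background = {g.upper() for g in background_genes}
    stray = hits - background
    if stray:
        raise DataIntegrityError(
            f"{len(stray)} hit gene(s) not in background: {sorted(stray)[:10]}"
        )
    if not annotations.term_to_genes:
        raise DataIntegrityError("annotation set is empty")

    if config.background_mode == "annotated_genome":
        effective_bg = annotations.genes
    else:
        effective_bg = background & annotations.genes
    N = len(effective_bg)
    eff_hits = hits & effective_bg
    n = len(eff_hits)

    rows = []
    for term, genes in annotations.term_to_genes.items():
        aspect = annotations.term_aspect[term]
        term_bg = genes & effective_bg
        size = len(term_bg)
        if size == 0 or size > config.max_term_size:
            continue
        if aspect == "BP" and size < config.min_term_size_bp:
            continue
        k = len(term_bg & eff_hits)
        rows.append(
            {
                "term": term,
                "aspect": aspect,
                "k": k,
                "K": size,
                "n": n,
                "N": N,
                "p": hypergeom_upper_tail(k, size, n, N),
            }
        )
    result = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:7])
    if result.empty:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    q = np.empty(len(result))
    if config.bh_scope == "aspect":
        for _, group in result.groupby("aspect", sort=False):
            q[result.index.get_indexer(group.index)] = bh_adjust(group["p"].to_numpy())
    else:
        q = bh_adjust(result["p"].to_numpy())
    result["q"] = q
    result["significant"] = result["q"] < config.fdr_threshold
    return result.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
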