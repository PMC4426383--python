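"""Hit calling on Z-scores, condition comparison and screen summaries.

Hits are called at the mutant (allele) level with strict thresholds
(Z > z_hi increased, Z < z_lo decreased); gene-level collapsing is an
explicit separate step so both counts can be reported, matching screens
that carry multiple alleles of the same gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .enrichment import hypergeom_upper_tail
from .errors import DataIntegrityError


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round half away from zero at the given decimal precision.

    The convention used for all reported percentages (so 42.5% prints as
    43%), unlike banker's rounding.
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def percent(numerator: int, denominator: int, decimals: int = 0) -> float | None:
    """Percentage rounded half away from zero; None when undefined."""
    if denominator == 0:
        return None
    return round_half_away(100.0 * numerator / denominator, decimals)


@dataclass
class HitTable:
    """Strains called increased / decreased in one condition."""

    condition: str
    increased: set[str]
    decreased: set[str]
    z_hi: float
    z_lo: float
    n_screened: int

    def __post_init__(self) -> None:
        if self.increased & self.decreased:
            raise DataIntegrityError("increased and decreased hit sets overlap")

    def pct_increased(self, decimals: int = 1) -> float | None:
        return percent(len(self.increased), self.n_screened, decimals)

    def pct_decreased(self, decimals: int = 1) -> float | None:
        return percent(len(self.decreased), self.n_screened, decimals)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"strain_id": s, "direction": "increased"} for s in sorted(self.increased)
        ] + [{"strain_id": s, "direction": "decreased"} for s in sorted(self.decreased)]
        return pd.DataFrame(rows, columns=["strain_id", "direction"])


@dataclass
class OverlapSummary:
    """Exact set algebra of two gene/strain sets plus overlap significance."""

    n_a: int
    n_b: int
    n_intersection: int
    n_a_only: int
    n_b_only: int
    n_union: int
    universe: int | None = None
    p_value: float | None = None
    a_only: set[str] = field(default_factory=set)
    b_only: set[str] = field(default_factory=set)
    intersection: set[str] = field(default_factory=set)
    union: set[str] = field(default_factory=set)


def call_hits(scores: pd.DataFrame, config) -> HitTable:
    """Threshold one condition's Z-scores into a HitTable.

    Strictly greater / strictly less: a mutant at exactly Z = z_hi is not
    a hit.
    """
    conditions = scores["condition"].unique()
    if len(conditions) != 1:
        raise DataIntegrityError(
            f"call_hits expects scores for a single condition, got {sorted(conditions)}"
        )
    increased = set(scores.loc[scores["z"] > config.z_hi, "strain_id"])
    decreased = set(scores.loc[scores["z"] < config.z_lo, "strain_id"])
    return HitTable(
        condition=str(conditions[0]),
        increased=increased,
        decreased=decreased,
        z_hi=config.z_hi,
        z_lo=config.z_lo,
        n_screened=len(scores),
    )


def overlap_summary(set_a, set_b, universe=None) -> OverlapSummary:
    """Set algebra of two sets; one-sided hypergeometric overlap p if a
    universe is supplied.

    p = P(X >= |A∩B|) with X ~ Hypergeom(N=|universe|, K=|A|, n=|B|).
    """
    a, b = set(set_a), set(set_b)
    inter = a & b
    union = a | b
    n_universe = None
    p = None
    if universe is not None:
        n_universe = universe if isinstance(universe, int) else len(set(universe))
        if len(a) > n_universe or len(b) > n_universe:
            raise DataIntegrityError(
                f"universe ({n_universe}) smaller than a set ({len(a)}, {len(b)})"
            )
        p = hypergeom_upper_tail(len(inter), len(a), len(b), n_universe)
    return OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_intersection=len(inter),
        n_a_only=len(a - b),
        n_b_only=len(b - a),
        n_union=len(union),
        universe=n_universe,
        p_value=p,
        a_only=a - b,
        b_only=b - a,
        intersection=inter,
        union=union,
    )


def compare_conditions(hits_a: HitTable, hits_b: HitTable, universe) -> dict[str, OverlapSummary]:
    """Overlap of two conditions' hit sets, per direction.

    ``universe`` is the set (or count) of strains screened in both
    conditions; it must cover both hit sets.
    """
    return {
        "increased": overlap_summary(hits_a.increased, hits_b.increased, universe),
        "decreased": overlap_summary(hits_a.decreased, hits_b.decreased, universe),
    }


def collapse_alleles(
    hit_strains,
    allele_to_gene: dict[str, str],
    z_by_strain: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Collapse mutant(allele)-level hits onto genes.

    A gene is called if any of its alleles is called; the representative
    Z is the allele Z of largest magnitude. Returns one row per gene with
    columns gene, n_alleles, alleles, representative_z.
    """
    strains = sorted(set(hit_strains))
    unmapped = [s for s in strains if s not in allele_to_gene]
    if unmapped:
        raise DataIntegrityError(f"strains without a gene mapping: {unmapped[:10]}")
    by_gene: dict[str, list[str]] = {}
    for strain in strains:
        by_gene.setdefault(allele_to_gene[strain], []).append(strain)
    rows = []
    for gene in sorted(by_gene):
        alleles = by_gene[gene]
        rep_z = None
        if z_by_strain is not None:
            rep_z = max((z_by_strain[s] for s in alleles), key=abs)
        rows.append(
            {
                "gene": gene,
                "n_alleles": len(alleles),
                "alleles": ",".join(alleles),
                "representative_z": rep_z,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_alleles", "alleles", "representative_z"])


def _format_cell(count: int, pct: float | None) -> str:
    if pct is None:
        return f"{count} (-)"
    pct_str = f"{pct:g}"
    return f"{count} ({pct_str}%)"


def summarize_screen(
    gene_columns: dict[str, set[str]],
    ortholog_map: dict[str, set[str]],
    human_sets: dict[str, set[str]],
    decimals: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conservation summary table over gene-set columns.

    ``gene_columns`` maps column labels (e.g. "UT screened",
    "UT increased", "UT novel", ...) to gene sets. Rows: total genes,
    genes with a human ortholog, and — via the ortholog map — genes whose
    ortholog belongs to each named human gene list. Percentages use the
    column's gene count as denominator, rounded half away from zero;
    columns with zero genes report a dash.

    Returns ``(counts, formatted)``: numeric counts and display strings.
    """
    from .comparative import cross_reference_human  # local import avoids a cycle

    row_names = ["genes", "orthologs"] + list(human_sets)
    counts = pd.DataFrame(index=row_names, columns=list(gene_columns), dtype=object)
    formatted = counts.copy()
    for col_name, genes in gene_columns.items():
        genes = {g.upper() for g in genes}
        total = len(genes)
        with_ortholog = sum(1 for g in genes if ortholog_map.get(g))
        counts.loc["genes", col_name] = total
        formatted.loc["genes", col_name] = str(total)
        counts.loc["orthologs", col_name] = with_ortholog
        formatted.loc["orthologs", col_name] = _format_cell(
            with_ortholog, percent(with_ortholog, total, decimals)
        )
        for set_name, human_genes in human_sets.items():
            matched = cross_reference_human(genes, ortholog_map, human_genes)
            counts.loc[set_name, col_name] = len(matched)
            formatted.loc[set_name, col_name] = _format_cell(
                len(matched), percent(len(matched), total, decimals)
            )
    return counts, formatted
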