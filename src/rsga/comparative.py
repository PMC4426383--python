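"""Comparative gene subtraction and yeast-to-human cross-referencing.

Hits are annotated against a catalog of prior genome-instability gene
sets (mutator screens, damage-focus screens, chromosome-instability
screens, repair/replication GO terms, known transcriptional regulators of
the reporter); hits carrying no membership are the putative novel
genome-maintenance genes. Human relevance is assessed through an ortholog
map and named human gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .hits import OverlapSummary, overlap_summary, percent
from .io import read_gene_set, read_ortholog_table


@dataclass
class ReferenceCatalog:
    """Named reference gene sets plus an ortholog map.

    ``yeast_sets`` is ordered (insertion order is the display order);
    ``human_sets`` are gene lists in human identifier space.
    """

    yeast_sets: dict[str, set[str]] = field(default_factory=dict)
    human_sets: dict[str, set[str]] = field(default_factory=dict)
    orthologs: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_directory(cls, path: str | Path) -> "ReferenceCatalog":
        """Load a catalog directory.

        Convention: ``*.txt`` files are yeast gene lists except those
        prefixed ``human_``, which are human gene lists; ``orthologs.tsv``
        is the flattened two-column ortholog table.
        """
        path = Path(path)
        catalog = cls()
        for txt in sorted(path.glob("*.txt")):
            name = txt.stem
            genes = read_gene_set(txt, name=name)
            if name.startswith("human_"):
                catalog.human_sets[name] = genes
            else:
                catalog.yeast_sets[name] = genes
        ortho = path / "orthologs.tsv"
        if ortho.exists():
            catalog.orthologs = read_ortholog_table(ortho)
        return catalog


def classify_novel(
    hit_genes,
    catalog: ReferenceCatalog,
    scores: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Membership matrix of hits against every reference set.

    Returns one row per hit gene with a boolean column per reference set
    and a ``novel`` column true when the gene belongs to none of them.
    Rows are ordered by descending score when scores are supplied,
    otherwise by the input order (sorted if a plain set is given).
    """
    genes = [g.upper() for g in (sorted(hit_genes) if isinstance(hit_genes, (set, frozenset)) else hit_genes)]
    if scores is not None:
        genes = sorted(genes, key=lambda g: -scores.get(g, float("-inf")))
    matrix = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for name, reference in catalog.yeast_sets.items():
        upper = {g.upper() for g in reference}
        matrix[name] = [g in upper for g in genes]
    matrix["novel"] = ~matrix.any(axis=1) if len(catalog.yeast_sets) else True
    if len(genes) == 0:
        matrix["novel"] = pd.Series(dtype=bool)
    return matrix


def novel_genes(matrix: pd.DataFrame) -> set[str]:
    """The putative novel set: hits with no reference-set membership."""
    return set(matrix.index[matrix["novel"]])


def novel_overlap(novel_a, novel_b, universe=None) -> OverlapSummary:
    """Overlap of two conditions' novel sets; the union is the aggregate
    novel list."""
    return overlap_summary(novel_a, novel_b, universe)


@dataclass
class OrthologReport:
    """How many of a gene list carry at least one human ortholog."""

    n_genes: int
    n_with_ortholog: int
    pct_with_ortholog: float
    orthologs: dict[str, set[str]]


def map_orthologs(genes, ortholog_map: dict[str, set[str]], decimals: int = 0) -> OrthologReport:
    """Count genes with >= 1 human ortholog and report the percentage.

    The percentage is rounded half away from zero at ``decimals``.
    Raises ValueError on an empty gene list (fraction undefined).
    """
    gene_list = sorted({g.upper() for g in genes})
    if not gene_list:
        raise ValueError("gene list is empty; ortholog fraction undefined")
    mapping = {g: set(ortholog_map.get(g, set())) for g in gene_list}
    with_ortholog = {g for g, hs in mapping.items() if hs}
    return OrthologReport(
        n_genes=len(gene_list),
        n_with_ortholog=len(with_ortholog),
        pct_with_ortholog=percent(len(with_ortholog), len(gene_list), decimals),
        orthologs={g: hs for g, hs in mapping.items() if hs},
    )


def cross_reference_human(genes, ortholog_map: dict[str, set[str]], human_set) -> set[str]:
    """Yeast genes with at least one mapped human ortholog in ``human_set``."""
    human = {h.upper() for h in human_set}
    matched = set()
    for gene in genes:
        gene = gene.upper()
        if ortholog_map.get(gene, set()) & human:
            matched.add(gene)
    return matched
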