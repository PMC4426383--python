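"""Comparative gene subtraction and human cross-referencing of the hits.

Annotates each condition's increased hits against the bundle's toy
reference catalog (prior-screen stand-ins, repair/replication term
lists), isolates the putative novel set, overlaps the two conditions'
novel sets, and builds the conservation summary via the toy ortholog
map and human gene lists. Runs 02 first if its outputs are absent.
"""

import runpy
from pathlib import Path

import pandas as pd

from rsga import (
    ReferenceCatalog,
    classify_novel,
    map_orthologs,
    novel_genes,
    novel_overlap,
    read_gene_set,
    summarize_screen,
)

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"
SCORED = ROOT / "scratch" / "scored"
RESULTS = ROOT / "results"


def main() -> None:
    if not SCORED.exists():
        runpy.run_path(str(ROOT / "analysis" / "02_score_mutants.py"), run_name="__main__")
    catalog = ReferenceCatalog.from_directory(BUNDLE)
    RESULTS.mkdir(exist_ok=True)

    novel_sets = {}
    columns = {}
    for hits_path in sorted(SCORED.glob("increased_*.txt")):
        condition = hits_path.stem.removeprefix("increased_")
        hits = read_gene_set(hits_path, name=condition)
        matrix = classify_novel(hits, catalog)
        matrix.astype(int).to_csv(RESULTS / f"04_novelty_matrix_{condition}.tsv", sep="\t")
        novel = novel_genes(matrix)
        novel_sets[condition] = novel
        columns[f"{condition} increased"] = hits
        columns[f"{condition} novel"] = novel
        report = map_orthologs(hits, catalog.orthologs)
        print(
            f"{condition}: {len(hits)} increased hits, {len(novel)} "
            f"({100 * len(novel) / len(hits):.0f}%) not in any reference set; "
            f"{report.n_with_ortholog} ({report.pct_with_ortholog}%) with a human ortholog"
        )

    if len(novel_sets) == 2:
        (ca, a), (cb, b) = sorted(novel_sets.items())
        agg = novel_overlap(a, b)
        print(
            f"novel overlap {ca}/{cb}: {agg.n_intersection} shared, "
            f"aggregate of {agg.n_union} novel mutants"
        )

    counts, formatted = summarize_screen(columns, catalog.orthologs, catalog.human_sets)
    formatted.to_csv(RESULTS / "04_conservation_summary.tsv", sep="\t")
    print("\nConservation summary (count (percent of column)):")
    print(formatted.to_string())


if __name__ == "__main__":
    main()
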