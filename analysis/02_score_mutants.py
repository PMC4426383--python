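"""Score the simulated screen and call Z-score hits.

Reads the colony tables from scratch/bundle (running 01 first if
absent), applies the filter -> log-ratio -> LOESS -> average -> Z-score
chain, calls hits at |Z| > 2 per condition, and evaluates recovery of
the planted ground truth. Full per-strain tables go to scratch/scored;
compact summaries to results/.
"""

import runpy
import sys
from pathlib import Path

import pandas as pd

from rsga import (
    PipelineConfig,
    call_hits,
    compare_conditions,
    read_colony_table,
    replicate_correlation,
    score_screen,
    write_gene_set,
)

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"
SCORED = ROOT / "scratch" / "scored"
RESULTS = ROOT / "results"


def main() -> None:
    if not BUNDLE.exists():
        runpy.run_path(str(ROOT / "analysis" / "01_simulate_screen.py"), run_name="__main__")
    records = pd.concat(
        [read_colony_table(p) for p in sorted(BUNDLE.glob("colonies_*.tsv"))], ignore_index=True
    )
    result = score_screen(records)
    SCORED.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    result.scores.to_csv(SCORED / "scores.tsv", sep="\t", index=False)
    result.filter_report.to_frame().to_csv(RESULTS / "02_filter_report.tsv", sep="\t", index=False)
    print("Filter accounting:", result.filter_report.removed, "retained", result.filter_report.n_retained)

    truth = pd.read_csv(BUNDLE / "truth.tsv", sep="\t")
    config = PipelineConfig()
    rows = []
    hit_tables = {}
    for condition, group in result.scores.groupby("condition"):
        table = call_hits(group, config)
        hit_tables[condition] = table
        write_gene_set({s.upper() for s in table.increased}, SCORED / f"increased_{condition}.txt")
        cond_truth = truth[truth["condition"] == condition]
        planted = set(cond_truth.loc[cond_truth["is_planted_hit"], "strain_id"]) & set(group["strain_id"])
        nulls = set(cond_truth.loc[~cond_truth["is_planted_hit"], "strain_id"]) & set(group["strain_id"])
        rows.append(
            {
                "condition": condition,
                "screened": table.n_screened,
                "increased": len(table.increased),
                "pct_increased": table.pct_increased(),
                "decreased": len(table.decreased),
                "recall_of_planted": round(len(table.increased & planted) / len(planted), 4),
                "zero_effect_called": round(len(table.increased & nulls) / len(nulls), 4),
                "mean_replicate_r": round(replicate_correlation(result.ratios)[condition]["mean"], 3),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "02_hit_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    conds = sorted(hit_tables)
    if len(conds) == 2:
        screened = [set(g["strain_id"]) for _, g in result.scores.groupby("condition")]
        overlaps = compare_conditions(hit_tables[conds[0]], hit_tables[conds[1]], set.intersection(*screened))
        inc = overlaps["increased"]
        print(
            f"\n{conds[0]} vs {conds[1]} increased: {inc.n_a} and {inc.n_b} hits, "
            f"{inc.n_intersection} shared, {inc.n_b_only} specific to {conds[1]} "
            f"(overlap p = {inc.p_value:.2e})"
        )
        pd.DataFrame(
            [
                {
                    "direction": d,
                    "n_a": s.n_a,
                    "n_b": s.n_b,
                    "n_intersection": s.n_intersection,
                    "n_union": s.n_union,
                    "p_value": s.p_value,
                }
                for d, s in overlaps.items()
            ]
        ).to_csv(RESULTS / "02_condition_overlap.tsv", sep="\t", index=False)


if __name__ == "__main__":
    sys.exit(main())
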