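# rsga — reporter-SGA genome-instability screen analysis

`rsga` analyzes colony-array fluorescence screens in which a DNA-damage
inducible reporter (such as Rnr3-GFP) is read out across thousands of
arrayed yeast mutants, together with a constitutive control fluorophore
(tdTomato) that corrects for colony size. It is written for functional
genomicists running reporter synthetic genetic array (R-SGA) screens:
from per-colony intensity tables to filtered, normalized per-mutant
scores, Z-score hit lists, GO term over-representation, and comparative
identification of putative novel genome-maintenance genes.

## The method

For each colony the reporter metric is the log ratio
`m = log2(GFP / tdTomato)`. Per replicate experiment:

1. **Filtering.** Border colonies, small colonies (area < 500 px,
   strict), colonies with a non-positive intensity, and the bottom 0.05%
   of tdTomato values (`ceil(q·n)` lowest, rank-based) are removed, in
   that order, with exact accounting (`removed + retained = input`).
2. **LOESS normalization.** Within each plate/replicate/condition, a
   local linear regression (tricube weights, span 0.3, no robustness
   iterations) of `m` on log2 tdTomato (or on row then column in spatial
   mode) is subtracted, and the residuals re-centered to median 0.
3. **Averaging and Z-scores.** Normalized values are averaged across all
   surviving replicate colonies of each strain, and per condition
   `z_i = (x_i − x̄) / s` with the sample SD over all strains. Mutants
   with `Z > 2` have increased reporter abundance (putative genome
   instability); `Z < −2` decreased.
4. **Enrichment.** GO over-representation by the upper-tail
   hypergeometric test `P(X ≥ k)`, `X ~ Hypergeom(N, K, n)`, per-aspect
   Benjamini-Hochberg FDR at 0.05, omitting terms with more than 2000
   annotated background genes (all aspects) or fewer than 10 (BP only).
5. **Comparative subtraction.** Hits present in none of a catalog of
   prior instability screens / repair–replication gene sets are the
   putative novel genes; an inParanoid-style ortholog table and human
   gene lists (γH2AX, Cancer Census) quantify conservation.

A synthetic screen generator (`rsga.simulate`) produces 1536-format
plates with planted hit effects, log-normal tdTomato, smooth spatial and
intensity-dependent biases, and dead colonies, so the whole chain is
testable against known ground truth.

## Worked example

```python
from rsga import SimConfig, simulate_screen, score_screen, call_hits, PipelineConfig

colonies, truth = simulate_screen(SimConfig(n_mutants=2000, seed=7))
result = score_screen(colonies)
for condition, group in result.scores.groupby("condition"):
    table = call_hits(group, PipelineConfig())
    print(condition, len(table.increased), f"{table.pct_increased()}%")
```

prints

```
MMS 92 4.6%
UT 93 4.6%
```

— with 5% of 2000 mutants planted as hits at +0.75 log2 units, ~92–93
strains per condition exceed Z = 2 (recall ≈ 0.98 of the planted hits;
the percentage is of all strains screened in that condition). The
numbered scripts under `analysis/` run the same pipeline at full scale
(5000 mutants, quadruplicate, two conditions) and write their tables
under `results/`; large intermediates go to `scratch/`:

```sh
python analysis/01_simulate_screen.py
python analysis/02_score_mutants.py
python analysis/03_go_enrichment.py
python analysis/04_comparative_analysis.py
```

A `rsga` command-line tool exposes the same stages
(`rsga simulate | score | enrich | compare | all`) with a YAML config
and provenance manifests.

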