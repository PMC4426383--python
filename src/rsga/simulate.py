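"""Synthetic colony-array screen generator with known ground truth.

Emulates a reporter-SGA screen of ~5000 mutant strains pinned in 1536
format (32 x 48 grids) in quadruplicate under two conditions, with a
constitutive control fluorophore (tdTomato) and a damage-responsive
reporter (GFP). The measurement model works on the log2(GFP/tdTomato)
scale, where the downstream pipeline operates:

    log2(GFP/td) = baseline + strain_dev + planted_effect
                   + spatial_surface(row, col) + intensity_bias(log2 td)
                   + noise

* tdTomato intensities are log-normal; GFP is derived from tdTomato and
  the ratio model, so colony size effects cancel exactly in the ratio.
* The spatial surface is a smooth low-order polynomial plus two Gaussian
  bumps, drawn independently for each physical plate (plate x replicate x
  condition), normalized to unit variance and scaled by the configured
  amplitude.
* The intensity bias is a smooth bounded function (tanh) of standardized
  log2 tdTomato, shared across plates.
* Dead colonies get near-zero tdTomato, inflated ratio noise (background
  subtraction dominates at low signal) and small areas, so the area and
  low-tdTomato filters have true positives to remove.
* The strain layout is fixed across replicates and conditions, as on real
  SGA arrays; border positions carry a control strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    AnnotationSet,
    write_colony_table,
    write_gaf,
    write_gene_set,
    write_ortholog_table,
)

#: Control strain occupying border and spare interior positions.
CONTROL_STRAIN_ID = "ctrl"
CONTROL_GENE = "CTRL"

# Dead-colony measurement model (log2 units / pixels).
DEAD_TD_LOG_OFFSET = -6.0
DEAD_RATIO_NOISE_SD = 1.0
DEAD_AREA_MEAN_PX = 250.0
DEAD_AREA_SD_PX = 100.0

TRUTH_COLUMNS = ["strain_id", "condition", "true_effect", "is_planted_hit"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic screen; defaults are the study conditions.

    All effect/noise magnitudes are in log2-ratio units. ``hit_effect_mean``
    defaults to 3 x ``baseline_log_ratio_sd`` so planted hits sit three
    per-colony noise SDs above baseline.
    """

    n_mutants: int = 5000
    plate_rows: int = 32
    plate_cols: int = 48
    n_replicates: int = 4
    conditions: tuple[str, ...] = ("UT", "MMS")
    baseline_log_ratio_mean: float = -2.0
    baseline_log_ratio_sd: float = 0.25
    strain_baseline_sd: float = 0.0
    hit_fraction: float = 0.05
    hit_effect_mean: float = 0.75
    hit_effect_sd: float = 0.0
    spatial_artifact_amplitude: float = 0.1
    intensity_bias_amplitude: float = 0.1
    dead_fraction: float = 0.01
    tdtomato_log_mean: float = 10.0
    tdtomato_log_sd: float = 0.5
    area_mean_px: float = 1500.0
    area_sd_px: float = 400.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_mutants": self.n_mutants,
            "plate_rows": self.plate_rows,
            "plate_cols": self.plate_cols,
            "n_replicates": self.n_replicates,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.plate_rows < 3 or self.plate_cols < 3:
            raise ConfigurationError(
                "plate_rows and plate_cols must be >= 3 to leave interior "
                f"positions inside the border, got {self.plate_rows}x{self.plate_cols}"
            )
        if not self.conditions or len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("conditions must be a non-empty list of unique labels")
        for name in ("hit_fraction", "dead_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name in (
            "baseline_log_ratio_sd",
            "strain_baseline_sd",
            "hit_effect_sd",
            "tdtomato_log_sd",
            "area_sd_px",
        ):
            value = getattr(self, name)
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        if self.area_mean_px <= 0:
            raise ConfigurationError(f"area_mean_px must be > 0, got {self.area_mean_px}")

    @property
    def interior_per_plate(self) -> int:
        return (self.plate_rows - 2) * (self.plate_cols - 2)

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_mutants / self.interior_per_plate)


@dataclass
class ScreenLayout:
    """Fixed strain-to-position assignment shared by replicates/conditions."""

    plate: np.ndarray  # 1-based plate index per position
    row: np.ndarray
    col: np.ndarray
    strain_idx: np.ndarray  # index into strain arrays, -1 for control
    strain_id: np.ndarray
    gene: np.ndarray
    is_border: np.ndarray


def _make_layout(config: SimConfig, genes: np.ndarray, strain_ids: np.ndarray) -> ScreenLayout:
    rows, cols = config.plate_rows, config.plate_cols
    n_plates = config.n_plates
    plate = np.repeat(np.arange(1, n_plates + 1), rows * cols)
    rr, cc = np.meshgrid(np.arange(1, rows + 1), np.arange(1, cols + 1), indexing="ij")
    row = np.tile(rr.ravel(), n_plates)
    col = np.tile(cc.ravel(), n_plates)
    border = (row == 1) | (row == rows) | (col == 1) | (col == cols)

    strain_idx = np.full(row.shape, -1, dtype=int)
    interior_positions = np.flatnonzero(~border)
    strain_idx[interior_positions[: config.n_mutants]] = np.arange(config.n_mutants)

    strain_id = np.where(strain_idx >= 0, strain_ids[np.clip(strain_idx, 0, None)], CONTROL_STRAIN_ID)
    gene = np.where(strain_idx >= 0, genes[np.clip(strain_idx, 0, None)], CONTROL_GENE)
    return ScreenLayout(plate, row, col, strain_idx, strain_id, gene, border)


def _spatial_surface(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """Smooth random surface on the grid, normalized to mean 0 and SD 1."""
    r = np.linspace(-1.0, 1.0, rows)[:, None]
    c = np.linspace(-1.0, 1.0, cols)[None, :]
    coef = rng.normal(size=5)
    surface = coef[0] * r + coef[1] * c + coef[2] * r * c + coef[3] * r**2 + coef[4] * c**2
    for _ in range(2):  # Gaussian bumps
        r0, c0 = rng.uniform(-1, 1, size=2)
        width = rng.uniform(0.3, 0.8)
        surface = surface + rng.normal() * np.exp(-(((r - r0) ** 2) + ((c - c0) ** 2)) / (2 * width**2))
    surface = surface - surface.mean()
    sd = surface.std()
    if sd > 0:
        surface = surface / sd
    return surface


def simulate_screen(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate colony records and the ground-truth effect table.

    Returns ``(colonies, truth)``: colonies with the canonical colony-table
    columns covering every grid position of every plate, replicate and
    condition; truth with one row per (mutant strain, condition) recording
    the planted log2 effect. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_mutants

    genes = np.array([f"YSG{i + 1:04d}" for i in range(n)])
    strain_ids = np.char.lower(genes)
    strain_dev = rng.normal(0.0, config.strain_baseline_sd, size=n) if config.strain_baseline_sd > 0 else np.zeros(n)

    # Planted effects, drawn independently per (strain, condition).
    truth_frames = []
    effects = {}
    for condition in config.conditions:
        is_hit = rng.random(n) < config.hit_fraction
        effect = np.zeros(n)
        effect[is_hit] = rng.normal(config.hit_effect_mean, config.hit_effect_sd, size=int(is_hit.sum()))
        effects[condition] = effect
        truth_frames.append(
            pd.DataFrame(
                {
                    "strain_id": strain_ids,
                    "condition": condition,
                    "true_effect": effect,
                    "is_planted_hit": is_hit,
                }
            )
        )
    truth = pd.concat(truth_frames, ignore_index=True)

    layout = _make_layout(config, genes, strain_ids)
    n_pos = layout.row.size
    rows, cols = config.plate_rows, config.plate_cols

    base_effect = np.zeros(n_pos)
    mutant_mask = layout.strain_idx >= 0
    frames = []
    for condition in config.conditions:
        cond_effect = base_effect.copy()
        cond_effect[mutant_mask] = (
            effects[condition][layout.strain_idx[mutant_mask]]
            + strain_dev[layout.strain_idx[mutant_mask]]
        )
        for replicate in range(1, config.n_replicates + 1):
            # Fresh physical plates: one artifact surface per plate instance.
            spatial = np.zeros(n_pos)
            if config.spatial_artifact_amplitude != 0:
                for p in range(config.n_plates):
                    surf = _spatial_surface(rng, rows, cols)
                    spatial[layout.plate == p + 1] = config.spatial_artifact_amplitude * surf.ravel()

            dead = rng.random(n_pos) < config.dead_fraction
            log2_td = rng.normal(config.tdtomato_log_mean, config.tdtomato_log_sd, size=n_pos)
            log2_td[dead] += DEAD_TD_LOG_OFFSET

            bias = np.zeros(n_pos)
            if config.intensity_bias_amplitude != 0 and config.tdtomato_log_sd > 0:
                z = (log2_td - config.tdtomato_log_mean) / config.tdtomato_log_sd
                bias = config.intensity_bias_amplitude * np.tanh(z)

            noise = rng.normal(0.0, config.baseline_log_ratio_sd, size=n_pos)
            noise[dead] += rng.normal(0.0, DEAD_RATIO_NOISE_SD, size=int(dead.sum()))

            log_ratio = config.baseline_log_ratio_mean + cond_effect + spatial + bias + noise
            tdtomato = np.exp2(log2_td)
            gfp = tdtomato * np.exp2(log_ratio)

            area = rng.normal(config.area_mean_px, config.area_sd_px, size=n_pos)
            area[dead] = rng.normal(DEAD_AREA_MEAN_PX, DEAD_AREA_SD_PX, size=int(dead.sum()))
            area = np.maximum(1, np.rint(area)).astype(int)

            frames.append(
                pd.DataFrame(
                    {
                        "plate": [f"p{p}" for p in layout.plate],
                        "condition": condition,
                        "replicate": replicate,
                        "row": layout.row,
                        "col": layout.col,
                        "strain_id": layout.strain_id,
                        "gene": layout.gene,
                        "gfp": gfp,
                        "tdtomato": tdtomato,
                        "area_px": area,
                    }
                )
            )
    colonies = pd.concat(frames, ignore_index=True)
    return colonies, truth


def _toy_references(
    config: SimConfig, genes: np.ndarray, truth: pd.DataFrame
) -> tuple[dict[str, set[str]], dict[str, set[str]], dict[str, set[str]], AnnotationSet]:
    """Deterministic toy reference catalog derived from the simulated genes.

    Synthetic stand-ins for the external resources the comparative stage
    consumes: prior-screen gene lists, human gene lists, an ortholog map
    and a small GO annotation set. Reference sets are enriched for planted
    hits so comparative analyses have signal.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(genes)
    first_cond = config.conditions[0]
    hit_genes = set(
        truth.loc[(truth["condition"] == first_cond) & truth["is_planted_hit"], "strain_id"]
        .str.upper()
        .tolist()
    )

    def sample_set(fraction: float, hit_enrichment: float = 3.0) -> set[str]:
        weight = np.where(np.isin(genes, sorted(hit_genes)), hit_enrichment, 1.0)
        prob = np.minimum(1.0, fraction * n * weight / weight.sum())
        chosen = set(genes[rng.random(n) < prob])
        if not chosen:  # tiny universes: keep every reference set non-empty
            chosen = {str(rng.choice(genes))}
        return chosen

    yeast_sets = {
        "mutator": sample_set(0.01),
        "ddc2_foci": sample_set(0.02),
        "rad52_foci": sample_set(0.02),
        "chromosome_instability": sample_set(0.12),
        "go_dna_repair": sample_set(0.04),
        "go_dna_replication": sample_set(0.03),
        "rnr_regulators": sample_set(0.003),
    }

    orthologs: dict[str, set[str]] = {}
    has_ortholog = rng.random(n) < 0.4
    for gene, flag in zip(genes, has_ortholog):
        if flag:
            orthologs[gene] = {f"HS_{gene}"}
            if rng.random() < 0.1:
                orthologs[gene].add(f"HS_{gene}B")
    human_universe = np.array(sorted({h for hs in orthologs.values() for h in hs}))
    human_sets = {
        "human_gamma_h2ax": set(human_universe[rng.random(human_universe.size) < 0.07]),
        "human_cancer_census": set(human_universe[rng.random(human_universe.size) < 0.02]),
    }

    annotations = AnnotationSet()
    n_terms = {"BP": 30, "MF": 10, "CC": 10}
    term_no = 0
    for aspect, count in n_terms.items():
        for _ in range(count):
            term_no += 1
            term = f"GO:{term_no:07d}"
            size = int(rng.integers(5, max(6, n // 10)))
            members = rng.choice(genes, size=min(size, n), replace=False)
            for gene in members:
                annotations.add(str(gene), term, aspect)
    return yeast_sets, human_sets, orthologs, annotations


def write_fixture_bundle(config: SimConfig, out_dir: str | Path) -> dict:
    """Simulate a screen and write every pipeline input under ``out_dir``.

    Writes one colony table per (plate, condition, replicate), the truth
    table, a toy GAF, toy reference gene lists and a toy ortholog table.
    Returns a manifest listing each file with its row count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    colonies, truth = simulate_screen(config)

    files: list[dict] = []

    def record(path: Path, rows: int) -> None:
        files.append({"path": str(path), "rows": int(rows)})

    for (plate, condition, replicate), group in colonies.groupby(
        ["plate", "condition", "replicate"], sort=True
    ):
        path = out_dir / f"colonies_{plate}_{condition}_r{replicate}.tsv"
        write_colony_table(group, path)
        record(path, len(group))

    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    record(truth_path, len(truth))

    genes = np.array(sorted(truth["strain_id"].str.upper().unique()))
    yeast_sets, human_sets, orthologs, annotations = _toy_references(config, genes, truth)
    for name, geneset in {**yeast_sets, **human_sets}.items():
        path = out_dir / f"{name}.txt"
        write_gene_set(geneset, path)
        record(path, len(geneset))
    ortho_path = out_dir / "orthologs.tsv"
    write_ortholog_table(orthologs, ortho_path)
    record(ortho_path, sum(len(v) for v in orthologs.values()))
    gaf_path = out_dir / "annotations.gaf"
    write_gaf(annotations, gaf_path)
    record(gaf_path, sum(len(v) for v in annotations.term_to_genes.values()))

    return {"seed": config.seed, "files": files}


def null_config(config: SimConfig) -> SimConfig:
    """The matched global-null configuration: no hits, no artifacts."""
    return replace(
        config,
        hit_fraction=0.0,
        spatial_artifact_amplitude=0.0,
        intensity_bias_amplitude=0.0,
        strain_baseline_sd=0.0,
    )
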