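"""From raw colony records to per-mutant normalized log-ratio Z-scores.

The stages mirror the screen's analysis recipe: optional background
handling, removal of border / small / low-tdTomato colonies, the
log2(GFP/tdTomato) ratio, LOESS normalization per replicate experiment,
replicate averaging and condition-wide Z-scores.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ConfigurationError, DataIntegrityError

logger = logging.getLogger(__name__)

_LOESS_MODES = ("intensity", "spatial", "none")
_BACKGROUND_METHODS = ("none", "plate_min", "control_quantile")
_SD_MODES = ("sample", "population")
_TDTOMATO_SCOPES = ("replicate", "plate", "global")

#: One physical plate scanned in one replicate of one condition.
PLATE_GROUP = ["plate", "condition", "replicate"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds and modes of the scoring pipeline.

    Defaults follow the screen's published filters: border colonies
    removed, colony area < 500 px removed (strict), bottom 0.05% of
    tdTomato removed, hits at |Z| > 2.
    """

    area_min_px: int = 500
    tdtomato_low_quantile: float = 0.0005
    border_depth: int = 1
    loess_mode: str = "intensity"
    loess_span: float = 0.3
    background_method: str = "none"
    z_hi: float = 2.0
    z_lo: float = -2.0
    sd_mode: str = "sample"
    positive_floor: float = 1e-9
    tdtomato_scope: str = "replicate"
    min_loess_group: int = 20
    control_strain: str = "ctrl"

    def validate(self) -> None:
        if self.area_min_px < 0:
            raise ConfigurationError(f"area_min_px must be >= 0, got {self.area_min_px}")
        if not 0.0 < self.tdtomato_low_quantile < 1.0:
            raise ConfigurationError(
                f"tdtomato_low_quantile must be in (0, 1), got {self.tdtomato_low_quantile}"
            )
        if self.border_depth < 0:
            raise ConfigurationError(f"border_depth must be >= 0, got {self.border_depth}")
        if self.loess_mode not in _LOESS_MODES:
            raise ConfigurationError(f"loess_mode must be one of {_LOESS_MODES}, got {self.loess_mode!r}")
        if not 0.0 < self.loess_span <= 1.0:
            raise ConfigurationError(f"loess_span must be in (0, 1], got {self.loess_span}")
        if self.background_method not in _BACKGROUND_METHODS:
            raise ConfigurationError(
                f"background_method must be one of {_BACKGROUND_METHODS}, got {self.background_method!r}"
            )
        if not self.z_hi > self.z_lo:
            raise ConfigurationError(f"z_hi ({self.z_hi}) must exceed z_lo ({self.z_lo})")
        if self.sd_mode not in _SD_MODES:
            raise ConfigurationError(f"sd_mode must be one of {_SD_MODES}, got {self.sd_mode!r}")
        if self.tdtomato_scope not in _TDTOMATO_SCOPES:
            raise ConfigurationError(
                f"tdtomato_scope must be one of {_TDTOMATO_SCOPES}, got {self.tdtomato_scope!r}"
            )


@dataclass
class FilterReport:
    """Accounting of colony filtering; removed + retained = input, always.

    A colony is attributed to the first rule that removed it, in rule
    order: border, small_area, nonpositive, low_tdtomato.
    """

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def check(self) -> None:
        if self.n_removed + self.n_retained != self.n_input:
            raise DataIntegrityError(
                f"filter accounting broken: {self.n_removed} removed + "
                f"{self.n_retained} retained != {self.n_input} input"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": rule, "removed": count} for rule, count in self.removed.items()]
        rows.append({"rule": "retained", "removed": self.n_retained})
        rows.append({"rule": "input", "removed": self.n_input})
        return pd.DataFrame(rows)


def subtract_background(records: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Optional per-plate background subtraction of both channels.

    ``none`` is the identity (input tables are assumed already
    background-subtracted, as in the screen); ``plate_min`` subtracts each
    plate's per-channel minimum; ``control_quantile`` subtracts the 1st
    percentile of control-strain intensities per plate. Colonies driven to
    a non-positive intensity are removed later by the nonpositive filter.
    """
    if config.background_method == "none":
        return records.copy()
    out = records.copy()
    if config.background_method == "plate_min":
        for channel in ("gfp", "tdtomato"):
            out[channel] = out[channel] - out.groupby(PLATE_GROUP)[channel].transform("min")
        return out
    # control_quantile
    controls = out[out["strain_id"] == config.control_strain]
    if controls.empty:
        raise ConfigurationError(
            "background_method 'control_quantile' requires control positions "
            f"(strain_id == {config.control_strain!r}), none found"
        )
    for channel in ("gfp", "tdtomato"):
        level = controls.groupby(PLATE_GROUP)[channel].quantile(0.01)
        missing = set(map(tuple, out[PLATE_GROUP].drop_duplicates().itertuples(index=False))) - set(level.index)
        if missing:
            raise ConfigurationError(
                f"background_method 'control_quantile': plates without controls: {sorted(missing)[:5]}"
            )
        out[channel] = out[channel] - out[PLATE_GROUP].apply(tuple, axis=1).map(level).to_numpy()
    return out


def filter_colonies(
    records: pd.DataFrame,
    grid_dims: tuple[int, int],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove border, small, non-positive and low-tdTomato colonies.

    * border: within ``border_depth`` positions of any plate edge;
    * small_area: ``area_px < area_min_px`` (strict, as published);
    * nonpositive: gfp or tdtomato <= ``positive_floor`` (cannot form a ratio);
    * low_tdtomato: among survivors of the prior rules, the
      ceil(quantile x n) colonies with smallest tdTomato, per
      ``tdtomato_scope`` group (default: per condition/replicate across
      plates), ties broken by input order.
    """
    config.validate()
    rows, cols = grid_dims
    if records["row"].max() > rows or records["col"].max() > cols:
        raise DataIntegrityError(
            f"grid dims {rows}x{cols} smaller than observed positions "
            f"({records['row'].max()}x{records['col'].max()})"
        )
    report = FilterReport(n_input=len(records))
    depth = config.border_depth
    border = (
        (records["row"] <= depth)
        | (records["row"] > rows - depth)
        | (records["col"] <= depth)
        | (records["col"] > cols - depth)
    )
    small = ~border & (records["area_px"] < config.area_min_px)
    nonpos = (
        ~border
        & ~small
        & ((records["gfp"] <= config.positive_floor) | (records["tdtomato"] <= config.positive_floor))
    )
    survivors = ~(border | small | nonpos)

    low_td = pd.Series(False, index=records.index)
    if config.tdtomato_scope == "replicate":
        group_cols = ["condition", "replicate"]
    elif config.tdtomato_scope == "plate":
        group_cols = ["plate", "condition", "replicate"]
    else:
        group_cols = []
    surviving = records[survivors]
    groups = surviving.groupby(group_cols, sort=False) if group_cols else [(None, surviving)]
    for _, group in groups:
        k = math.ceil(config.tdtomato_low_quantile * len(group))
        if k > 0:
            order = np.argsort(group["tdtomato"].to_numpy(), kind="stable")
            low_td.loc[group.index[order[:k]]] = True

    report.removed = {
        "border": int(border.sum()),
        "small_area": int(small.sum()),
        "nonpositive": int(nonpos.sum()),
        "low_tdtomato": int(low_td.sum()),
    }
    kept = records[survivors & ~low_td].copy()
    report.n_retained = len(kept)
    report.check()
    logger.info(
        "filtered %d/%d colonies (%s)",
        report.n_removed,
        report.n_input,
        ", ".join(f"{k}={v}" for k, v in report.removed.items()),
    )
    return kept, report


def compute_log_ratio(records: pd.DataFrame) -> pd.DataFrame:
    """Attach log_ratio = log2(gfp/tdtomato); the reporter abundance metric.

    ``normalized_log_ratio`` starts equal to ``log_ratio`` and is replaced
    by :func:`loess_normalize`.
    """
    if ((records["gfp"] <= 0) | (records["tdtomato"] <= 0)).any():
        raise DataIntegrityError(
            "non-positive intensity reached compute_log_ratio; filter contract violated"
        )
    out = records.copy()
    out["log_ratio"] = np.log2(out["gfp"] / out["tdtomato"])
    out["normalized_log_ratio"] = out["log_ratio"]
    return out


def _lowess_fit(y: np.ndarray, x: np.ndarray, span: float) -> np.ndarray:
    if np.unique(x).size < 2:
        return np.full_like(y, y.mean())
    fitted = lowess(y, x, frac=span, it=0, xvals=x)
    return np.asarray(fitted)


def loess_normalize(ratios: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """LOESS-normalize log-ratios within each plate/replicate/condition.

    ``intensity`` mode (default) fits local linear regression of the
    log-ratio on log2 tdTomato (MA-style, removing intensity-dependent
    trends); ``spatial`` mode applies separable row-then-column passes;
    ``none`` is the identity. Each normalized group is re-centered to
    median 0. Groups smaller than ``min_loess_group`` are passed through
    unchanged with a warning and ``loess_applied = False``.
    """
    config.validate()
    out = ratios.copy()
    if config.loess_mode == "none":
        out["loess_applied"] = False
        return out
    out["loess_applied"] = True
    normalized = out["log_ratio"].to_numpy(dtype=float).copy()
    for key, group in out.groupby(PLATE_GROUP, sort=False):
        idx = out.index.get_indexer(group.index)
        y = group["log_ratio"].to_numpy(dtype=float)
        if len(group) < config.min_loess_group:
            warnings.warn(
                f"group {key}: {len(group)} colonies < {config.min_loess_group}; "
                "LOESS skipped, values passed through",
                stacklevel=2,
            )
            out.loc[group.index, "loess_applied"] = False
            continue
        if config.loess_mode == "intensity":
            x = np.log2(group["tdtomato"].to_numpy(dtype=float))
            resid = y - _lowess_fit(y, x, config.loess_span)
        else:  # spatial: separable row then column pass
            resid = y - _lowess_fit(y, group["row"].to_numpy(dtype=float), config.loess_span)
            resid = resid - _lowess_fit(resid, group["col"].to_numpy(dtype=float), config.loess_span)
        resid = resid - np.median(resid)
        normalized[idx] = resid
    out["normalized_log_ratio"] = normalized
    return out


def average_replicates(
    ratios: pd.DataFrame, universe: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average normalized log-ratios over surviving replicate colonies.

    Strains pinned at multiple positions contribute each surviving colony
    as an extra replicate. ``universe`` (optional, columns strain_id /
    gene / condition, e.g. the pre-filter records) defines which strains
    are expected; expected strains with zero surviving colonies are
    returned in the missing table, never imputed.
    """
    means = (
        ratios.groupby(["strain_id", "gene", "condition"], sort=True)["normalized_log_ratio"]
        .agg(mean_normalized_log_ratio="mean", n_replicates="size")
        .reset_index()
    )
    if universe is not None:
        expected = universe[["strain_id", "gene", "condition"]].drop_duplicates()
        merged = expected.merge(
            means[["strain_id", "condition"]], on=["strain_id", "condition"], how="left", indicator=True
        )
        missing = merged[merged["_merge"] == "left_only"].drop(columns="_merge").reset_index(drop=True)
    else:
        missing = means.iloc[0:0][["strain_id", "gene", "condition"]]
    if len(missing):
        logger.info("%d strain/condition pairs lost to filtering", len(missing))
    return means, missing


def compute_zscores(means: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Condition-wide Z-scores of the per-strain mean normalized log-ratio.

    z = (mean_i - grand mean) / SD across all strains of the condition;
    the SD estimator follows ``sd_mode`` (default: sample, n-1).
    Location-invariant: adding a constant to every mean leaves z unchanged.
    """
    config.validate()
    ddof = 1 if config.sd_mode == "sample" else 0
    out = means.copy()
    zs = np.empty(len(out))
    for condition, group in out.groupby("condition", sort=False):
        values = group["mean_normalized_log_ratio"].to_numpy(dtype=float)
        if len(values) < 3:
            raise DataIntegrityError(
                f"condition {condition!r}: need >= 3 strains for Z-scores, got {len(values)}"
            )
        sd = values.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise DataIntegrityError(f"condition {condition!r}: degenerate score distribution (SD=0)")
        zs[out.index.get_indexer(group.index)] = (values - values.mean()) / sd
    out["z"] = zs
    return out


def replicate_correlation(ratios: pd.DataFrame) -> dict[str, dict]:
    """Pairwise Pearson correlations of normalized log-ratios per condition.

    Strain-level values (colonies averaged within replicate) are compared
    between each replicate pair over the strains present in both; returns
    per condition a replicate x replicate matrix and the mean off-diagonal
    correlation.
    """
    results: dict[str, dict] = {}
    for condition, group in ratios.groupby("condition", sort=True):
        wide = group.pivot_table(
            index="strain_id", columns="replicate", values="normalized_log_ratio", aggfunc="mean"
        )
        reps = list(wide.columns)
        if len(reps) < 2:
            raise DataIntegrityError(f"condition {condition!r}: need >= 2 replicates")
        matrix = pd.DataFrame(np.eye(len(reps)), index=reps, columns=reps)
        pair_rs = []
        for i, a in enumerate(reps):
            for b in reps[i + 1 :]:
                shared = wide[[a, b]].dropna()
                if len(shared) < 2:
                    raise DataIntegrityError(
                        f"condition {condition!r}: replicates {a} and {b} share "
                        f"only {len(shared)} strains"
                    )
                r = float(np.corrcoef(shared[a], shared[b])[0, 1])
                matrix.loc[a, b] = matrix.loc[b, a] = r
                pair_rs.append(r)
        results[condition] = {"matrix": matrix, "mean": float(np.mean(pair_rs))}
    return results


@dataclass
class ScreenScores:
    """Everything the scoring pipeline produces for one screen."""

    ratios: pd.DataFrame
    scores: pd.DataFrame
    filter_report: FilterReport
    missing: pd.DataFrame


def score_screen(
    records: pd.DataFrame,
    grid_dims: tuple[int, int] | None = None,
    config: PipelineConfig | None = None,
) -> ScreenScores:
    """Run the full scoring chain on raw colony records.

    background -> filters -> log-ratio -> LOESS -> replicate average ->
    Z-scores. ``grid_dims`` defaults to the largest observed (row, col).
    """
    config = config or PipelineConfig()
    config.validate()
    if grid_dims is None:
        grid_dims = (int(records["row"].max()), int(records["col"].max()))
    records = subtract_background(records, config)
    kept, report = filter_colonies(records, grid_dims, config)
    ratios = compute_log_ratio(kept)
    ratios = loess_normalize(ratios, config)
    means, missing = average_replicates(ratios, universe=records)
    scores = compute_zscores(means, config)
    return ScreenScores(ratios=ratios, scores=scores, filter_report=report, missing=missing)
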