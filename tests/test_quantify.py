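"""Scoring pipeline stages: filters, ratios, LOESS, averaging, Z-scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsga import (
    ConfigurationError,
    DataIntegrityError,
    PipelineConfig,
    average_replicates,
    compute_log_ratio,
    compute_zscores,
    filter_colonies,
    loess_normalize,
    replicate_correlation,
    subtract_background,
)
from conftest import one_plate_frame


def _frame(**overrides) -> pd.DataFrame:
    base = {
        "plate": "p1",
        "condition": "UT",
        "replicate": 1,
        "row": 2,
        "col": 2,
        "strain_id": "s",
        "gene": "G",
        "gfp": 100.0,
        "tdtomato": 50.0,
        "area_px": 1000,
    }
    sizes = [len(v) for v in overrides.values() if hasattr(v, "__len__") and not isinstance(v, str)]
    n = max(sizes) if sizes else 1
    data = {}
    for key, value in {**base, **overrides}.items():
        if hasattr(value, "__len__") and not isinstance(value, str):
            data[key] = list(value)
        else:
            data[key] = [value] * n
    return pd.DataFrame(data)


# ---------------------------------------------------------------- background

def test_background_none_identity():
    records = _frame(gfp=[10.0, 20.0, 30.0])
    out = subtract_background(records, PipelineConfig(background_method="none"))
    pd.testing.assert_frame_equal(out, records)


def test_background_plate_min():
    records = _frame(gfp=[10.0, 20.0, 30.0], tdtomato=[5.0, 6.0, 7.0], col=[2, 3, 4])
    out = subtract_background(records, PipelineConfig(background_method="plate_min"))
    assert list(out["gfp"]) == [0.0, 10.0, 20.0]
    # the minimum colony becomes non-positive and is removed downstream
    kept, report = filter_colonies(out, (8, 12), PipelineConfig(background_method="plate_min"))
    assert report.removed["nonpositive"] == 1


def test_background_all_equal_degenerate():
    records = _frame(gfp=[10.0, 10.0, 10.0], tdtomato=[10.0, 10.0, 10.0], col=[2, 3, 4])
    out = subtract_background(records, PipelineConfig(background_method="plate_min"))
    _, report = filter_colonies(out, (8, 12), PipelineConfig())
    assert report.removed["nonpositive"] == 3


def test_background_control_quantile_requires_controls():
    records = _frame(gfp=[10.0, 20.0], col=[2, 3], strain_id=["a", "b"])
    with pytest.raises(ConfigurationError, match="control"):
        subtract_background(records, PipelineConfig(background_method="control_quantile"))


# ------------------------------------------------------------------- filters

def test_border_count_32x48():
    """Depth-1 border of a 32x48 grid is the 156-colony perimeter."""
    records = one_plate_frame(np.zeros(32 * 48))
    _, report = filter_colonies(records, (32, 48), PipelineConfig())
    assert report.removed["border"] == 2 * (32 + 48) - 4 == 156
    report.check()


def test_area_threshold_strict():
    records = _frame(area_px=[499, 500, 501], tdtomato=[50.0, 60.0, 40.0], col=[2, 3, 4])
    kept, report = filter_colonies(records, (8, 12), PipelineConfig())
    assert report.removed["small_area"] == 1  # 499 < 500 is strict
    assert 500 in set(kept["area_px"])  # area exactly 500 survives the area rule
    # ceil(q * 2 survivors) = 1: the lowest-tdTomato survivor (501) goes too
    assert report.removed["low_tdtomato"] == 1
    assert set(kept["area_px"]) == {500}


def test_low_tdtomato_ceiling():
    """2000 survivors at quantile 0.0005 remove exactly ceil(1.0)=1 colony."""
    rng = np.random.default_rng(0)
    records = one_plate_frame(np.zeros(2000), rows=40, cols=50)
    records["row"] = np.repeat(np.arange(2, 42), 50)  # keep off the border
    records["col"] = np.tile(np.arange(2, 52), 40)
    records["tdtomato"] = rng.uniform(100, 200, 2000)
    records["gfp"] = records["tdtomato"]
    kept, report = filter_colonies(records, (50, 60), PipelineConfig())
    assert report.removed == {"border": 0, "small_area": 0, "nonpositive": 0, "low_tdtomato": 1}
    assert records.loc[records["tdtomato"].idxmin(), "strain_id"] not in set(kept["strain_id"])


def test_low_tdtomato_ties_input_order():
    records = _frame(tdtomato=[1.0, 1.0, 5.0, 5.0], col=[2, 3, 4, 5], strain_id=list("abcd"))
    cfg = PipelineConfig(tdtomato_low_quantile=0.25)
    kept, report = filter_colonies(records, (8, 12), cfg)
    assert report.removed["low_tdtomato"] == 1
    assert "a" not in set(kept["strain_id"])  # first of the tied pair


def test_grid_dims_too_small():
    records = _frame(row=10)
    with pytest.raises(DataIntegrityError, match="grid"):
        filter_colonies(records, (8, 12), PipelineConfig())


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.integers(1, 20), st.integers(1, 20), st.integers(0, 2000), st.floats(1, 1e4)), min_size=1, max_size=60))
def test_filter_conservation_property(colonies):
    rows = pd.DataFrame(
        {
            "plate": "p1",
            "condition": "UT",
            "replicate": 1,
            "row": [r for r, _, _, _ in colonies],
            "col": [c for _, c, _, _ in colonies],
            "strain_id": [f"s{i}" for i in range(len(colonies))],
            "gene": [f"G{i}" for i in range(len(colonies))],
            "gfp": [t for _, _, _, t in colonies],
            "tdtomato": [t for _, _, _, t in colonies],
            "area_px": [a for _, _, a, _ in colonies],
        }
    )
    kept, report = filter_colonies(rows, (20, 20), PipelineConfig())
    report.check()
    assert report.n_retained == len(kept)
    assert report.n_input == len(rows)


# -------------------------------------------------------------------- ratios

@pytest.mark.parametrize("gfp, tdtomato, expected", [(50.0, 50.0, 0.0), (200.0, 50.0, 2.0), (25.0, 50.0, -1.0)])
def test_log_ratio_values(gfp, tdtomato, expected):
    out = compute_log_ratio(_frame(gfp=gfp, tdtomato=tdtomato))
    assert out["log_ratio"].iloc[0] == pytest.approx(expected, abs=1e-12)
    assert (out["normalized_log_ratio"] == out["log_ratio"]).all()


def test_log_ratio_rejects_nonpositive():
    with pytest.raises(DataIntegrityError, match="filter contract"):
        compute_log_ratio(_frame(gfp=0.0))


# --------------------------------------------------------------------- LOESS

def test_loess_linear_signal_removed_exactly():
    """Local linear regression reproduces a globally linear trend."""
    rng = np.random.default_rng(1)
    td = np.exp2(rng.normal(10, 0.5, 500))
    y = -2.0 + 0.4 * np.log2(td)
    records = _frame(
        gfp=td * np.exp2(y), tdtomato=td, col=np.tile(np.arange(2, 12), 50), row=np.repeat(np.arange(2, 52), 10)
    )
    ratios = compute_log_ratio(records)
    out = loess_normalize(ratios, PipelineConfig(loess_mode="intensity"))
    assert np.abs(out["normalized_log_ratio"]).max() < 1e-8
    assert out["loess_applied"].all()


def test_loess_constant_absorbed():
    records = one_plate_frame(np.full(32 * 48, 1.7))
    records["tdtomato"] = np.exp2(np.random.default_rng(2).normal(10, 0.5, len(records)))
    records["gfp"] = records["tdtomato"] * 2.0**1.7
    out = loess_normalize(compute_log_ratio(records), PipelineConfig())
    assert np.abs(out["normalized_log_ratio"]).max() < 1e-10


def test_loess_spatial_sinusoid_removed():
    """A planted sinusoidal plate surface decorrelates after spatial LOESS."""
    rng = np.random.default_rng(42)
    rr, cc = np.meshgrid(np.arange(1, 33), np.arange(1, 49), indexing="ij")
    artifact = 0.5 * np.sin(2 * np.pi * rr / 32) + 0.5 * np.sin(2 * np.pi * cc / 48)
    y = -2.0 + artifact.ravel() + rng.normal(0, 0.1, 1536)
    records = one_plate_frame(y)
    out = loess_normalize(compute_log_ratio(records), PipelineConfig(loess_mode="spatial", loess_span=0.1))
    r = np.corrcoef(out["normalized_log_ratio"], artifact.ravel())[0, 1]
    assert abs(r) < 0.05


def test_loess_small_group_passed_through():
    records = _frame(gfp=np.linspace(10, 20, 5), col=np.arange(2, 7))
    ratios = compute_log_ratio(records)
    with pytest.warns(UserWarning, match="LOESS skipped"):
        out = loess_normalize(ratios, PipelineConfig())
    assert not out["loess_applied"].any()
    assert (out["normalized_log_ratio"] == out["log_ratio"]).all()


def test_loess_none_identity():
    ratios = compute_log_ratio(_frame(gfp=[10.0, 30.0], col=[2, 3]))
    out = loess_normalize(ratios, PipelineConfig(loess_mode="none"))
    assert (out["normalized_log_ratio"] == out["log_ratio"]).all()


def test_loess_median_recentering_and_count():
    rng = np.random.default_rng(3)
    records = one_plate_frame(rng.normal(-2, 0.3, 1536))
    records["tdtomato"] = np.exp2(rng.normal(10, 0.5, 1536))
    records["gfp"] = records["tdtomato"] * np.exp2(rng.normal(-2, 0.3, 1536))
    out = loess_normalize(compute_log_ratio(records), PipelineConfig())
    assert len(out) == 1536  # record count preserved
    assert abs(np.median(out["normalized_log_ratio"])) < 1e-6


# ----------------------------------------------------------------- averaging

def test_average_replicates():
    ratios = _frame(gfp=[100.0, 400.0], tdtomato=[50.0, 50.0], replicate=[1, 2])
    ratios = compute_log_ratio(ratios)
    means, missing = average_replicates(ratios)
    assert means["mean_normalized_log_ratio"].iloc[0] == pytest.approx((1.0 + 3.0) / 2)
    assert means["n_replicates"].iloc[0] == 2
    assert missing.empty


def test_average_single_replicate_and_missing():
    records = _frame(strain_id=["a", "b"], gene=["A", "B"], col=[2, 3])
    ratios = compute_log_ratio(records[records["strain_id"] == "a"])
    means, missing = average_replicates(ratios, universe=records)
    assert list(means["strain_id"]) == ["a"]
    assert means["n_replicates"].iloc[0] == 1
    assert list(missing["strain_id"]) == ["b"]


# ------------------------------------------------------------------ Z-scores

def test_zscore_textbook_vector():
    means = pd.DataFrame(
        {
            "strain_id": list("abcde"),
            "gene": list("ABCDE"),
            "condition": "UT",
            "mean_normalized_log_ratio": [1.0, 2.0, 3.0, 4.0, 5.0],
            "n_replicates": 4,
        }
    )
    out = compute_zscores(means, PipelineConfig())
    expected = [-1.2649, -0.6325, 0.0, 0.6325, 1.2649]
    assert out["z"].to_numpy() == pytest.approx(expected, abs=5e-5)


def test_zscore_location_invariance_and_moments():
    rng = np.random.default_rng(4)
    means = pd.DataFrame(
        {
            "strain_id": [f"s{i}" for i in range(200)],
            "gene": [f"G{i}" for i in range(200)],
            "condition": "UT",
            "mean_normalized_log_ratio": rng.normal(size=200),
            "n_replicates": 4,
        }
    )
    out = compute_zscores(means, PipelineConfig())
    shifted = means.assign(mean_normalized_log_ratio=means["mean_normalized_log_ratio"] + 10)
    out2 = compute_zscores(shifted, PipelineConfig())
    assert out["z"].to_numpy() == pytest.approx(out2["z"].to_numpy(), abs=1e-9)
    assert abs(out["z"].mean()) < 1e-10
    assert abs(out["z"].std(ddof=1) - 1) < 1e-10


def test_zscore_degenerate_sd():
    means = pd.DataFrame(
        {
            "strain_id": list("abc"),
            "gene": list("ABC"),
            "condition": "UT",
            "mean_normalized_log_ratio": [1.0, 1.0, 1.0],
            "n_replicates": 1,
        }
    )
    with pytest.raises(DataIntegrityError, match="degenerate"):
        compute_zscores(means, PipelineConfig())


# -------------------------------------------------------------- correlations

def _ratio_pair(values_a, values_b):
    n = len(values_a)
    frames = []
    for rep, values in ((1, values_a), (2, values_b)):
        frames.append(
            pd.DataFrame(
                {
                    "plate": "p1",
                    "condition": "UT",
                    "replicate": rep,
                    "row": 2,
                    "col": np.arange(2, 2 + n),
                    "strain_id": [f"s{i}" for i in range(n)],
                    "gene": [f"G{i}" for i in range(n)],
                    "normalized_log_ratio": values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def test_replicate_correlation_examples():
    same = _ratio_pair([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert replicate_correlation(same)["UT"]["mean"] == pytest.approx(1.0)
    neg = _ratio_pair([1.0, 2.0, 3.0], [-1.0, -2.0, -3.0])
    assert replicate_correlation(neg)["UT"]["mean"] == pytest.approx(-1.0)
    close = _ratio_pair([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
    assert replicate_correlation(close)["UT"]["mean"] == pytest.approx(0.9820, abs=5e-5)


def test_replicate_correlation_insufficient():
    one = _ratio_pair([1.0], [2.0])
    with pytest.raises(DataIntegrityError, match="share"):
        replicate_correlation(one)


def test_replicate_correlation_brackets_reported_range():
    """With realistic strain-to-strain spread the simulated replicate
    correlations land in the 0.73-0.95 band reported for real screens."""
    from rsga import SimConfig, simulate_screen, score_screen

    cfg = SimConfig(n_mutants=1000, n_replicates=2, conditions=("UT",), strain_baseline_sd=0.5, seed=3)
    colonies, _ = simulate_screen(cfg)
    result = score_screen(colonies)
    mean_r = replicate_correlation(result.ratios)["UT"]["mean"]
    assert 0.73 <= mean_r <= 0.95
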