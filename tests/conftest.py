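import numpy as np
import pandas as pd
import pytest

from rsga import SimConfig, simulate_screen


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """96-format plate, 20 mutants, 2 replicates: fast structural checks."""
    return SimConfig(
        n_mutants=20,
        plate_rows=8,
        plate_cols=12,
        n_replicates=2,
        dead_fraction=0.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_screen(tiny_config):
    return simulate_screen(tiny_config)


@pytest.fixture(scope="session")
def bundle_dir(tiny_config, tmp_path_factory):
    from rsga import write_fixture_bundle

    out = tmp_path_factory.mktemp("bundle")
    manifest = write_fixture_bundle(tiny_config, out)
    return out, manifest


def one_plate_frame(values: np.ndarray, rows: int = 32, cols: int = 48) -> pd.DataFrame:
    """Colony table for a single plate from an array of log2 ratios."""
    rr, cc = np.meshgrid(np.arange(1, rows + 1), np.arange(1, cols + 1), indexing="ij")
    values = np.asarray(values, dtype=float).ravel()
    return pd.DataFrame(
        {
            "plate": "p1",
            "condition": "UT",
            "replicate": 1,
            "row": rr.ravel(),
            "col": cc.ravel(),
            "strain_id": [f"s{i}" for i in range(values.size)],
            "gene": [f"G{i}" for i in range(values.size)],
            "gfp": np.exp2(values),
            "tdtomato": 1.0,
            "area_px": 1000,
        }
    )
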