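"""Shared fixtures: the reference synthetic dataset and trained maps are
built once per session because several test modules exercise them."""

import warnings

import numpy as np
import pandas as pd
import pytest

from geosomtrack import pipeline, simulate


@pytest.fixture(scope="session")
def reference():
    """Fixed-seed reference dataset (fixes, habitat map, temperatures, truth)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate.reference_dataset()


@pytest.fixture(scope="session")
def reference_features(reference):
    fixes, hmap, temps, _ = reference
    config = pipeline.PipelineConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        feat, log = pipeline.build_feature_table(fixes, hmap, temps, config)
    return feat, log, config


@pytest.fixture(scope="session")
def trained_maps(reference_features):
    """Geo-SOM trainings (female-target, male-target, pooled) at defaults."""
    feat, _, config = reference_features
    maps = {}
    for target in ("F", "M", "all"):
        trained, norm, samples, rows, qe = pipeline.train_map(
            feat, config, target)
        maps[target] = {"grid": trained, "norm": norm, "samples": samples,
                        "rows": rows, "qe": qe}
    return maps, config


def make_fixes(rows):
    """Tiny fix-table builder: rows of (id, sex, iso_time, x, y)."""
    df = pd.DataFrame(rows, columns=["individual_id", "sex", "timestamp",
                                     "x", "y"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="mixed")
    df["survey_round"] = (((df["timestamp"].dt.month - 10) % 12) + 1).astype(int)
    return df.sort_values(["individual_id", "timestamp"]).reset_index(drop=True)


@pytest.fixture
def tiny_fixes():
    return make_fixes([
        ("F1", "F", "2015-10-05 00:00", 0.0, 0.0),
        ("F1", "F", "2015-10-05 01:00", 30.0, 40.0),
        ("F1", "F", "2015-10-05 02:00", 60.0, 80.0),
        ("M1", "M", "2015-10-05 00:00", 100.0, 0.0),
        ("M1", "M", "2015-10-05 01:00", 130.0, 40.0),
        ("M1", "M", "2015-10-05 02:00", 160.0, 80.0),
    ])
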