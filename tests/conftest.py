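"""Shared fixtures and dataset builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from obecart.core import ClassSpec, FeatureSchema, OrdinalDataset

# one deterministic hypothesis profile for the whole suite
settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

FOUR_CLASSES = ("not absent", "hours", "days", "weeks")


@pytest.fixture
def four_spec() -> ClassSpec:
    return ClassSpec(FOUR_CLASSES)


def build_dataset(
    columns: dict[str, list],
    y,
    class_spec: ClassSpec | None = None,
    categorical: set[str] | None = None,
) -> OrdinalDataset:
    """Construct an OrdinalDataset from plain columns.

    Columns whose values are all numbers become numeric features unless
    named in *categorical*; everything else becomes categorical with the
    observed values as the category set.
    """
    class_spec = class_spec or ClassSpec(FOUR_CLASSES)
    categorical = categorical or set()
    schema = []
    X = pd.DataFrame()
    for name, vals in columns.items():
        numeric = name not in categorical and all(
            isinstance(v, (int, float, np.integer, np.floating)) for v in vals
        )
        if numeric:
            schema.append(FeatureSchema(name, "numeric"))
            X[name] = np.asarray(vals, dtype=float)
        else:
            cats = tuple(sorted({str(v) for v in vals}))
            schema.append(FeatureSchema(name, "categorical", cats))
            X[name] = [str(v) for v in vals]
    return OrdinalDataset(tuple(schema), X, np.asarray(y, dtype=np.int64), class_spec)


def random_mixed_dataset(
    seed: int,
    T: int,
    n_classes: int = 4,
    n_numeric: int = 2,
    n_categorical: int = 2,
    value_grid: int = 0,
) -> OrdinalDataset:
    """Random mixed-type dataset with class labels loosely tied to x0.

    ``value_grid > 0`` rounds numeric values onto that many distinct
    levels, which keeps candidate-split counts (and fitted trees) small.
    """
    rng = np.random.default_rng(seed)
    cols: dict[str, list] = {}
    for j in range(n_numeric):
        v = rng.random(T)
        if value_grid:
            v = np.round(v * value_grid) / value_grid
        cols[f"x{j}"] = list(v)
    for j in range(n_categorical):
        cats = ["a", "b", "c"][: rng.integers(2, 4)]
        cols[f"c{j}"] = [cats[i] for i in rng.integers(0, len(cats), T)]
    # class depends on x0 plus noise so trees have something to learn
    base = np.clip(
        (np.asarray(cols["x0"]) * n_classes).astype(int) + rng.integers(-1, 2, T),
        0,
        n_classes - 1,
    )
    labels = tuple(f"k{i}" for i in range(1, n_classes + 1))
    return build_dataset(
        cols,
        base + 1,
        class_spec=ClassSpec(labels),
        categorical={f"c{j}" for j in range(n_categorical)},
    )
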