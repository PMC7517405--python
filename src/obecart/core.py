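"""Domain types and file I/O for ordinal-outcome tabular data.

The central container is :class:`OrdinalDataset`: a table of mixed
numeric/categorical features plus one ordered class label per row.  The
ordered classes ``c_1 < ... < c_n`` carry integer values ``V(c_i) = i``,
so the distance between two classes is well defined -- the entropy and
tree modules build on that.

File formats are deliberately plain: RFC-4180-style CSV with a header row
for data, JSON for the column schema and for fitted tree models.  Data
files store class *labels*, never indices, so files stay meaningful if the
class ordering is ever revised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NUMERIC = "numeric"
CATEGORICAL = "categorical"


class ValidationError(ValueError):
    """Raised when data, schema or model files violate their contract.

    The message names the offending row/column or file location so the
    problem can be fixed at the source rather than silently imputed.
    """


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassSpec:
    """The ordered class set c_1 < ... < c_n with values V(c_i) = i.

    Parameters
    ----------
    labels
        Class names in increasing order of the quantity they encode,
        e.g. ``("not absent", "hours", "days", "weeks")``.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(self.labels) < 2:
            raise ValidationError("a class spec needs at least 2 classes")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("class labels must be unique")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def values(self) -> tuple[int, ...]:
        """Integer class values V(c_i) = i, 1-based."""
        return tuple(range(1, self.n + 1))

    def index_of(self, label: str) -> int:
        """1-based class index of *label*."""
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise ValidationError(
                f"unknown class label {label!r}; expected one of {self.labels}"
            ) from None


@dataclass(frozen=True)
class FeatureSchema:
    """Declaration of a single feature column."""

    name: str
    kind: str
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (NUMERIC, CATEGORICAL):
            raise ValidationError(
                f"feature {self.name!r}: kind must be 'numeric' or 'categorical', "
                f"got {self.kind!r}"
            )
        if self.kind == CATEGORICAL:
            if not self.categories:
                raise ValidationError(
                    f"categorical feature {self.name!r} must list >= 1 category"
                )
            object.__setattr__(
                self, "categories", tuple(str(c) for c in self.categories)
            )
            if len(set(self.categories)) != len(self.categories):
                raise ValidationError(
                    f"feature {self.name!r}: duplicate categories"
                )
        elif self.categories is not None:
            raise ValidationError(
                f"numeric feature {self.name!r} must not list categories"
            )


@dataclass
class ClassDistribution:
    """A probability vector over the n classes plus its sample support."""

    probs: np.ndarray
    support: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.support = int(self.support)
        if self.probs.ndim != 1:
            raise ValidationError("probs must be a 1-d vector")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValidationError("probabilities must lie in [0, 1]")
        total = float(self.probs.sum())
        if self.support == 0:
            if total > 1e-9:
                raise ValidationError("support 0 requires an all-zero vector")
        elif abs(total - 1.0) > 1e-9:
            raise ValidationError(f"probabilities sum to {total}, not 1")

    @classmethod
    def from_counts(cls, counts: Sequence[float]) -> "ClassDistribution":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total == 0:
            return cls(np.zeros_like(counts), 0)
        return cls(counts / total, int(round(total)))

    def counts(self) -> np.ndarray:
        """Integer class counts implied by probs * support.

        Rounding error (at most one count) is absorbed by the largest class
        so the counts always sum to ``support``.
        """
        c = np.rint(self.probs * self.support).astype(int)
        diff = self.support - int(c.sum())
        if diff != 0:
            c[int(np.argmax(c))] += diff
        return c

    @property
    def n(self) -> int:
        return len(self.probs)


@dataclass
class TreeNode:
    """One node of a fitted binary tree.

    Every node carries the class distribution and support of the training
    rows that reached it.  Internal nodes additionally hold the split
    condition (numeric ``value <= threshold`` or categorical
    ``value == category``; the condition being *true* routes left) and the
    information gain the split achieved.  Leaves hold the predicted class.
    """

    distribution: ClassDistribution
    support: int
    # split fields
    feature: str | None = None
    kind: str | None = None
    threshold: float | None = None
    category: str | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    gain: float | None = None
    # leaf field
    predicted: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def condition_str(self) -> str:
        if self.is_leaf:
            return "<leaf>"
        if self.kind == NUMERIC:
            return f"{self.feature} <= {self.threshold:g}"
        return f"{self.feature} = {self.category}"


@dataclass
class OrdinalTreeModel:
    """A fitted ordinal CART: root node, training config and class spec."""

    root: TreeNode
    config: dict
    class_spec: ClassSpec
    schema: tuple[FeatureSchema, ...]

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)


@dataclass
class OrdinalDataset:
    """Samples x (mixed features, ordinal class).

    ``X`` is a pandas DataFrame whose columns match ``schema`` (numeric
    columns as float64, categorical as strings); ``y`` is the 1-based class
    index per row.
    """

    schema: tuple[FeatureSchema, ...]
    X: pd.DataFrame
    y: np.ndarray
    class_spec: ClassSpec

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        names = [f.name for f in self.schema]
        if len(set(names)) != len(names):
            raise ValidationError("feature names must be unique")
        if list(self.X.columns) != names:
            raise ValidationError(
                f"dataframe columns {list(self.X.columns)} do not match "
                f"schema feature names {names}"
            )
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.y) != len(self.X):
            raise ValidationError("y length does not match number of rows")
        if len(self.y) and (self.y.min() < 1 or self.y.max() > self.class_spec.n):
            bad = int(np.argmax((self.y < 1) | (self.y > self.class_spec.n)))
            raise ValidationError(
                f"row {bad}: target index {self.y[bad]} outside "
                f"1..{self.class_spec.n}"
            )

    @property
    def T(self) -> int:
        return len(self.y)

    @property
    def K(self) -> int:
        return len(self.schema)

    def feature(self, name: str) -> FeatureSchema:
        for f in self.schema:
            if f.name == name:
                return f
        raise ValidationError(f"unknown feature {name!r}")

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y - 1, minlength=self.class_spec.n) if self.T else np.zeros(
            self.class_spec.n, dtype=np.int64
        )

    def subset(self, indices: Iterable[int]) -> "OrdinalDataset":
        idx = np.asarray(list(indices), dtype=np.int64)
        return OrdinalDataset(
            schema=self.schema,
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y[idx],
            class_spec=self.class_spec,
        )


def empirical_distribution(data: OrdinalDataset) -> ClassDistribution:
    """Empirical class probabilities P(c_i) of a dataset (support = T)."""
    return ClassDistribution.from_counts(data.class_counts())


# ---------------------------------------------------------------------------
# schema I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetSchema:
    """Parsed schema file: feature declarations plus the target contract.

    ``binning`` is the optional ordered boundary list turning a
    non-negative numeric target into classes (see ``preprocess.HoursBinning``);
    when absent the target column must contain class labels directly.
    """

    features: tuple[FeatureSchema, ...]
    target_column: str
    class_spec: ClassSpec
    binning: tuple[float, ...] | None = None


def read_schema(path: str | Path) -> DatasetSchema:
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(
            f"{path}: malformed schema JSON at line {e.lineno}, column {e.colno}"
        ) from None
    try:
        feats = tuple(
            FeatureSchema(
                name=f["name"],
                kind=f["kind"],
                categories=tuple(f["categories"]) if f.get("categories") else None,
            )
            for f in raw["features"]
        )
        target = raw["target"]
        spec = ClassSpec(tuple(target["classes"]))
        binning = tuple(float(b) for b in target["binning"]) if "binning" in target else None
        return DatasetSchema(feats, str(target["column"]), spec, binning)
    except (KeyError, TypeError) as e:
        raise ValidationError(f"{path}: schema JSON missing field: {e}") from None


def write_schema(schema: DatasetSchema, path: str | Path) -> None:
    target: dict = {
        "column": schema.target_column,
        "classes": list(schema.class_spec.labels),
    }
    if schema.binning is not None:
        target["binning"] = list(schema.binning)
    doc = {
        "features": [
            {"name": f.name, "kind": f.kind}
            | ({"categories": list(f.categories)} if f.categories else {})
            for f in schema.features
        ],
        "target": target,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------


def read_dataset(csv_path: str | Path, schema_path: str | Path) -> OrdinalDataset:
    """Read and validate a CSV against its JSON schema.

    Numeric columns are parsed as floats, categorical values checked
    against the schema's category list, and the target column either
    matched against the class labels or -- when the schema declares a
    ``binning`` -- parsed as non-negative hours and categorized.  Any
    violation raises :class:`ValidationError` naming the row and column
    (rows are 0-based data rows, excluding the header).
    """
    schema = read_schema(schema_path)
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    needed = [f.name for f in schema.features] + [schema.target_column]
    for col in needed:
        if col not in df.columns:
            raise ValidationError(f"{csv_path}: missing column {col!r}")

    X = pd.DataFrame(index=df.index)
    for f in schema.features:
        col = df[f.name]
        empty = col.str.strip() == ""
        if empty.any():
            row = int(np.argmax(empty.to_numpy()))
            raise ValidationError(
                f"{csv_path}: missing value at row {row}, column {f.name!r}"
            )
        if f.kind == NUMERIC:
            parsed = pd.to_numeric(col, errors="coerce")
            if parsed.isna().any():
                row = int(np.argmax(parsed.isna().to_numpy()))
                raise ValidationError(
                    f"{csv_path}: unparseable numeric {col.iloc[row]!r} at "
                    f"row {row}, column {f.name!r}"
                )
            X[f.name] = parsed.astype(float)
        else:
            allowed = set(f.categories)
            bad = ~col.isin(allowed)
            if bad.any():
                row = int(np.argmax(bad.to_numpy()))
                raise ValidationError(
                    f"{csv_path}: category {col.iloc[row]!r} at row {row}, "
                    f"column {f.name!r} not in schema categories {f.categories}"
                )
            X[f.name] = col.astype(str)

    tcol = df[schema.target_column]
    if schema.binning is not None:
        from .preprocess import HoursBinning, categorize_hours  # local: avoid cycle

        binning = HoursBinning(schema.binning)
        hours = pd.to_numeric(tcol, errors="coerce")
        if hours.isna().any():
            row = int(np.argmax(hours.isna().to_numpy()))
            raise ValidationError(
                f"{csv_path}: unparseable numeric target {tcol.iloc[row]!r} "
                f"at row {row}"
            )
        if (hours < 0).any():
            row = int(np.argmax((hours < 0).to_numpy()))
            raise ValidationError(
                f"{csv_path}: negative target {hours.iloc[row]} at row {row}"
            )
        y = np.array(
            [categorize_hours(v, binning) for v in hours.to_numpy()], dtype=np.int64
        )
        if y.max(initial=1) > schema.class_spec.n:
            row = int(np.argmax(y > schema.class_spec.n))
            raise ValidationError(
                f"{csv_path}: row {row}: binned class {y[row]} exceeds the "
                f"{schema.class_spec.n} declared classes"
            )
    else:
        labels = {lab: i + 1 for i, lab in enumerate(schema.class_spec.labels)}
        bad = ~tcol.isin(labels)
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValidationError(
                f"{csv_path}: target {tcol.iloc[row]!r} at row {row} not in "
                f"classes {schema.class_spec.labels}"
            )
        y = tcol.map(labels).to_numpy(dtype=np.int64)

    return OrdinalDataset(schema.features, X, y, schema.class_spec)


def write_dataset(
    data: OrdinalDataset,
    csv_path: str | Path,
    schema_path: str | Path | None = None,
    target_column: str = "class",
) -> None:
    """Write a dataset as CSV (+ optional schema JSON) using class labels."""
    out = data.X.copy()
    if target_column in out.columns:
        raise ValidationError(
            f"target column name {target_column!r} collides with a feature"
        )
    out[target_column] = [data.class_spec.labels[i - 1] for i in data.y]
    out.to_csv(csv_path, index=False)
    if schema_path is not None:
        write_schema(
            DatasetSchema(data.schema, target_column, data.class_spec), schema_path
        )


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

_MODEL_FORMAT = "obecart-model"


def _node_to_dict(node: TreeNode) -> dict:
    d: dict = {
        "probs": [float(p) for p in node.distribution.probs],
        "support": node.support,
    }
    if node.is_leaf:
        d["leaf"] = True
        d["predicted"] = node.predicted
    else:
        d["leaf"] = False
        d["feature"] = node.feature
        d["kind"] = node.kind
        if node.kind == NUMERIC:
            d["threshold"] = node.threshold
        else:
            d["category"] = node.category
        d["gain"] = node.gain
        d["left"] = _node_to_dict(node.left)
        d["right"] = _node_to_dict(node.right)
    return d


def _node_from_dict(d: dict, where: str = "root") -> TreeNode:
    try:
        dist = ClassDistribution(np.asarray(d["probs"], dtype=float), d["support"])
        if d["leaf"]:
            return TreeNode(dist, int(d["support"]), predicted=int(d["predicted"]))
        kind = d["kind"]
        if kind == NUMERIC and not math.isfinite(float(d["threshold"])):
            raise ValidationError(f"{where}: non-finite threshold")
        return TreeNode(
            dist,
            int(d["support"]),
            feature=str(d["feature"]),
            kind=kind,
            threshold=float(d["threshold"]) if kind == NUMERIC else None,
            category=str(d["category"]) if kind == CATEGORICAL else None,
            gain=float(d["gain"]) if d.get("gain") is not None else None,
            left=_node_from_dict(d["left"], where + "/L"),
            right=_node_from_dict(d["right"], where + "/R"),
        )
    except (KeyError, TypeError, ValueError) as e:
        if isinstance(e, ValidationError):
            raise
        raise ValidationError(f"malformed model node at {where}: {e}") from None


def serialize_model(model: OrdinalTreeModel, path: str | Path) -> None:
    doc = {
        "format": _MODEL_FORMAT,
        "version": 1,
        "class_spec": {"labels": list(model.class_spec.labels)},
        "schema": [
            {"name": f.name, "kind": f.kind}
            | ({"categories": list(f.categories)} if f.categories else {})
            for f in model.schema
        ],
        "config": model.config,
        "root": _node_to_dict(model.root),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def deserialize_model(path: str | Path) -> OrdinalTreeModel:
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(
            f"{path}: malformed model JSON at line {e.lineno}, column {e.colno}"
        ) from None
    if raw.get("format") != _MODEL_FORMAT:
        raise ValidationError(f"{path}: not an {_MODEL_FORMAT} file")
    try:
        spec = ClassSpec(tuple(raw["class_spec"]["labels"]))
        schema = tuple(
            FeatureSchema(
                f["name"], f["kind"],
                tuple(f["categories"]) if f.get("categories") else None,
            )
            for f in raw["schema"]
        )
        root = _node_from_dict(raw["root"])
        return OrdinalTreeModel(root, dict(raw["config"]), spec, schema)
    except (KeyError, TypeError) as e:
        raise ValidationError(f"{path}: malformed model file: {e}") from None
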