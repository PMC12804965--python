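"""Reading and writing the pipeline's delimited-text formats.

Trial tables are CSV with the header
``subject_id,pool_id,image_id,true_category,response_category,session``;
extra columns are preserved with a warning, malformed rows are reported
with their file line numbers, and all writes are atomic (temp file +
rename).
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .decoder import FeatureSet
from .simulate import TRIAL_COLUMNS


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv_atomic(df: pd.DataFrame, path) -> None:
    _atomic_write(Path(path), lambda fh: df.to_csv(fh, index=False))


def write_json_atomic(obj, path) -> None:
    _atomic_write(
        Path(path),
        lambda fh: fh.write(json.dumps(obj, indent=2, sort_keys=True) + "\n"),
    )


def read_trials_csv(path, valid_categories=("A", "B")) -> pd.DataFrame:
    """Read a trial table, validating header and category tokens.

    ``valid_categories=None`` skips token validation (any pair of labels).
    Line numbers in error messages count the header as line 1.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring extra column(s) {extra}", stacklevel=2)
    for col in ("true_category", "response_category"):
        empty = df[col] == ""
        if empty.any():
            line = int(np.flatnonzero(empty.to_numpy())[0]) + 2
            raise ValueError(f"{path}: empty {col} on line {line}")
        if valid_categories is not None:
            bad = ~df[col].isin(valid_categories)
            if bad.any():
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                tok = df[col].iloc[line - 2]
                raise ValueError(
                    f"{path}: bad {col} token {tok!r} on line {line} "
                    f"(expected one of {sorted(valid_categories)})"
                )
    return df


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing column(s) {missing}")
    ordered = TRIAL_COLUMNS + [c for c in trials.columns if c not in TRIAL_COLUMNS]
    write_csv_atomic(trials[ordered], path)


def write_feature_set(fs: FeatureSet, features_path, labels_path) -> None:
    """Feature matrix as a plain numeric CSV plus a two-column label table."""
    mat = pd.DataFrame(fs.features)
    mat.insert(0, "image_id", fs.image_ids)
    write_csv_atomic(mat, features_path)
    write_csv_atomic(
        pd.DataFrame({"image_id": fs.image_ids, "category": fs.labels}), labels_path
    )


def read_feature_set(features_path, labels_path) -> FeatureSet:
    mat = pd.read_csv(features_path)
    if "image_id" not in mat.columns:
        raise ValueError(f"{features_path}: missing image_id column")
    labels = pd.read_csv(labels_path, dtype=str)
    for col in ("image_id", "category"):
        if col not in labels.columns:
            raise ValueError(f"{labels_path}: missing {col} column")
    labels = labels.set_index("image_id")["category"]
    ids = mat["image_id"].astype(str).to_numpy()
    missing = [i for i in ids if i not in labels.index]
    if missing:
        raise ValueError(f"label table missing image {missing[0]!r}")
    return FeatureSet(
        ids, labels.loc[ids].to_numpy(), mat.drop(columns="image_id").to_numpy(float)
    )
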