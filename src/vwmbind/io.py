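"""Plain-text dataset format.

One row per trial, tab-separated, with a commented header carrying the
schema version and angle conventions.  Angles are stored in radians;
orientations are stored *native* (half-circle values in [-pi/2, pi/2)) and
doubled on load, matching how raw lab data is recorded.  Responses may be
left blank for stimulus-only files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .circstats import wrap
from .dataset import DELAY_LEVELS, FEATURE_DIMS, Dataset

SCHEMA_VERSION = "1"

__all__ = ["read_dataset", "write_dataset", "SCHEMA_VERSION"]


def _columns(n_items: int) -> list[str]:
    cols = ["participant_id", "trial_id", "block", "delay", "cue_dim", "target_index"]
    for prefix in ("loc", "col", "ori"):
        cols += [f"{prefix}_{i}" for i in range(n_items)]
    cols += ["response1_dim", "response1_value", "response2_dim", "response2_value"]
    return cols


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset to the tab-separated text format."""
    n, N = dataset.n_trials, dataset.n_items
    df = pd.DataFrame(
        {
            "participant_id": dataset.participant,
            "trial_id": np.arange(n),
            "block": dataset.block,
            "delay": dataset.delay.astype(str),
            "cue_dim": dataset.cue_dim,
            "target_index": dataset.target_index,
        }
    )
    for i in range(N):
        df[f"loc_{i}"] = dataset.locations[:, i]
    for i in range(N):
        df[f"col_{i}"] = dataset.colors[:, i]
    for i in range(N):
        df[f"ori_{i}"] = wrap(dataset.orientations[:, i]) / 2.0  # native on disk
    for r in (0, 1):
        dim = dataset.report_dims[r]
        df[f"response{r + 1}_dim"] = dim
        if dataset.responses is None:
            df[f"response{r + 1}_value"] = np.nan
        else:
            v = dataset.responses[:, r]
            df[f"response{r + 1}_value"] = wrap(v) / 2.0 if dim == "orientation" else v
    header = (
        f"# vwmbind-dataset schema={SCHEMA_VERSION}\n"
        f"# n_items={N}\n"
        f"# angle_unit=radians\n"
        f"# orientation_storage=native\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def _fail(row, col, msg):
    raise ValueError(f"dataset file error at row {row}, column {col!r}: {msg}")


def read_dataset(path) -> Dataset:
    """Read a dataset file; validates the schema and wraps/doubles angles."""
    path = Path(path)
    n_items = None
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#") and "n_items=" in line:
            n_items = int(line.split("n_items=")[1].strip())
        if not line.startswith("#"):
            break
    df = pd.read_csv(_io.StringIO(text), sep="\t", comment="#")
    if n_items is None:
        # infer from the location columns
        n_items = sum(c.startswith("loc_") for c in df.columns)
    expected = _columns(n_items)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file is missing columns {missing}")
    n = len(df)
    if n == 0:
        raise ValueError("dataset file has no trials")
    cue_dim = str(df["cue_dim"].iloc[0])
    if cue_dim not in FEATURE_DIMS:
        _fail(0, "cue_dim", f"unknown dimension {cue_dim!r}")
    if (df["cue_dim"] != cue_dim).any():
        row = int(np.flatnonzero(df["cue_dim"] != cue_dim)[0])
        _fail(row, "cue_dim", "mixed cue dimensions in one file")
    report_dims = (str(df["response1_dim"].iloc[0]), str(df["response2_dim"].iloc[0]))
    for r, dim in enumerate(report_dims):
        if dim not in FEATURE_DIMS:
            _fail(0, f"response{r + 1}_dim", f"unknown dimension {dim!r}")
    for row, d in enumerate(df["delay"]):
        if d not in DELAY_LEVELS:
            _fail(row, "delay", f"unknown delay level {d!r}")
    tgt = df["target_index"].to_numpy()
    bad = np.flatnonzero((tgt < 0) | (tgt >= n_items))
    if bad.size:
        _fail(int(bad[0]), "target_index", f"out of range [0, {n_items})")
    feats = {}
    for dim, prefix in (("location", "loc"), ("color", "col"), ("orientation", "ori")):
        cols = [f"{prefix}_{i}" for i in range(n_items)]
        arr = df[cols].to_numpy(float)
        nonfinite = ~np.isfinite(arr)
        if nonfinite.any():
            r, c = np.argwhere(nonfinite)[0]
            _fail(int(r), cols[int(c)], "non-finite angle")
        feats[dim] = arr
    feats["orientation"] = feats["orientation"] * 2.0  # doubled in memory
    resp_vals = df[["response1_value", "response2_value"]].to_numpy(float)
    if np.isnan(resp_vals).all():
        responses = None
    else:
        nonfinite = ~np.isfinite(resp_vals)
        if nonfinite.any():
            r, c = np.argwhere(nonfinite)[0]
            _fail(int(r), f"response{int(c) + 1}_value", "missing or non-finite")
        responses = resp_vals.copy()
        for r, dim in enumerate(report_dims):
            if dim == "orientation":
                responses[:, r] = responses[:, r] * 2.0
    return Dataset(
        locations=feats["location"],
        colors=feats["color"],
        orientations=feats["orientation"],
        cue_dim=cue_dim,
        report_dims=report_dims,
        target_index=tgt,
        delay=df["delay"].to_numpy(object),
        responses=responses,
        participant=df["participant_id"].to_numpy(int),
        block=df["block"].to_numpy(int),
    )
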