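"""Matrix-file input, model serialization and YAML configuration.

Feature files are delimited numeric text (CSV or TSV, delimiter sniffed);
the default orientation is samples-as-rows, transposed on load into the
internal features-by-samples layout. Models round-trip losslessly through a
single HDF5 container of named dense arrays.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import List, Optional, Sequence

import h5py
import numpy as np
import yaml

from .kernels import KernelSpec
from .types import DomainError, FeatureMatrix, Hyperparams, ModelState

MODEL_FORMAT_VERSION = 1


class MatrixFormatError(ValueError):
    """Ragged or structurally invalid matrix file."""


class MatrixParseError(ValueError):
    """Non-numeric or non-finite token, reported with its position."""


class ModelCorruptionError(RuntimeError):
    """Model container unreadable or missing a required array."""


class UnsupportedVersionError(RuntimeError):
    """Model container written by an incompatible format version."""


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t; ").delimiter
    except csv.Error:
        return ","


def _parse_rows(path: Path) -> List[List[float]]:
    text = path.read_text()
    if not text.strip():
        raise MatrixFormatError(f"{path}: file is empty")
    delim = _sniff_delimiter(text[:4096])
    rows: List[List[float]] = []
    reader = csv.reader(text.splitlines(), delimiter=delim)
    for i, rec in enumerate(reader):
        rec = [tok for tok in rec if tok.strip() != ""]
        if not rec:
            continue
        row = []
        for j, tok in enumerate(rec):
            try:
                val = float(tok)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: non-numeric token {tok!r} at row {i + 1}, "
                    f"column {j + 1}"
                ) from None
            if not math.isfinite(val):
                raise MatrixParseError(
                    f"{path}: non-finite value {tok!r} at row {i + 1}, "
                    f"column {j + 1}"
                )
            row.append(val)
        rows.append(row)
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise MatrixFormatError(
            f"{path}: ragged rows (widths {sorted(widths)})"
        )
    return rows


def read_feature_matrix(
    path, orientation: str = "samples_as_rows"
) -> FeatureMatrix:
    """Read a delimited numeric matrix file into a FeatureMatrix.

    ``orientation`` says how the file is laid out; the returned matrix is
    always features-by-samples internally (files with samples as rows are
    transposed on load).
    """
    if orientation not in ("samples_as_rows", "samples_as_cols"):
        raise DomainError(f"unknown orientation {orientation!r}")
    arr = np.asarray(_parse_rows(Path(path)), dtype=float)
    if orientation == "samples_as_rows":
        arr = arr.T
    return FeatureMatrix(arr)


def read_labels(path) -> np.ndarray:
    """Read an integer label vector (one value per line or a single row)."""
    arr = np.asarray(_parse_rows(Path(path)), dtype=float)
    flat = arr.ravel()
    if arr.ndim == 2 and 1 not in arr.shape:
        raise MatrixFormatError(f"{path}: labels must be a vector")
    labels = flat.astype(int)
    if not np.array_equal(labels, flat):
        raise MatrixParseError(f"{path}: labels must be integers")
    return labels


# ---------------------------------------------------------------------------
# model serialization


def save_model(state: ModelState, path) -> None:
    """Write every model array to a single HDF5 container (lossless)."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = MODEL_FORMAT_VERSION
        f.attrs["mode"] = state.mode
        f.attrs["n_sources"] = state.S
        f.create_dataset("W_t", data=state.W_t)
        f.create_dataset("F", data=state.F)
        f.create_dataset("vartheta", data=state.vartheta)
        f.create_dataset("eta", data=state.eta)
        for a in range(state.S):
            g = f.create_group(f"source_{a}")
            g.create_dataset("Theta", data=state.Theta[a])
            g.create_dataset("P", data=state.P[a])
            g.create_dataset("T", data=state.T[a])
            g.create_dataset("F_a", data=state.F_a[a])
            if state.train_pairs is not None:
                g.create_dataset("train_pair", data=state.train_pairs[a])
        if state.train_target is not None:
            f.create_dataset("train_target", data=state.train_target)
        if state.kernel_specs is not None:
            f.attrs["kernel_specs"] = yaml.safe_dump(
                [{"name": s.name, "sigma": s.sigma}
                 for s in state.kernel_specs]
            )


def _require(node, name: str) -> np.ndarray:
    if name not in node:
        raise ModelCorruptionError(f"model container is missing array {name!r}")
    return np.asarray(node[name])


def load_model(path) -> ModelState:
    """Load a model saved by :func:`save_model`, bit-exactly."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ModelCorruptionError(f"cannot open model file: {exc}") from exc
    with f:
        version = int(f.attrs.get("format_version", -1))
        if version != MODEL_FORMAT_VERSION:
            raise UnsupportedVersionError(
                f"model format version {version} is not supported "
                f"(expected {MODEL_FORMAT_VERSION})"
            )
        S = int(f.attrs["n_sources"])
        mode = str(f.attrs["mode"])
        Theta, P, T, F_a = [], [], [], []
        train_pairs: Optional[List[np.ndarray]] = [] if mode == "kernel" else None
        for a in range(S):
            if f"source_{a}" not in f:
                raise ModelCorruptionError(
                    f"model container is missing group 'source_{a}'"
                )
            g = f[f"source_{a}"]
            Theta.append(_require(g, "Theta"))
            P.append(_require(g, "P"))
            T.append(_require(g, "T"))
            F_a.append(_require(g, "F_a"))
            if train_pairs is not None:
                train_pairs.append(_require(g, "train_pair"))
        specs = None
        if "kernel_specs" in f.attrs:
            specs = [
                KernelSpec(**d)
                for d in yaml.safe_load(str(f.attrs["kernel_specs"]))
            ]
        return ModelState(
            Theta=Theta, P=P, T=T, F_a=F_a,
            W_t=_require(f, "W_t"), F=_require(f, "F"),
            vartheta=_require(f, "vartheta"), eta=_require(f, "eta"),
            mode=mode,
            train_pairs=train_pairs,
            train_target=(
                np.asarray(f["train_target"]) if "train_target" in f else None
            ),
            kernel_specs=specs,
        )


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> Hyperparams:
    """Load a YAML config whose keys mirror the Hyperparams field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise DomainError("config must be a YAML mapping")
    known = set(Hyperparams().asdict())
    unknown = set(raw) - known
    if unknown:
        raise DomainError(f"unknown config keys: {sorted(unknown)}")
    if isinstance(raw.get("kernel"), dict):
        raw["kernel"] = KernelSpec(**raw["kernel"])
    if raw.get("mkl"):
        raw["mkl"] = [
            KernelSpec(**s) if isinstance(s, dict) else s for s in raw["mkl"]
        ]
    return Hyperparams(**raw)


def save_config(hyper: Hyperparams, path) -> None:
    """Write a Hyperparams object back to YAML (inverse of load_config)."""
    data = hyper.asdict()
    if isinstance(data.get("kernel"), KernelSpec):
        data["kernel"] = {
            "name": data["kernel"].name, "sigma": data["kernel"].sigma
        }
    if data.get("mkl"):
        data["mkl"] = [
            {"name": s.name, "sigma": s.sigma} if isinstance(s, KernelSpec)
            else s
            for s in data["mkl"]
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_feature_matrix(
    X: FeatureMatrix, path, orientation: str = "samples_as_rows"
) -> None:
    """Write a FeatureMatrix as CSV (inverse of read_feature_matrix)."""
    arr = X.values.T if orientation == "samples_as_rows" else X.values
    np.savetxt(path, arr, delimiter=",")


def write_labels(labels: Sequence[int], path) -> None:
    np.savetxt(path, np.asarray(labels, int)[:, None], fmt="%d")
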