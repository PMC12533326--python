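"""Readers and writers for the on-disk formats.

Matrices travel as delimited text (TSV or CSV, autodetected), features in
rows and samples in columns, with a feature-ID first column and a sample-ID
header row.  Missing entries are "NA" (or empty / "NaN").  Fitted parameters
are stored as an ``.npz`` container of named arrays together with a JSON
echo of the configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MultiModalDataset
from .model import FitConfig, GPCCAParameters

__all__ = [
    "load_modalities",
    "write_modalities",
    "write_embedding",
    "write_labels",
    "load_labels",
    "save_parameters",
    "load_parameters",
]

NA_TOKENS = ("NA", "", "NaN")


def _detect_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_matrix(path, na_tokens) -> pd.DataFrame:
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    raw = np.char.strip(df.to_numpy(dtype=str))
    is_na = np.isin(raw, list(na_tokens))
    work = np.where(is_na, "nan", raw)
    try:
        values = work.astype(float)      # strtod: correctly-rounded parsing
    except ValueError:
        for (i, j), cell in np.ndenumerate(work):
            try:
                float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {raw[i, j]!r} at feature "
                    f"{df.index[i]!r}, sample {df.columns[j]!r}"
                ) from None
        raise
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def load_modalities(paths, na_tokens=NA_TOKENS) -> MultiModalDataset:
    """Read one delimited file per modality into a stacked dataset.

    All files must share an identical sample header (same IDs, same order).
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no modality files given")
    frames = [_read_matrix(p, na_tokens) for p in paths]
    ref = list(frames[0].columns)
    bad = [str(p) for p, f in zip(paths, frames) if list(f.columns) != ref]
    if bad:
        raise ValueError(
            "sample headers differ across modality files; offending files: "
            + ", ".join(bad)
        )
    return MultiModalDataset(
        [f.to_numpy() for f in frames],
        sample_ids=ref,
        feature_ids=[list(f.index) for f in frames],
    )


def write_modalities(dataset: MultiModalDataset, out_dir, prefix="modality",
                     sep="\t", na_rep="NA") -> list:
    """Write one file per modality in the same layout ``load_modalities``
    reads; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    ext = "tsv" if sep == "\t" else "csv"
    for r in range(dataset.n_modalities):
        M, _ = dataset.modality_view(r)
        df = pd.DataFrame(M, index=dataset.feature_ids[r],
                          columns=dataset.sample_ids)
        p = out_dir / f"{prefix}{r + 1}.{ext}"
        df.to_csv(p, sep=sep, na_rep=na_rep)
        paths.append(p)
    return paths


def write_embedding(path, embedding: np.ndarray, sample_ids) -> None:
    """Samples in rows, factors in columns."""
    d = embedding.shape[0]
    df = pd.DataFrame(embedding.T, index=sample_ids,
                      columns=[f"factor_{j + 1}" for j in range(d)])
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def write_labels(path, labels, sample_ids) -> None:
    df = pd.DataFrame({"label": np.asarray(labels)}, index=sample_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def load_labels(path) -> np.ndarray:
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.iloc[:, 0].to_numpy()


def save_parameters(path, params: GPCCAParameters, config: FitConfig = None) -> None:
    """Named-array container: W, mu, per-modality Psi blocks, modality
    dims/offsets, and a JSON echo of the fit configuration."""
    arrays = dict(
        W=params.W,
        mu=params.mu,
        dims=np.asarray(params.dims, dtype=np.int64),
        offsets=params.offsets.astype(np.int64),
        covariance_mode=np.array(params.covariance_mode),
    )
    for r, B in enumerate(params.Psi_blocks):
        arrays[f"Psi_block_{r}"] = B
    if config is not None:
        arrays["config_json"] = np.array(json.dumps(vars(config)))
    np.savez(path, **arrays)


def load_parameters(path):
    """Inverse of :func:`save_parameters`; returns ``(params, config)``
    (``config`` is None if absent)."""
    with np.load(path, allow_pickle=False) as z:
        dims = tuple(int(v) for v in z["dims"])
        blocks = [z[f"Psi_block_{r}"] for r in range(len(dims))]
        params = GPCCAParameters(
            z["W"], z["mu"], blocks, dims, str(z["covariance_mode"]),
        )
        config = None
        if "config_json" in z:
            config = FitConfig(**json.loads(str(z["config_json"])))
    return params, config
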