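"""Tabular IO: CSV/TSV tables, spectra, and YAML configuration.

Plain CSV/TSV is the interchange surface (the analysis starts from binned
tables, not vendor NMR formats). Dialect is auto-detected from the file
extension; unknown columns are preserved on round trips.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import RawSpectraSet, SpectraMatrix

__all__ = [
    "read_table",
    "write_table",
    "write_spectra",
    "read_spectra",
    "write_spectra_matrix",
    "read_spectra_matrix",
    "load_config",
]


def _sep(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","


def read_table(
    path,
    required: tuple[str, ...] = (),
    index_col: str | None = None,
) -> pd.DataFrame:
    """Read a CSV/TSV table with a header row.

    ``required`` columns must be present (error names the missing one);
    with ``index_col`` set, duplicated index values are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if index_col is not None:
        if index_col not in df.columns:
            raise ValueError(f"{path}: missing required column {index_col!r}")
        if df[index_col].duplicated().any():
            dup = df[index_col][df[index_col].duplicated()].iloc[0]
            raise ValueError(f"{path}: duplicated {index_col} {dup!r}")
        df = df.set_index(index_col)
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep(path), index=df.index.name is not None)
    return path


def write_spectra(raw: RawSpectraSet, path) -> Path:
    """Wide CSV: first column sample_id, remaining columns the ppm grid."""
    df = pd.DataFrame(raw.intensities, columns=[f"{p:.6g}" for p in raw.ppm])
    df.insert(0, "sample_id", raw.sample_ids)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep(path), index=False)
    return path


def read_spectra(path) -> RawSpectraSet:
    df = read_table(path, index_col="sample_id")
    ppm = np.array([float(c) for c in df.columns])
    return RawSpectraSet(ppm, df.to_numpy(dtype=float), list(df.index.astype(str)))


def write_spectra_matrix(matrix: SpectraMatrix, path) -> Path:
    """Binned matrix as wide CSV (columns labelled by ppm bin center) plus a
    JSON sidecar (<path>.meta.json) with bin edges, exclusions and labels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = matrix.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep(path))
    sidecar = {
        "bin_edges": matrix.bin_edges,
        "excluded_regions": matrix.excluded_regions,
        "normalization": matrix.normalization,
        "scaling": matrix.scaling,
    }
    Path(f"{path}.meta.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_spectra_matrix(path) -> SpectraMatrix:
    path = Path(path)
    df = read_table(path, index_col="sample_id")
    meta_path = Path(f"{path}.meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        return SpectraMatrix(
            df,
            [tuple(e) for e in meta["bin_edges"]],
            excluded_regions=[tuple(e) for e in meta["excluded_regions"]],
            normalization=meta["normalization"],
            scaling=meta["scaling"],
        )
    width = float(df.columns[1]) - float(df.columns[0]) if df.shape[1] > 1 else 0.01
    edges = [(float(c) - width / 2, float(c) + width / 2) for c in df.columns]
    return SpectraMatrix(df, edges)


def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration mapping."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
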