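"""Frozen on-disk dialect: TSV matrices and region tables.

Matrices are dense tab-separated text with a single header row naming
the region order; undefined entries are serialized as ``nan``.  Sparse
structural matrices may also travel as 3-column edge lists (i, j,
weight), 0-based indices, upper triangle only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .regions import RegionSet

__all__ = [
    "write_regions",
    "read_regions",
    "write_matrix",
    "read_matrix",
    "write_edge_list",
    "read_edge_list",
]

_FLOAT_FMT = "%.10g"


def write_regions(regions: RegionSet, path: str | Path) -> None:
    regions.to_frame().to_csv(path, sep="\t", index=False, na_rep="nan",
                              float_format=_FLOAT_FMT)


def read_regions(path: str | Path) -> RegionSet:
    return RegionSet.from_frame(pd.read_csv(path, sep="\t"))


def write_matrix(m: np.ndarray, region_ids: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(m, float), columns=[str(r) for r in region_ids])
    df.to_csv(path, sep="\t", index=False, na_rep="nan", float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (matrix, region_ids)."""
    df = pd.read_csv(path, sep="\t")
    ids = np.array([int(c) for c in df.columns])
    return df.to_numpy(float), ids


def write_edge_list(weights: np.ndarray, path: str | Path) -> None:
    w = np.asarray(weights, float)
    i, j = np.where(np.triu(w, k=1) != 0)
    pd.DataFrame({"i": i, "j": j, "weight": w[i, j]}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_edge_list(path: str | Path, n: int) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    w = np.zeros((n, n))
    i = df["i"].to_numpy(int)
    j = df["j"].to_numpy(int)
    w[i, j] = df["weight"].to_numpy(float)
    w[j, i] = w[i, j]
    return w
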