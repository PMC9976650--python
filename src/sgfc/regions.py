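"""Region metadata: the geometric frame of reference.

A :class:`RegionSet` holds, per cortical region, a 3-D centroid in mm,
a hemisphere label, an optional intrinsic-network label, an optional
unit position on the (within-hemisphere) sphere used by spin tests, and
an optional planted hierarchy position (synthetic data only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RegionSet", "HEMISPHERES"]

HEMISPHERES = ("left", "right")


@dataclass
class RegionSet:
    """Identities and geometry of the parcellation's regions.

    Parameters
    ----------
    region_id
        Integer region indices, unique.
    centroids
        (n, 3) centroid coordinates in mm; finite, no duplicate rows.
    hemisphere
        Per-region label, ``"left"`` or ``"right"``.
    network_label
        Optional categorical intrinsic-network labels.
    sphere_coord
        Optional (n, 3) unit vectors: each region's direction on its
        hemisphere's sphere, required by spin permutations.
    gradient_truth
        Optional planted hierarchy position (synthetic data only).
    """

    region_id: np.ndarray
    centroids: np.ndarray
    hemisphere: np.ndarray
    network_label: np.ndarray | None = None
    sphere_coord: np.ndarray | None = None
    gradient_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.region_id = np.asarray(self.region_id, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        n = self.region_id.shape[0]
        if self.centroids.shape != (n, 3):
            raise ValueError(f"centroids must be ({n}, 3), got {self.centroids.shape}")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if len(np.unique(self.region_id)) != n:
            raise ValueError("region_id values must be unique")
        uniq = np.unique(self.centroids, axis=0)
        if uniq.shape[0] != n:
            raise ValueError("two regions share identical centroids")
        bad = set(self.hemisphere) - set(HEMISPHERES)
        if bad:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad)}")
        if self.sphere_coord is not None:
            self.sphere_coord = np.asarray(self.sphere_coord, dtype=float)
            if self.sphere_coord.shape != (n, 3):
                raise ValueError("sphere_coord must be (n, 3)")
            norms = np.linalg.norm(self.sphere_coord, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValueError("sphere_coord rows must have unit norm (tol 1e-9)")
        if self.network_label is not None:
            self.network_label = np.asarray(self.network_label, dtype=object)
            if self.network_label.shape[0] != n:
                raise ValueError("network_label length mismatch")
        if self.gradient_truth is not None:
            self.gradient_truth = np.asarray(self.gradient_truth, dtype=float)
            if self.gradient_truth.shape[0] != n:
                raise ValueError("gradient_truth length mismatch")

    @property
    def n(self) -> int:
        return int(self.region_id.shape[0])

    def hemi_mask(self, which: str) -> np.ndarray:
        if which not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        return self.hemisphere == which

    def require_spin_ready(self) -> None:
        """Raise unless spin permutations can be built on this set."""
        if self.sphere_coord is None:
            raise ValueError("sphere_coord is required for spin permutations")
        for h in HEMISPHERES:
            if not np.any(self.hemi_mask(h)):
                raise ValueError(f"{h} hemisphere is empty; spin test needs both")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "region_id": self.region_id,
                "x_mm": self.centroids[:, 0],
                "y_mm": self.centroids[:, 1],
                "z_mm": self.centroids[:, 2],
                "hemisphere": self.hemisphere,
            }
        )
        df["network_label"] = (
            self.network_label if self.network_label is not None else np.nan
        )
        if self.sphere_coord is not None:
            df["sphere_x"] = self.sphere_coord[:, 0]
            df["sphere_y"] = self.sphere_coord[:, 1]
            df["sphere_z"] = self.sphere_coord[:, 2]
        else:
            df[["sphere_x", "sphere_y", "sphere_z"]] = np.nan
        df["gradient_truth"] = (
            self.gradient_truth if self.gradient_truth is not None else np.nan
        )
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionSet":
        sphere = None
        if {"sphere_x", "sphere_y", "sphere_z"} <= set(df.columns):
            s = df[["sphere_x", "sphere_y", "sphere_z"]].to_numpy(float)
            if np.all(np.isfinite(s)):
                sphere = s
        network = None
        if "network_label" in df.columns and not df["network_label"].isna().all():
            network = df["network_label"].to_numpy(object)
        gradient = None
        if "gradient_truth" in df.columns:
            g = df["gradient_truth"].to_numpy(float)
            if np.all(np.isfinite(g)):
                gradient = g
        return cls(
            region_id=df["region_id"].to_numpy(int),
            centroids=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
            hemisphere=df["hemisphere"].to_numpy(object),
            network_label=network,
            sphere_coord=sphere,
            gradient_truth=gradient,
        )
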