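"""Spatial quantification of micropatterned colonies.

Cells carry (x, y) coordinates relative to the colony center plus per-marker
intensities.  Profiles are built over equal-width annular bins of the
normalized radius r/R in [0, 1]; bin statistics are plain per-cell means
(no area weighting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ColonyPointCloud",
    "RadialProfile",
    "radial_profile",
    "normalize_profile",
    "profile_auc",
    "composition_fractions",
]

#: Cells may scatter slightly past the nominal colony edge.
EDGE_TOLERANCE = 1.2


@dataclass
class ColonyPointCloud:
    """Per-cell coordinates (µm, colony-centered) and marker intensities."""

    cells: pd.DataFrame
    colony_id: str
    colony_radius: float

    def __post_init__(self) -> None:
        if self.colony_radius <= 0:
            raise ValueError("colony_radius must be > 0")
        for col in ("x", "y"):
            if col not in self.cells.columns:
                raise ValueError(f"cells table needs an {col!r} column")
        r = np.hypot(self.cells["x"], self.cells["y"])
        if (r > EDGE_TOLERANCE * self.colony_radius).any():
            raise ValueError(
                f"cells beyond {EDGE_TOLERANCE}x the colony radius in "
                f"colony {self.colony_id!r}"
            )

    @property
    def markers(self) -> list[str]:
        return [c for c in self.cells.columns if c not in ("x", "y")]

    def normalized_radius(self) -> np.ndarray:
        r = np.hypot(
            self.cells["x"].to_numpy(dtype=float),
            self.cells["y"].to_numpy(dtype=float),
        )
        return np.clip(r / self.colony_radius, 0.0, 1.0)


@dataclass
class RadialProfile:
    """Annular-bin means (± standard error) of one marker.

    ``se`` is NaN for bins with fewer than two cells; ``mean`` is NaN for
    empty bins.
    """

    marker: str
    bin_edges: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_cells: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "marker": self.marker,
                "mean": self.mean,
                "se": self.se,
                "n_cells": self.n_cells,
            }
        )


def radial_profile(
    cloud: ColonyPointCloud, marker: str, n_bins: int = 20
) -> RadialProfile:
    """Mean marker intensity over equal-width annuli of normalized radius."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(cloud.cells) == 0:
        raise ValueError(f"colony {cloud.colony_id!r} has no cells")
    if marker not in cloud.markers:
        raise KeyError(f"unknown marker {marker!r}")
    r = cloud.normalized_radius()
    intensity = cloud.cells[marker].to_numpy(dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # r == 1 belongs to the last bin
    idx = np.minimum((r * n_bins).astype(int), n_bins - 1)
    mean = np.full(n_bins, np.nan)
    se = np.full(n_bins, np.nan)
    n_cells = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        vals = intensity[idx == b]
        n_cells[b] = vals.size
        if vals.size:
            mean[b] = vals.mean()
        if vals.size >= 2:
            se[b] = vals.std(ddof=1) / math.sqrt(vals.size)
    return RadialProfile(
        marker=marker, bin_edges=edges, mean=mean, se=se, n_cells=n_cells
    )


def normalize_profile(profile: RadialProfile) -> RadialProfile:
    """Scale so the highest radial intensity equals 1 (SEs scaled alike)."""
    if np.all(np.isnan(profile.mean)):
        raise ValueError("profile has no populated bins")
    peak = np.nanmax(profile.mean)
    if peak <= 0:
        raise ValueError("cannot normalize a profile with non-positive peak")
    return replace(profile, mean=profile.mean / peak, se=profile.se / peak)


def profile_auc(profile: RadialProfile) -> tuple[float, float]:
    """Trapezoidal area above the lowest radial intensity, with its SE.

    The baseline is the profile's own minimum bin mean.  Empty bins are
    dropped; the SE is propagated in quadrature through the trapezoid
    weights (bins with undefined SE contribute zero variance).
    """
    ok = ~np.isnan(profile.mean)
    if ok.sum() < 2:
        raise ValueError("need at least two populated bins")
    x = profile.bin_centers[ok]
    y = profile.mean[ok]
    baseline = y.min()
    auc = float(np.trapezoid(y - baseline, x))
    # trapezoid rule as a weighted sum: w_i = (x_{i+1} - x_{i-1}) / 2
    w = np.zeros_like(x)
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    if x.size > 2:
        w[1:-1] = (x[2:] - x[:-2]) / 2.0
    se = profile.se[ok]
    var = np.nansum((w * np.where(np.isnan(se), 0.0, se)) ** 2)
    return auc, float(math.sqrt(var))


def composition_fractions(
    cloud: ColonyPointCloud, thresholds: Mapping[str, float]
) -> dict[str, float]:
    """Fraction of cells strictly above each marker's positivity threshold.

    Thresholds come from negative-control clouds via the same 99.9th
    percentile rule as cytometry gating.  Markers are not mutually
    exclusive, so fractions need not sum to 1.
    """
    if len(cloud.cells) == 0:
        raise ValueError(f"colony {cloud.colony_id!r} has no cells")
    fractions = {}
    for marker, threshold in thresholds.items():
        if marker not in cloud.markers:
            raise KeyError(f"unknown marker {marker!r}")
        values = cloud.cells[marker].to_numpy(dtype=float)
        fractions[marker] = float((values > threshold).mean())
    return fractions


def read_point_clouds(
    cells_csv, colonies_csv
) -> list[ColonyPointCloud]:
    """Read the per-cell CSV (colony_id, x, y, markers...) and the colony
    sheet CSV (colony_id, radius)."""
    cells = pd.read_csv(cells_csv)
    sheet = pd.read_csv(colonies_csv).set_index("colony_id")
    clouds = []
    for cid, sub in cells.groupby("colony_id", sort=True):
        if cid not in sheet.index:
            raise ValueError(f"colony {cid!r} missing from colony sheet")
        clouds.append(
            ColonyPointCloud(
                cells=sub.drop(columns=["colony_id"]).reset_index(drop=True),
                colony_id=str(cid),
                colony_radius=float(sheet.loc[cid, "radius"]),
            )
        )
    return clouds
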