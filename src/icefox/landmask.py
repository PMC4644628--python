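"""Land/sea classification and the coastline.

A :class:`LandMask` wraps a shapely polygon set (land) together with a
coastline geometry. The coastline defaults to the land boundary but can be
given explicitly — useful when the land polygon is a bounded rectangle whose
only physically meaningful edge is the shore.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, MultiPolygon, Point, Polygon
from shapely.geometry.base import BaseGeometry

from .grids import GridGeometry


@dataclass
class LandMask:
    land: BaseGeometry
    coastline: BaseGeometry | None = None
    _grid_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.land.is_empty:
            raise ValueError("land geometry is empty")
        if not self.land.is_valid:
            raise ValueError("land geometry is invalid (self-intersection?)")
        if not isinstance(self.land, (Polygon, MultiPolygon)):
            raise TypeError("land must be a Polygon or MultiPolygon")
        if self.coastline is None:
            self.coastline = self.land.boundary

    def is_land(self, x, y) -> np.ndarray:
        """Vectorized point-in-land test (boundary counts as land)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return shapely.intersects_xy(self.land, x, y)

    def coast_distance(self, x: float, y: float) -> float:
        """Planar distance (m) from a point to the nearest coastline point."""
        return float(self.coastline.distance(Point(x, y)))

    def land_grid(self, geometry: GridGeometry) -> np.ndarray:
        """Boolean (nrows, ncols) array: cell centers on land. Cached per
        grid geometry since hotspot pipelines reuse one shared grid."""
        key = (
            geometry.xll,
            geometry.yll,
            geometry.cell_size,
            geometry.nrows,
            geometry.ncols,
        )
        if key not in self._grid_cache:
            xs = geometry.x_centers
            ys = geometry.y_centers
            xx, yy = np.meshgrid(xs, ys)
            self._grid_cache[key] = self.is_land(xx.ravel(), yy.ravel()).reshape(
                geometry.nrows, geometry.ncols
            )
        return self._grid_cache[key]


def straight_coast_mask(
    coast_length_m: float,
    inland_depth_m: float,
    pad_m: float = 20_000.0,
) -> LandMask:
    """Synthetic landscape: land is the strip y in [0, depth+pad] along a
    straight east-west coastline at y = 0; everything south (y < 0) is sea."""
    land = Polygon(
        [
            (-pad_m, 0.0),
            (coast_length_m + pad_m, 0.0),
            (coast_length_m + pad_m, inland_depth_m + pad_m),
            (-pad_m, inland_depth_m + pad_m),
        ]
    )
    coast = LineString([(-pad_m, 0.0), (coast_length_m + pad_m, 0.0)])
    return LandMask(land=land, coastline=coast)
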