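"""Gap analysis: overlay binary habitat with reserve polygons.

Membership is decided by cell center with a strict interior test (centers on
a reserve boundary count as outside), so inside + outside = total suitable
area holds exactly in cell counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .raster import RasterGrid

__all__ = ["overlay_gap"]


def _validate(polys: list[Polygon], kind: str) -> None:
    for i, p in enumerate(polys):
        if not p.is_valid:
            raise ValueError(f"invalid {kind} polygon at index {i}: {shapely.is_valid_reason(p)}")


def overlay_gap(
    binary: RasterGrid,
    reserves: list[Polygon],
    regions: list[Polygon] | None = None,
) -> pd.DataFrame:
    """Protected vs unprotected suitable habitat, per region plus a total row.

    Returns a table with columns region, suitable_area_km2,
    inside_reserve_km2, outside_reserve_km2, fraction_inside.  Areas are
    habitat-cell counts times the cell area; a habitat cell is "inside" iff
    its center lies strictly inside some reserve polygon.
    """
    vals = binary.values
    if not np.isin(vals[~binary.nodata_mask], (0, 1)).all():
        raise ValueError("binary habitat raster must contain only 0/1")
    _validate(reserves, "reserve")
    if regions is not None:
        _validate(regions, "region")

    habitat = (vals == 1) & ~binary.nodata_mask
    xs, ys = binary.cell_centers()
    hx, hy = xs[habitat], ys[habitat]

    if reserves:
        runion = unary_union(reserves)
        inside = shapely.contains_xy(runion, hx, hy)  # strict interior
    else:
        inside = np.zeros(hx.shape, dtype=bool)

    area = binary.cell_area_km2
    rows = []
    if regions is not None:
        for i, reg in enumerate(regions):
            in_reg = shapely.contains_xy(reg, hx, hy)
            n_suit = int(in_reg.sum())
            n_in = int((in_reg & inside).sum())
            rows.append(_row(f"region_{i}", n_suit, n_in, area))
    rows.append(_row("total", int(habitat.sum()), int(inside.sum()), area))
    return pd.DataFrame(rows)


def _row(region: str, n_suit: int, n_in: int, cell_area: float) -> dict:
    suitable = n_suit * cell_area
    inside = n_in * cell_area
    return {
        "region": region,
        "suitable_area_km2": suitable,
        "inside_reserve_km2": inside,
        "outside_reserve_km2": (n_suit - n_in) * cell_area,
        "fraction_inside": (n_in / n_suit) if n_suit > 0 else 0.0,
    }
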