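"""Multi-criteria corridor scoring and priority-corridor selection.

Each candidate corridor is scored on six metrics — length, mean elevation,
current-flow centrality, forest coverage, distance to residential areas and
distance to nature reserves — each mapped linearly onto [0, 1] by its
dispersion from the optimal end of a configured range.  The metrics group
into three criteria: biophysical (length, elevation), biotic (forest,
centrality) and anthropogenic (residential distance, reserve distance).
Corridors longer than the maximum dispersal distance are removed outright;
the top-k composite scores become the priority habitat corridors (PHCs).

The length rule encodes giant-panda movement ecology: 25 km is the maximum
known dispersal distance (corridors longer than that are removed), 2 km the
within-patch seasonal movement distance (corridors at or below it score 1).
Between the thresholds the score falls linearly as (25 - L) / 25, the
interpolation that yields 0.8 at 5 km and 0.2 at 20 km; the small jump at
2 km (1.0 vs 0.92) is a property of the published rule set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REMOVED",
    "ScoringConfig",
    "CorridorMetrics",
    "score_length",
    "score_elevation",
    "score_minmax",
    "score_corridor",
    "aggregate_and_select",
]


class Removed:
    """Sentinel for corridors struck from the candidate list."""

    def __repr__(self) -> str:  # pragma: no cover
        return "REMOVED"


REMOVED = Removed()

GROUPS = {
    "biophysical": ("length", "elevation"),
    "biotic": ("forest", "centrality"),
    "anthropogenic": ("dist_residential", "dist_reserve"),
}
METRIC_ORDER = ("length", "elevation", "centrality", "forest", "dist_residential", "dist_reserve")


@dataclass
class ScoringConfig:
    """Metric ranges and selection settings.

    Default ranges are the observed spans of the original corridor survey;
    any of them can be recomputed from the candidate set at hand via
    :meth:`with_observed_ranges`.
    """

    length_bounds_km: tuple[float, float] = (2.0, 25.0)
    elevation_optimal_m: tuple[float, float] = (1000.0, 3000.0)
    elevation_extremes_m: tuple[float, float] = (0.0, 4122.0)
    centrality_range: tuple[float, float] = (1.87, 60.83)
    forest_range_pct: tuple[float, float] = (54.0, 100.0)
    dist_residential_range_km: tuple[float, float] = (1.0, 15.0)
    dist_reserve_range_km: tuple[float, float] = (0.0, 49.0)
    top_k: int = 6
    group_threshold: float = 0.75
    metric_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name in ("length_bounds_km", "elevation_optimal_m", "elevation_extremes_m",
                     "centrality_range", "forest_range_pct",
                     "dist_residential_range_km", "dist_reserve_range_km"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an increasing interval")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    def with_observed_ranges(self, metrics: "list[CorridorMetrics]") -> "ScoringConfig":
        """New config with centrality/forest/distance ranges recomputed from
        the observed candidate set (ranges of width zero are widened by 1)."""
        def rng(vals):
            lo, hi = float(np.min(vals)), float(np.max(vals))
            return (lo, hi) if hi > lo else (lo, lo + 1.0)

        return ScoringConfig(
            length_bounds_km=self.length_bounds_km,
            elevation_optimal_m=self.elevation_optimal_m,
            elevation_extremes_m=self.elevation_extremes_m,
            centrality_range=rng([m.centrality for m in metrics]),
            forest_range_pct=rng([m.forest_cover_pct for m in metrics]),
            dist_residential_range_km=rng([m.dist_residential_km for m in metrics]),
            dist_reserve_range_km=rng([m.dist_reserve_km for m in metrics]),
            top_k=self.top_k,
            group_threshold=self.group_threshold,
            metric_weights=self.metric_weights,
        )


@dataclass
class CorridorMetrics:
    """The six raw metrics of one candidate corridor."""

    corridor_id: int
    length_km: float
    mean_elevation_m: float
    centrality: float
    forest_cover_pct: float
    dist_residential_km: float
    dist_reserve_km: float

    def __post_init__(self) -> None:
        if self.length_km <= 0:
            raise ValueError("corridor length must be positive")
        if not 0.0 <= self.forest_cover_pct <= 100.0:
            raise ValueError("forest cover must lie in [0, 100] percent")


def score_length(length_km: float, config: ScoringConfig | None = None):
    """Length score, or :data:`REMOVED` beyond the dispersal maximum.

    >>> score_length(5.0)
    0.8
    """
    config = config or ScoringConfig()
    lo, hi = config.length_bounds_km
    if length_km <= 0:
        raise ValueError("corridor length must be positive")
    if length_km > hi:
        return REMOVED
    if length_km <= lo:
        return 1.0
    return float(np.clip((hi - length_km) / hi, 0.0, 1.0))


def score_elevation(mean_elevation_m: float, config: ScoringConfig | None = None) -> float:
    """1 inside the optimal band, linear decay to 0 at the extremes."""
    config = config or ScoringConfig()
    opt_lo, opt_hi = config.elevation_optimal_m
    ext_lo, ext_hi = config.elevation_extremes_m
    e = mean_elevation_m
    if opt_lo <= e <= opt_hi:
        return 1.0
    if e < opt_lo:
        return float(np.clip((e - ext_lo) / (opt_lo - ext_lo), 0.0, 1.0))
    return float(np.clip((ext_hi - e) / (ext_hi - opt_hi), 0.0, 1.0))


def score_minmax(value: float, vrange: tuple[float, float], direction: str) -> float:
    """Linear [0, 1] rescaling: 'increasing' rewards high values,
    'decreasing' rewards low ones; clipped outside the range."""
    lo, hi = vrange
    if not lo < hi:
        raise ValueError("degenerate range")
    if direction == "increasing":
        s = (value - lo) / (hi - lo)
    elif direction == "decreasing":
        s = (hi - value) / (hi - lo)
    else:
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    return float(np.clip(s, 0.0, 1.0))


def score_corridor(m: CorridorMetrics, config: ScoringConfig):
    """Six unit-interval scores for one corridor, or REMOVED."""
    s_len = score_length(m.length_km, config)
    if s_len is REMOVED:
        return REMOVED
    return {
        "length": s_len,
        "elevation": score_elevation(m.mean_elevation_m, config),
        "centrality": score_minmax(m.centrality, config.centrality_range, "increasing"),
        "forest": score_minmax(m.forest_cover_pct, config.forest_range_pct, "increasing"),
        # closer settlements are worse -> larger distance scores higher
        "dist_residential": score_minmax(
            m.dist_residential_km, config.dist_residential_range_km, "increasing"
        ),
        # farther reserves are worse -> smaller distance scores higher
        "dist_reserve": score_minmax(
            m.dist_reserve_km, config.dist_reserve_range_km, "decreasing"
        ),
    }


def aggregate_and_select(
    metrics: list[CorridorMetrics], config: ScoringConfig | None = None
) -> pd.DataFrame:
    """Score, rank and select priority corridors.

    Corridors beyond the length maximum are removed; the rest get a
    composite score (mean of the six metric scores, optionally weighted),
    per-group means, the set of criterion groups met at the group threshold,
    and a descending rank (ties: higher centrality, then shorter length,
    then id).  The top-k ranked corridors are flagged ``is_phc``.
    """
    config = config or ScoringConfig()
    if not metrics:
        raise ValueError("empty candidate list")
    weights = config.metric_weights or {k: 1.0 for k in METRIC_ORDER}

    rows = []
    for m in metrics:
        scores = score_corridor(m, config)
        if scores is REMOVED:
            continue
        wsum = sum(weights[k] for k in METRIC_ORDER)
        composite = sum(weights[k] * scores[k] for k in METRIC_ORDER) / wsum
        group_scores = {
            g: float(np.mean([scores[k] for k in keys])) for g, keys in GROUPS.items()
        }
        groups_met = sorted(g for g, v in group_scores.items() if v >= config.group_threshold)
        rows.append(
            {
                "corridor_id": m.corridor_id,
                "length_km": m.length_km,
                "mean_elevation_m": m.mean_elevation_m,
                "centrality": m.centrality,
                "forest_cover_pct": m.forest_cover_pct,
                "dist_residential_km": m.dist_residential_km,
                "dist_reserve_km": m.dist_reserve_km,
                **{f"score_{k}": scores[k] for k in METRIC_ORDER},
                **{f"group_{g}": group_scores[g] for g in GROUPS},
                "n_groups_met": len(groups_met),
                "groups_met": "+".join(groups_met) if groups_met else "none",
                "composite": composite,
            }
        )
    if not rows:
        raise ValueError("all candidate corridors were removed by the length rule")
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["composite", "centrality", "length_km", "corridor_id"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["is_phc"] = df["rank"] <= config.top_k
    return df
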