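"""End-to-end pipeline: simulate -> covariates -> habitat -> gaps ->
connect -> prioritize, with per-stage artifacts and a run manifest.

Every stage reads only files written by upstream stages (so stages can be
re-run independently), records its outputs with checksums in
``manifest.json``, and derives its randomness from one root seed split per
stage.  Missing upstream artifacts raise an error naming the stage that
produces them.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import LineString

from . import __version__
from . import circuit, covariates as cov, gaps, landscape as ls, scoring
from .habitat import HabitatSuitabilityModel
from .raster import RasterGrid, read_ascii_grid, write_ascii_grid
from .vectorio import read_geojson, write_geojson

__all__ = ["PipelineConfig", "Pipeline", "STAGES"]

STAGES = ("simulate", "covariates", "habitat", "gaps", "connect", "prioritize")

_PRODUCERS = {
    "elevation.asc": "simulate",
    "landcover.asc": "simulate",
    "true_suitability.asc": "simulate",
    "occurrences.csv": "simulate",
    "patches.geojson": "simulate",
    "reserves.geojson": "simulate",
    "roads.geojson": "simulate",
    "residential.geojson": "simulate",
    "transects.geojson": "simulate",
    "stack": "covariates",
    "vif.csv": "covariates",
    "suitability.asc": "habitat",
    "habitat_binary.asc": "habitat",
    "model_evals.csv": "habitat",
    "habitat_manifest.json": "habitat",
    "gap_report.csv": "gaps",
    "corridor_metrics.csv": "connect",
    "corridors.geojson": "connect",
    "cumulative_current.asc": "connect",
    "scored_corridors.csv": "prioritize",
    "phcs.geojson": "prioritize",
    "venn_summary.csv": "prioritize",
}


class MissingArtifactError(FileNotFoundError):
    """An upstream artifact is absent; the message names the producing stage."""


@dataclass
class PipelineConfig:
    """Fully-resolved pipeline configuration (one YAML file mirrors this)."""

    landscape: ls.LandscapeConfig = field(default_factory=ls.LandscapeConfig)
    # habitat modeling
    n_repeats: int = 10
    train_fraction: float = 0.7
    auc_cutoff: float = 0.85
    tss_cutoff: float = 0.85
    weighting: str = "tss"
    # connectivity
    epsilon: float = 1e-3
    neighborhood: int = 8
    cutoff_fraction: float = 0.2
    # prioritization
    top_k: int = 6
    group_threshold: float = 0.75
    max_length_km: float = 25.0
    use_observed_ranges: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        land = raw.pop("landscape", {})
        if "elevation_range_m" in land:
            land["elevation_range_m"] = tuple(land["elevation_range_m"])
        flat = {}
        for section in ("habitat", "connectivity", "scoring"):
            flat.update(raw.pop(section, {}))
        flat.update(raw)
        return cls(landscape=ls.LandscapeConfig(**land), **flat)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "landscape"}
        d["landscape"] = self.landscape.to_dict()
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Pipeline:
    """Stage runner over one output directory."""

    def __init__(self, config: PipelineConfig, outdir, seed: int | None = None):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        if seed is not None:
            self.config.landscape.random_seed = int(seed)
        self.seed = self.config.landscape.random_seed
        self._manifest_path = self.outdir / "manifest.json"

    # -- seeds: one root seed, split per stage ------------------------------

    def _stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    # -- manifest -----------------------------------------------------------

    def _load_manifest(self) -> dict:
        if self._manifest_path.exists():
            return json.loads(self._manifest_path.read_text())
        cfg_json = json.dumps(self.config.to_dict(), sort_keys=True)
        return {
            "version": __version__,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "stages": {},
            "files": {},
        }

    def _record(self, stage: str, outputs: list[Path], elapsed: float) -> None:
        manifest = self._load_manifest()
        manifest["stages"][stage] = {"elapsed_s": round(elapsed, 3)}
        for p in outputs:
            manifest["files"][p.name] = {"stage": stage, "sha256": _sha256(p)}
        self._manifest_path.write_text(json.dumps(manifest, indent=2))

    def _require(self, *names: str) -> None:
        for name in names:
            if not (self.outdir / name).exists():
                raise MissingArtifactError(
                    f"missing artifact '{name}'; run the "
                    f"'{_PRODUCERS.get(name, '?')}' stage first"
                )

    # -- stages -------------------------------------------------------------

    def run_stage(self, stage: str) -> list[Path]:
        if stage not in STAGES:
            raise ValueError(f"unknown stage '{stage}'; choose from {STAGES}")
        t0 = time.perf_counter()
        outputs = getattr(self, f"_stage_{stage}")()
        self._record(stage, outputs, time.perf_counter() - t0)
        return outputs

    def run_all(self) -> None:
        for stage in STAGES:
            self.run_stage(stage)

    def _stage_simulate(self) -> list[Path]:
        cfg = self.config.landscape
        elev = ls.generate_terrain(cfg)
        lc = ls.generate_landcover(cfg, elev)
        feats = ls.place_features(cfg, elev)
        transects = ls.generate_transects(cfg, elev)
        stack = cov.build_stack(elev, lc, feats)
        truth = ls.TrueSuitability().evaluate(stack)
        rng = np.random.default_rng(self._stage_seed("simulate"))
        occ = ls.sample_occurrences(truth, transects, cfg, rng)

        out = self.outdir
        write_ascii_grid(elev, out / "elevation.asc")
        write_ascii_grid(lc, out / "landcover.asc")
        write_ascii_grid(truth, out / "true_suitability.asc")
        occ.to_csv(out / "occurrences.csv")
        write_geojson(feats.patches, out / "patches.geojson",
                      [{"patch_id": i} for i in range(len(feats.patches))])
        write_geojson(feats.reserves, out / "reserves.geojson")
        write_geojson(feats.roads, out / "roads.geojson")
        write_geojson(feats.residential, out / "residential.geojson")
        write_geojson([t.as_linestring() for t in transects], out / "transects.geojson",
                      [{"transect_id": t.id, "length_m": t.length_m} for t in transects])
        return [out / n for n in (
            "elevation.asc", "landcover.asc", "true_suitability.asc", "occurrences.csv",
            "patches.geojson", "reserves.geojson", "roads.geojson",
            "residential.geojson", "transects.geojson")]

    def _load_features(self) -> ls.LandscapeFeatures:
        self._require("patches.geojson", "reserves.geojson", "roads.geojson",
                      "residential.geojson", "elevation.asc")
        patches, _ = read_geojson(self.outdir / "patches.geojson")
        reserves, _ = read_geojson(self.outdir / "reserves.geojson")
        roads, _ = read_geojson(self.outdir / "roads.geojson")
        residential, _ = read_geojson(self.outdir / "residential.geojson")
        elev = read_ascii_grid(self.outdir / "elevation.asc")
        patch_cells = [np.argwhere(cov.rasterize_features([p], elev)) for p in patches]
        return ls.LandscapeFeatures(patches, patch_cells, reserves, roads, residential)

    def _load_stack(self) -> dict[str, RasterGrid]:
        missing = [f"stack_{n}.asc" for n in cov.STACK_LAYERS
                   if not (self.outdir / f"stack_{n}.asc").exists()]
        if missing:
            raise MissingArtifactError(
                f"missing covariate layers {missing}; run the 'covariates' stage first")
        return {n: read_ascii_grid(self.outdir / f"stack_{n}.asc") for n in cov.STACK_LAYERS}

    def _stage_covariates(self) -> list[Path]:
        self._require("elevation.asc", "landcover.asc", "occurrences.csv")
        elev = read_ascii_grid(self.outdir / "elevation.asc")
        lc = read_ascii_grid(self.outdir / "landcover.asc")
        feats = self._load_features()
        stack = cov.build_stack(elev, lc.like(lc.values.astype(int)), feats)
        outputs = []
        for name, grid in stack.items():
            p = self.outdir / f"stack_{name}.asc"
            write_ascii_grid(grid, p)
            outputs.append(p)
        occ = ls.OccurrenceSet.from_csv(self.outdir / "occurrences.csv")
        design = cov.design_matrix(stack, occ.records[["x", "y"]].to_numpy())
        report = cov.compute_vif(design)
        report.to_csv(self.outdir / "vif.csv")
        outputs.append(self.outdir / "vif.csv")
        return outputs

    def _stage_habitat(self) -> list[Path]:
        self._require("occurrences.csv")
        stack = self._load_stack()
        occ = ls.OccurrenceSet.from_csv(self.outdir / "occurrences.csv")
        model = HabitatSuitabilityModel(occ, stack)
        res = model.fit(
            n_repeats=self.config.n_repeats,
            train_fraction=self.config.train_fraction,
            auc_cutoff=self.config.auc_cutoff,
            tss_cutoff=self.config.tss_cutoff,
            weighting=self.config.weighting,
            seed=self._stage_seed("habitat"),
        )
        product = res.binarize()
        out = self.outdir
        write_ascii_grid(product.continuous, out / "suitability.asc")
        write_ascii_grid(product.binary, out / "habitat_binary.asc")
        product.evals.to_csv(out / "model_evals.csv", index=False)
        (out / "habitat_manifest.json").write_text(json.dumps({
            "threshold": product.threshold,
            "included_models": product.included_models,
            "weights": res.weights,
        }, indent=2))
        return [out / n for n in ("suitability.asc", "habitat_binary.asc",
                                  "model_evals.csv", "habitat_manifest.json")]

    def _stage_gaps(self) -> list[Path]:
        self._require("habitat_binary.asc", "reserves.geojson")
        binary = read_ascii_grid(self.outdir / "habitat_binary.asc")
        reserves, _ = read_geojson(self.outdir / "reserves.geojson")
        report = gaps.overlay_gap(binary, reserves)
        report.to_csv(self.outdir / "gap_report.csv", index=False)
        return [self.outdir / "gap_report.csv"]

    def _stage_connect(self) -> list[Path]:
        self._require("suitability.asc", "patches.geojson")
        suit = read_ascii_grid(self.outdir / "suitability.asc")
        stack = self._load_stack()
        feats = self._load_features()
        resist = circuit.build_resistance(suit, self.config.epsilon)
        graph = circuit.build_graph(resist, self.config.neighborhood, feats.patch_cells)

        n_patch = len(feats.patch_cells)
        pairs = list(combinations(range(n_patch), 2))
        cum = np.zeros(suit.shape)
        corridors, links, rows = [], [], []
        for cid, (i, j) in enumerate(pairs):
            sol = circuit.solve_pair(graph, graph.patch_nodes[i], graph.patch_nodes[j])
            cum += sol.current_map.values
            geom = circuit.extract_corridor(
                graph, i, j, cutoff_fraction=self.config.cutoff_fraction)
            corridors.append(geom)
            links.append((i, j, geom.lcp_cost))
            rows.append({
                "corridor_id": cid, "patch_a": i, "patch_b": j,
                "length_km": geom.length_km, "lcp_cost": geom.lcp_cost,
                "effective_resistance": sol.effective_resistance,
            })
        cent = circuit.corridor_centrality(n_patch, links)

        lc = stack["forest_composition"].values
        for row, geom in zip(rows, corridors):
            mask = geom.corridor_mask
            row["centrality"] = cent[tuple(sorted(geom.pair))]
            row["mean_elevation_m"] = float(stack["elevation"].values[mask].mean())
            forest = np.isin(lc[mask], ls.FOREST_CLASSES)
            row["forest_cover_pct"] = float(100.0 * forest.mean())
            row["dist_residential_km"] = float(
                stack["dist_residential"].values[mask].min() / 1000.0)
            row["dist_reserve_km"] = float(stack["dist_reserve"].values[mask].min() / 1000.0)

        df = pd.DataFrame(rows)
        df.to_csv(self.outdir / "corridor_metrics.csv", index=False)
        write_geojson(
            [LineString(g.path_xy) for g in corridors],
            self.outdir / "corridors.geojson",
            [{"corridor_id": r["corridor_id"], "length_km": r["length_km"]} for r in rows],
        )
        write_ascii_grid(suit.like(cum), self.outdir / "cumulative_current.asc")
        return [self.outdir / n for n in
                ("corridor_metrics.csv", "corridors.geojson", "cumulative_current.asc")]

    def _stage_prioritize(self) -> list[Path]:
        self._require("corridor_metrics.csv", "corridors.geojson")
        df = pd.read_csv(self.outdir / "corridor_metrics.csv")
        metrics = [
            scoring.CorridorMetrics(
                corridor_id=int(r.corridor_id), length_km=float(r.length_km),
                mean_elevation_m=float(r.mean_elevation_m), centrality=float(r.centrality),
                forest_cover_pct=float(r.forest_cover_pct),
                dist_residential_km=float(r.dist_residential_km),
                dist_reserve_km=float(r.dist_reserve_km),
            )
            for r in df.itertuples()
        ]
        cfg = scoring.ScoringConfig(
            length_bounds_km=(2.0, self.config.max_length_km),
            top_k=self.config.top_k,
            group_threshold=self.config.group_threshold,
        )
        survivors = [m for m in metrics if m.length_km <= self.config.max_length_km]
        if self.config.use_observed_ranges and survivors:
            cfg = cfg.with_observed_ranges(survivors)
        scored = scoring.aggregate_and_select(metrics, cfg)
        scored.to_csv(self.outdir / "scored_corridors.csv", index=False)

        geoms, props = read_geojson(self.outdir / "corridors.geojson")
        by_id = {p["corridor_id"]: g for g, p in zip(geoms, props)}
        phc = scored[scored["is_phc"]]
        write_geojson(
            [by_id[int(cid)] for cid in phc["corridor_id"]],
            self.outdir / "phcs.geojson",
            [{"corridor_id": int(r.corridor_id), "rank": int(r.rank),
              "composite": float(r.composite)} for r in phc.itertuples()],
        )
        venn = (scored.groupby("groups_met").size().rename("n_corridors")
                .reset_index())
        venn.to_csv(self.outdir / "venn_summary.csv", index=False)
        return [self.outdir / n for n in
                ("scored_corridors.csv", "phcs.geojson", "venn_summary.csv")]
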