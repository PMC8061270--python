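"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order: diversity stats → FST (+ panmixia test) →
population graph → network metrics → landscape tests → MLPE regression.
Inputs come either from files (VCF/CSV genotypes, locale CSV, ASCII-grid
rasters) or from a synthetic scenario.  Every run writes its artifacts plus
a machine-readable manifest (parameters, seeds, file hashes) so two runs are
byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import DegenerateInputError, SNPDataset
from . import popgen, popgraph, netmetrics, landscape, mlpe, synthetic

log = logging.getLogger("landgraph")

STAGES = ("stats", "fst", "graph", "netmetrics", "landscape", "mlpe")


@dataclass
class RunConfig:
    """One run: inputs (files or a synthetic scenario), toggles, parameters."""

    output_dir: str = "landgraph_out"
    seed: int = 0
    # either a scenario ...
    scenario: synthetic.SyntheticScenario | None = None
    # ... or file inputs
    genotypes_path: str | None = None
    genotypes_format: str = "csv"  # csv | vcf
    locale_map_path: str | None = None  # sample_id,locale_id (vcf only)
    locales_path: str | None = None  # locale_id,x,y
    ploidy: int = 1
    n_sites_surveyed: int | None = None
    raster_paths: dict = field(default_factory=dict)  # name -> .asc path
    categorical_rasters: list = field(default_factory=list)  # names
    # stage toggles / parameters
    stages: list = field(default_factory=lambda: list(STAGES))
    alpha: float = 0.05
    n_perm: int = 1000
    panmixia_test: bool = False
    netmetric_focus: list | None = None
    netmetric_metric: str = "closeness"
    netmetric_null: str = "edge_permutation"
    landscape_statistic: str = "mean"
    tail: str = "two-sided"
    mlpe_models: list = field(default_factory=list)  # list of predictor lists

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "scenario" in d and d["scenario"] is not None:
            sc = d["scenario"]
            sc["ancestral_freq_range"] = tuple(sc.get("ancestral_freq_range", (0.1, 0.9)))
            sc["raster_extent"] = tuple(sc.get("raster_extent", (60, 100)))
            d["scenario"] = synthetic.SyntheticScenario(**sc)
        return cls(**d)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}")
        if self.scenario is None:
            if not self.genotypes_path:
                raise ValueError("either a scenario or genotypes_path is required")
            if not Path(self.genotypes_path).exists():
                raise FileNotFoundError(self.genotypes_path)
            if ("landscape" in self.stages or "mlpe" in self.stages) and not self.locales_path:
                raise ValueError("locales_path required for landscape/mlpe stages")
            if self.locales_path and not Path(self.locales_path).exists():
                raise FileNotFoundError(self.locales_path)
        for name, p in self.raster_paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"raster {name!r}: {p}")
        if "landscape" in self.stages and self.scenario is None and not self.raster_paths:
            raise ValueError("landscape stage enabled but no rasters supplied")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: RunConfig):
    if cfg.scenario is not None:
        dataset, locales = synthetic.simulate_snp_dataset(cfg.scenario)
        rasters = {
            "gradient": synthetic.make_landscape(
                cfg.scenario, "gradient", direction="east", low=0.0, high=100.0
            ),
            "patches": synthetic.make_landscape(
                cfg.scenario, "categorical_patches", n_classes=4
            ),
        }
        return dataset, locales, rasters
    if cfg.genotypes_format == "vcf":
        if not cfg.locale_map_path:
            raise ValueError("VCF input needs locale_map_path (sample_id,locale_id)")
        dataset = SNPDataset.read_vcf(
            cfg.genotypes_path, cfg.locale_map_path, cfg.ploidy, cfg.n_sites_surveyed
        )
    else:
        dataset = SNPDataset.read_csv(
            cfg.genotypes_path, cfg.ploidy, cfg.n_sites_surveyed
        )
    locales = pd.read_csv(cfg.locales_path) if cfg.locales_path else None
    rasters = {
        name: landscape.read_ascii_grid(
            p, kind="categorical" if name in cfg.categorical_rasters else "continuous"
        )
        for name, p in cfg.raster_paths.items()
    }
    return dataset, locales, rasters


def run(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the report dict.

    Artifacts and a run manifest land in ``cfg.output_dir``.  The first
    failing stage aborts with a stage-qualified error; artifacts written
    before the failure are retained.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "landgraph_version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "alpha": cfg.alpha,
            "n_perm": cfg.n_perm,
            "tail": cfg.tail,
            "stages": list(cfg.stages),
        },
        "stage_seconds": {},
        "warnings": [],
        "outputs": {},
    }
    if cfg.scenario is not None:
        cfg.scenario.to_yaml(out / "scenario.yaml")
        manifest["scenario"] = asdict(cfg.scenario)
    report: dict = {s: None for s in STAGES}
    dataset, locales, rasters = _load_inputs(cfg)
    graph = None
    fst_matrix = None

    def _stage(name):
        return name in cfg.stages

    try:
        if _stage("stats"):
            t0 = time.perf_counter()
            overall = popgen.diversity_stats(dataset)
            per_locale = []
            for loc in dataset.locales:
                try:
                    s = popgen.diversity_stats(dataset, loc)
                    per_locale.append(
                        dict(locale_id=loc, theta_pi=s.theta_pi, theta_s=s.theta_s,
                             S=s.S, tajimas_d=s.tajimas_d, n=s.n)
                    )
                except Exception as exc:  # degenerate locale
                    manifest["warnings"].append(f"stats[{loc}]: {exc}")
            df = pd.DataFrame(per_locale)
            df.to_csv(out / "diversity_per_locale.csv", index=False)
            report["stats"] = {
                "theta_pi": overall.theta_pi,
                "theta_s": overall.theta_s,
                "S": overall.S,
                "tajimas_d": overall.tajimas_d,
                "n_alleles": overall.n,
            }
            manifest["stage_seconds"]["stats"] = time.perf_counter() - t0

        if _stage("fst"):
            t0 = time.perf_counter()
            fst_matrix, global_f = popgen.pairwise_fst_matrix(dataset)
            fst_matrix.write_csv(out / "fst_matrix.csv")
            report["fst"] = {"global_fst": global_f}
            if cfg.panmixia_test:
                pan = popgen.panmixia_permutation(
                    dataset, n_perm=cfg.n_perm, seed=cfg.seed
                )
                pan.p_matrix.write_csv(out / "panmixia_p.csv")
                frac = float(np.nanmean(pan.p_matrix.condensed() <= 0.05))
                report["fst"]["panmixia_frac_p_le_05"] = frac
            manifest["stage_seconds"]["fst"] = time.perf_counter() - t0

        if _stage("graph"):
            t0 = time.perf_counter()
            graph = popgraph.build_popgraph(dataset, alpha=cfg.alpha)
            popgraph.write_graphml(graph, out / "popgraph.graphml")
            popgraph.write_edges_csv(graph, out / "popgraph_edges.csv")
            cgd = popgraph.cgd_matrix(graph)
            cgd.write_csv(out / "cgd_matrix.csv")
            report["graph"] = {
                "n_nodes": graph.number_of_nodes(),
                "n_edges": graph.number_of_edges(),
                "isolated": popgraph.isolated_nodes(graph),
                "shrinkage": graph.graph.get("shrinkage", 0.0),
            }
            manifest["stage_seconds"]["graph"] = time.perf_counter() - t0

        if _stage("netmetrics"):
            t0 = time.perf_counter()
            if graph is None:
                raise RuntimeError("netmetrics stage requires the graph stage")
            nm = netmetrics.node_metrics(graph)
            nm.to_csv(out / "node_metrics.csv", index_label="locale_id")
            try:
                res = netmetrics.metric_permutation_test(
                    graph,
                    metric=cfg.netmetric_metric,
                    focus=cfg.netmetric_focus,
                    n_perm=cfg.n_perm,
                    seed=cfg.seed,
                    null_model=cfg.netmetric_null,
                    tail=cfg.tail,
                )
                (out / "netmetric_test.json").write_text(json.dumps(res.to_dict()))
                report["netmetrics"] = {
                    "metric": cfg.netmetric_metric,
                    "observed": res.observed,
                    "p_value": res.p_value,
                }
            except DegenerateInputError as exc:
                manifest["warnings"].append(f"netmetrics: {exc}")
                report["netmetrics"] = {
                    "metric": cfg.netmetric_metric, "skipped": str(exc)
                }
            manifest["stage_seconds"]["netmetrics"] = time.perf_counter() - t0

        if _stage("landscape"):
            t0 = time.perf_counter()
            if graph is None:
                raise RuntimeError("landscape stage requires the graph stage")
            geo = landscape.geographic_distance_matrix(locales)
            geo.write_csv(out / "geo_matrix.csv")
            land_report = {}
            for name, ras in rasters.items():
                stat = (
                    cfg.landscape_statistic
                    if ras.kind == "continuous"
                    else f"category:{sorted(ras.class_table)[0] if ras.class_table else 0}"
                )
                try:
                    res = landscape.landscape_permutation_test(
                        graph, ras, locales, statistic=stat,
                        n_perm=cfg.n_perm, seed=cfg.seed, tail=cfg.tail,
                    )
                except DegenerateInputError as exc:
                    manifest["warnings"].append(f"landscape[{name}]: {exc}")
                    land_report[name] = {"statistic": stat, "skipped": str(exc)}
                    continue
                (out / f"landscape_test_{name}.json").write_text(
                    json.dumps(res.to_dict())
                )
                land_report[name] = {
                    "statistic": stat,
                    "observed": res.observed,
                    "p_value": res.p_value,
                }
            report["landscape"] = land_report
            manifest["stage_seconds"]["landscape"] = time.perf_counter() - t0

        if _stage("mlpe"):
            t0 = time.perf_counter()
            if fst_matrix is None:
                raise RuntimeError("mlpe stage requires the fst stage")
            geo = landscape.geographic_distance_matrix(locales)
            summaries = {
                name: landscape.edge_resistance_summary(
                    ras, fst_matrix.pairs(), locales
                )
                for name, ras in rasters.items()
                if ras.kind == "continuous"
            }
            table = mlpe.build_pair_table(fst_matrix, geo, summaries)
            table.write_csv(out / "pair_table.csv")
            models = cfg.mlpe_models or [
                ["geographic_distance"],
                table.predictors,
            ]
            fits = [mlpe.fit_mlpe(table, prds) for prds in models]
            ranking = mlpe.compare_models_aic(fits)
            ranking.to_csv(out / "mlpe_ranking.csv", index=False)
            report["mlpe"] = {
                "best_model": ranking["model"].iloc[0],
                "ranking": ranking.to_dict(orient="records"),
            }
            manifest["stage_seconds"]["mlpe"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"stage failure: {exc}") from exc

    write_report(report, out / "report.json")
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


def write_report(report: dict, path: str | Path) -> dict:
    """Single JSON aggregating all stage outputs (absent stages stay null)."""
    full = {s: report.get(s) for s in STAGES}
    Path(path).write_text(json.dumps(full, indent=2, sort_keys=True, default=float))
    return full
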