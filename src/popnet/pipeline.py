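"""End-to-end pipeline: generate (or load) a register panel, build the six
layers, and write every report table with a manifest.

The run is fully deterministic given the configured seed: the generator,
each affiliation layer, the path-length source sample, the closeness
sample and the tie-range census sample all draw from seeded streams
derived from it, and every output is written with fixed formatting so a
re-run is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import closure as closure_mod
from . import connectivity as conn_mod
from . import network as net_mod
from . import profiles as prof_mod
from .layers import LAYERS, build_all_layers
from .registry import (
    GeneratorConfig,
    analysis_year_frame,
    config_to_dict,
    generate_population,
    read_registry,
    write_registry,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclasses.dataclass
class PipelineConfig:
    generator: GeneratorConfig = dataclasses.field(default_factory=GeneratorConfig)
    analysis_year: int = 2017
    seed: int = 0
    n_path_sources: int = 500
    closeness_sample_size: int = 300
    tie_range_max_edges: int | None = 4000
    compute_diameter: bool = True


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    *,
    registry_path: str | Path | None = None,
    generate: bool = True,
) -> dict:
    """Run every stage and write the report bundle under ``out_dir``.

    Returns the manifest dict (also written as ``manifest.json``).  Any
    stage failure is re-raised annotated with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "layers").mkdir(exist_ok=True)
    manifest: dict = {
        "config": {
            "generator": config_to_dict(config.generator),
            "analysis_year": config.analysis_year,
            "seed": config.seed,
            "n_path_sources": config.n_path_sources,
            "closeness_sample_size": config.closeness_sample_size,
            "tie_range_max_edges": config.tie_range_max_edges,
        },
        "stages": {},
    }
    ss = np.random.SeedSequence(config.seed)
    s_layers, s_paths, s_close, s_ties = ss.spawn(4)

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            dt = time.perf_counter() - t0
            # timings are logged, not persisted: the manifest must be
            # byte-identical across re-runs
            manifest["stages"][name] = "ok"
            logger.info("stage %s done in %.2fs", name, dt)
            return result

        return deco

    @stage("registry")
    def registry():
        if registry_path is not None:
            return read_registry(registry_path)
        if not generate:
            raise ValueError("no registry_path given and generate=False")
        df = generate_population(config.generator)
        write_registry(df, out / "registry.csv")
        return df

    @stage("layers")
    def layers():
        return build_all_layers(registry, config.analysis_year, seed=s_layers)

    snapshot = analysis_year_frame(registry, config.analysis_year)
    vertices = snapshot["person_id"].to_numpy()

    @stage("network")
    def network():
        return net_mod.MultilayerNetwork(vertices, layers, layers=LAYERS)

    @stage("layer_tables")
    def layer_tables():
        combined = []
        for l in LAYERS:
            df = layers[l][["u", "v", "subtype"]]
            _write(df, out / "layers" / f"{l}.csv")
            combined.append(df.assign(layer=l))
        _write(pd.concat(combined, ignore_index=True), out / "layers" / "combined.csv")

    @stage("degree_stats")
    def degree_stats():
        summary = net_mod.degree_distributions(network)
        corr = net_mod.layer_degree_correlation(network)
        overlap = net_mod.edge_overlap_matrix(network)
        corr.to_csv(out / "layer_degree_correlation.csv", float_format=_FLOAT_FMT)
        overlap.to_csv(out / "layer_edge_overlap.csv", float_format=_FLOAT_FMT)
        hist = pd.concat(
            [s.rename("count").rename_axis("degree").reset_index().assign(layer=l)
             for l, s in summary.layer_histograms.items()]
            + [summary.total_histogram.rename("count").rename_axis("degree")
               .reset_index().assign(layer="total"),
               summary.flattened_histogram.rename("count").rename_axis("degree")
               .reset_index().assign(layer="flattened")],
            ignore_index=True,
        )
        _write(hist, out / "degree_histograms.csv")
        _write(
            summary.active_layer_histogram.rename("count")
            .rename_axis("active_layers").reset_index(),
            out / "active_layer_histogram.csv",
        )
        slopes = pd.DataFrame(
            {"layer": list(summary.tail_slopes), "tail_slope": list(summary.tail_slopes.values())}
        )
        _write(slopes, out / "tail_slopes.csv")
        disc = pd.DataFrame(
            {"layer": list(summary.disconnected), "disconnected": list(summary.disconnected.values())}
        )
        _write(disc, out / "disconnected_per_layer.csv")
        return summary

    @stage("connectivity")
    def connectivity():
        table = conn_mod.layer_accumulation_table(
            network,
            seed=int(s_paths.generate_state(1)[0] % (2**31)),
            n_sources=config.n_path_sources,
            compute_diameter=config.compute_diameter,
        )
        _write(table, out / "connectivity_table.csv")
        return table

    @stage("closeness")
    def closeness():
        series = conn_mod.closeness_sampled(
            network,
            seed=int(s_close.generate_state(1)[0] % (2**31)),
            sample_size=config.closeness_sample_size,
        )
        _write(
            series.rename_axis("person_id").reset_index(),
            out / "closeness_sample.csv",
        )
        return series

    @stage("closure")
    def closure():
        prof = closure_mod.closure_profiles(network)
        _write(prof, out / "closure_profiles.csv")
        _write(closure_mod.closure_by_degree(prof), out / "closure_by_degree.csv")
        emb = closure_mod.embeddedness_table(network)
        emb_hist = (
            emb["embeddedness"].value_counts().sort_index()
            .rename("count").rename_axis("embeddedness").reset_index()
        )
        _write(emb_hist, out / "embeddedness_histogram.csv")
        census = closure_mod.wormhole_census(
            network,
            max_edges=config.tie_range_max_edges,
            seed=int(s_ties.generate_state(1)[0] % (2**31)),
        )
        _write(
            census.tie_range_histogram.rename("count")
            .rename_axis("tie_range").reset_index(),
            out / "tie_range_histogram.csv",
        )
        counts = pd.DataFrame(
            [{k: getattr(census, k) for k in
              ("n_edges", "n_zero_embedded", "n_qualifying", "n_examined",
               "n_wormholes", "n_unreachable")}]
        )
        _write(counts, out / "wormhole_census.csv")
        return prof

    @stage("profiles")
    def profiles():
        attrs = prof_mod.person_attributes(snapshot, config.analysis_year)
        for name in prof_mod.STRATIFIERS:
            p = prof_mod.stratified_profile(
                network,
                attrs,
                name,
                excess=closure["c_excess"].to_numpy(),
                closeness=closeness,
            )
            _write(p.table, out / f"profile_{name}.csv")

    files = sorted(p for p in out.rglob("*.csv"))
    manifest["outputs"] = {str(p.relative_to(out)): _md5(p) for p in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
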