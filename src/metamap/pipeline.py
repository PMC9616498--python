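"""End-to-end run configuration and orchestration.

A :class:`RunConfig` is a single JSON-serializable document describing one
analysis: where the graph and metadata come from (files or a built-in
synthetic generator), the encoding model and its parameters, how to build
the encoding graph, and the optimizer settings.  :func:`run_pipeline`
executes the stages, writes all artifacts (flow graph TSV, partition in
.clu and TSV, metrics JSON, log) into the output directory, and returns a
summary.  A single master seed deterministically spawns per-stage seeds,
so rerunning an identical config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import io as mio
from .encoding import closed_form_encoding_graph, monte_carlo_encoding_graph
from .graph import stationary_distribution
from .mapeq import codelength, optimize
from .metadata import CategoricalParams, ContinuousParams, epsilon_matrix
from .metrics import class_overlap, mixing_ratio, quantile_bin
from .synthetic import clique_benchmark, reshuffle_metadata, ring_model

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("metamap")


class SyntheticConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    model: Literal["clique", "ring"]
    n_nodes: int = 240
    n_communities: int = 8
    p1: float = 0.6
    p2: float = 0.2
    d_c: int = 1
    n_reshuffles: int = 0


class EncodingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    model: Literal["categorical", "continuous"] = "categorical"
    p: float = 1.0
    c: float = 1.0
    b: float = 1.0
    s: float = 1.0
    standardize: bool = True
    continuous_form: Literal["literal", "factored"] = "literal"

    def params(self):
        if self.model == "categorical":
            return CategoricalParams(p=self.p, c=self.c)
        return ContinuousParams(
            p=self.p, b=self.b, s=self.s,
            standardize=self.standardize, form=self.continuous_form,
        )


class ConstructionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: Literal["closed_form", "monte_carlo"] = "closed_form"
    tol: float = 1e-10
    t_max: int = 100_000
    n_walks: int = 1_000_000
    max_steps: int = 10_000


class OptimizerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_trials: int = 100
    max_modules: Optional[int] = None


class RunConfig(BaseModel):
    """Complete, reproducible description of one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    graph: Optional[str] = None
    graph_format: Optional[Literal["edgelist", "pajek"]] = None
    directed: bool = False
    metadata: Optional[str] = None
    metadata_kind: Optional[Literal["categorical", "continuous"]] = None
    synthetic: Optional[SyntheticConfig] = None
    encoding: EncodingConfig = Field(default_factory=EncodingConfig)
    construction: ConstructionConfig = Field(default_factory=ConstructionConfig)
    optimizer: OptimizerConfig = Field(default_factory=OptimizerConfig)
    seed: int = 1
    output_dir: str = "metamap_run"

    @model_validator(mode="after")
    def _check_source(self) -> "RunConfig":
        file_input = self.graph is not None
        if file_input == (self.synthetic is not None):
            raise ValueError("exactly one of 'graph' or 'synthetic' must be given")
        if file_input and self.metadata is None:
            raise ValueError("file input requires 'metadata'")
        return self

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())


def _load_inputs(config: RunConfig, seeds):
    if config.synthetic is not None:
        sc = config.synthetic
        if sc.model == "clique":
            graph, meta = clique_benchmark(seed=int(seeds[0]))
        else:
            graph, meta, planted = ring_model(
                n_nodes=sc.n_nodes, n_communities=sc.n_communities,
                p1=sc.p1, p2=sc.p2, seed=int(seeds[0]),
            )
            if sc.n_reshuffles:
                meta = reshuffle_metadata(
                    meta, planted, d_c=sc.d_c,
                    n_steps=sc.n_reshuffles, seed=int(seeds[1]),
                )
        return graph, meta
    graph = mio.read_graph(config.graph, fmt=config.graph_format, directed=config.directed)
    meta = mio.read_metadata(config.metadata, kind=config.metadata_kind)
    return graph, meta


def run_pipeline(config: RunConfig) -> dict:
    """Run encode -> partition -> metrics and write all artifacts.

    Returns the run summary (also written as ``summary.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_json = config.model_dump_json(indent=2)
    config_hash = hashlib.sha256(config_json.encode()).hexdigest()[:16]
    (out / "config.json").write_text(config_json)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("numpy %s, scipy %s", np.__version__, __import__("scipy").__version__)
        logger.info("config hash %s", config_hash)
        seeds = [int(s % 2**31) for s in
                 np.random.SeedSequence(config.seed).generate_state(4)]

        t0 = time.perf_counter()
        graph, meta = _load_inputs(config, seeds)
        logger.info("inputs: %d nodes, %d edges (%.2fs)",
                    graph.n_nodes, graph.n_edges, time.perf_counter() - t0)

        t0 = time.perf_counter()
        params = config.encoding.params()
        eps = epsilon_matrix(graph, meta, params)
        p_stat = stationary_distribution(graph)
        cc = config.construction
        if cc.mode == "closed_form":
            flow_graph = closed_form_encoding_graph(
                graph, eps, p_stat, tol=cc.tol, t_max=cc.t_max
            )
        else:
            flow_graph = monte_carlo_encoding_graph(
                graph, eps, p_stat, n_walks=cc.n_walks,
                seed=seeds[2], max_steps=cc.max_steps,
            )
        flow_graph.to_tsv(out / "flows.tsv")
        logger.info("encoding graph: %d flows, total %.12f (%.2fs)",
                    flow_graph.flows.nnz, flow_graph.total(), time.perf_counter() - t0)

        t0 = time.perf_counter()
        part = optimize(
            flow_graph, n_trials=config.optimizer.n_trials,
            seed=seeds[3], max_modules=config.optimizer.max_modules,
        )
        mio.write_partition(part, out / "partition.tsv", fmt="tsv")
        mio.write_partition(part, out / "partition.clu", fmt="clu")
        logger.info("partition: %d modules, codelength %.6f bits (%.2fs)",
                    part.n_modules, part.codelength, time.perf_counter() - t0)

        meta_cat = meta if meta.kind == "categorical" else quantile_bin(meta)
        r_m = mixing_ratio(part, meta_cat)
        overlap = class_overlap(part, meta_cat)
        metrics = {
            "r_m": r_m.value,
            "r_m_per_category": {str(k): v for k, v in r_m.per_category.items()},
            "overlap_categories": list(overlap.categories),
            "m": overlap.m.tolist(),
            "m_tilde": overlap.m_tilde.tolist(),
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))

        summary = {
            "config_hash": config_hash,
            "n_nodes": graph.n_nodes,
            "n_edges": graph.n_edges,
            "codelength": part.codelength,
            "n_modules": part.n_modules,
            "r_m": r_m.value,
            "total_flow": flow_graph.total(),
            "codelength_check": codelength(flow_graph, part),
            "outputs": {
                "flows": str(out / "flows.tsv"),
                "partition_tsv": str(out / "partition.tsv"),
                "partition_clu": str(out / "partition.clu"),
                "metrics": str(out / "metrics.json"),
            },
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
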