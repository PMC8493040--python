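"""End-to-end pipeline: parse → graph → embed (or IC) → similarity → screen → evaluate.

Two embedding routes mirror the two halves of the method: the GO route embeds
terms from the flattened GO graph and compares proteins by DTW over their
annotating-term vector sets (``mode="go_dtw"``); the GOA route embeds
proteins directly from the combined GOA graph and compares them by cosine
(``mode="goa_cosine"``).  The IC routes (``ic_jc``, ``ic_rel``) skip
embedding and use Best-Match-Average term similarity instead.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx

from . import embeddings as emb
from . import linkpred as lp
from . import protein_sim as ps
from . import term_ic as ic
from .ontology import (
    AnnotationSet,
    OntologyGraph,
    build_go_graph,
    build_goa_graph,
    parse_gaf,
    parse_obo,
    read_edgelist,
    write_edgelist,
)

logger = logging.getLogger(__name__)

MODES = ("go_dtw", "goa_cosine", "ic_jc", "ic_rel")


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run; round-trips through JSON."""

    obo: str
    gaf: str
    mode: str = "go_dtw"
    ppi: str | None = None
    outdir: str = "run"
    embed_method: str = "deepwalk"
    dim: int = 64
    walk_length: int = 30
    num_walks: int = 10
    window: int = 5
    epochs: int = 3
    p: float = 1.0
    q: float = 1.0
    metric: str = "euclidean"
    tau: float | None = None
    band: str | None = "top"
    band_frac: float = 0.05
    index: str = "ra"
    remove_frac: float = 0.2
    probe_frac: float = 0.2
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.tau is None and self.band is None:
            raise ValueError("config must set tau or band")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _embedding_kwargs(cfg: RunConfig) -> dict:
    if cfg.embed_method in ("deepwalk", "node2vec"):
        kw = dict(
            d=cfg.dim, walk_length=cfg.walk_length, num_walks=cfg.num_walks,
            window=cfg.window, epochs=cfg.epochs, seed=cfg.seed,
        )
        if cfg.embed_method == "node2vec":
            kw.update(p=cfg.p, q=cfg.q)
        return kw
    if cfg.embed_method == "line":
        return dict(d=cfg.dim, epochs=max(cfg.epochs * 10, 20), seed=cfg.seed)
    if cfg.embed_method == "sdne":
        return dict(d=cfg.dim, epochs=max(cfg.epochs * 50, 100), seed=cfg.seed)
    raise ValueError(f"unknown embedding method {cfg.embed_method!r}")


def score_proteins(
    cfg: RunConfig, ontology: OntologyGraph, annotations: AnnotationSet
) -> ps.ScoreTable:
    """Compute the all-pairs protein score table for the configured mode."""
    proteins = annotations.proteins
    if cfg.mode == "go_dtw":
        graph = build_go_graph(ontology)
        vectors = emb.embed(graph, cfg.embed_method, **_embedding_kwargs(cfg))
        return ps.similarity_matrix(proteins, "go_dtw", vectors, annotations, cfg.metric)
    if cfg.mode == "goa_cosine":
        graph = build_goa_graph(ontology, annotations)
        vectors = emb.embed(graph, cfg.embed_method, **_embedding_kwargs(cfg))
        return ps.similarity_matrix(proteins, "goa_cosine", vectors)
    # IC routes
    table = ic.compute_ic_table(ontology, annotations)
    method = "jc" if cfg.mode == "ic_jc" else "rel"
    termsim = ic.make_termsim(ontology, table, method=method)
    return ps.ic_score_table(proteins, annotations, termsim, mode=cfg.mode)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline and write scores.tsv, network.tsv,
    result.json and run.log under the output directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("gosimnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    result: dict = {"config": asdict(cfg)}
    stage = "parse"
    t_all = time.perf_counter()
    try:
        logger.info("config: %s", json.dumps(asdict(cfg)))
        t0 = time.perf_counter()
        ontology = parse_obo(cfg.obo)
        annotations = parse_gaf(cfg.gaf, ontology)
        result["n_terms"] = len(ontology.terms)
        result["n_proteins"] = len(annotations.annotations)
        result["dropped_annotations"] = annotations.dropped
        logger.info("stage parse done in %.2fs", time.perf_counter() - t0)

        stage = "similarity"
        t0 = time.perf_counter()
        table = score_proteins(cfg, ontology, annotations)
        table.save_tsv(outdir / "scores.tsv")
        result["undefined_pairs"] = len(table.undefined)
        logger.info("stage similarity done in %.2fs", time.perf_counter() - t0)

        stage = "screen"
        t0 = time.perf_counter()
        network = ps.screen_network(
            table, tau=cfg.tau, band=cfg.band, band_frac=cfg.band_frac
        )
        write_edgelist(network, outdir / "network.tsv")
        result["network_edges"] = network.number_of_edges()
        logger.info("stage screen done in %.2fs", time.perf_counter() - t0)

        if cfg.ppi:
            stage = "coincidence"
            ppi = read_edgelist(cfg.ppi)
            result["coincidence_degree"] = ps.coincidence_degree(network, ppi)

        stage = "linkpred"
        t0 = time.perf_counter()
        ev = lp.run_experiment(
            network, cfg.index, cfg.remove_frac, cfg.probe_frac,
            seed=cfg.seed, repeats=cfg.repeats,
        )
        result["evaluation"] = ev.to_dict()
        logger.info("stage linkpred done in %.2fs", time.perf_counter() - t0)

        result["elapsed_s"] = time.perf_counter() - t_all
        (outdir / "result.json").write_text(json.dumps(result, indent=2) + "\n")
        cfg.save(outdir / "config.json")
        logger.info("run complete in %.2fs", result["elapsed_s"])
        return outdir
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
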