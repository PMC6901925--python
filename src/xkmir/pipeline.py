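"""End-to-end orchestration of the three discovery strategies.

Each strategy consumes a :class:`RunConfig`, persists every intermediate
under ``<outdir>/<stage>/`` and records checksums, row counts, and timings
in a run manifest, so a rerun with the same config (and seed) is verifiable
as byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .align import cross_kingdom_pairs, significant_pairs
from .coexnet import (ExpressionMatrix, dpi_prune, extract_target_subnetwork,
                      filter_components, permutation_mi_threshold, spearman_mi)
from .io import (read_hits, read_network, write_clusters, write_edge_list,
                 write_enrichment, write_graphml, write_hits, write_pairs,
                 write_shared)
from .netmodules import (AnnotationTable, ClusterOneParams, cluster_modularity,
                         cluster_one, enrich, retain_terms, shared_processes)
from .seqs import Region, read_mirna_fasta, read_transcript_fasta
from .targets import (DuplexParams, PlantScoringParams, scan_human_targets,
                      scan_plant_targets)

logger = logging.getLogger(__name__)

EXIT_OK, EXIT_CONFIG, EXIT_INPUT = 0, 2, 3


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    outdir: str = "out"
    seed: int = 0
    paths: dict = field(default_factory=dict)
    plant_params: PlantScoringParams = field(default_factory=PlantScoringParams)
    duplex_params: DuplexParams = field(default_factory=DuplexParams)
    cluster_one_params: ClusterOneParams = field(default_factory=ClusterOneParams)
    n_perm: int = 200
    alpha: float = 0.05
    mi_threshold: float | None = None
    dpi_eps: float = 0.0
    min_component: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("outdir", "seed", "paths", "n_perm", "alpha", "mi_threshold",
                    "dpi_eps", "min_component"):
            if key in raw:
                kwargs[key] = raw[key]
        for key, klass in (("plant_params", PlantScoringParams),
                           ("duplex_params", DuplexParams),
                           ("cluster_one_params", ClusterOneParams)):
            if key in raw:
                try:
                    block = dict(raw[key])
                    for rk in ("seed_range",):
                        if rk in block:
                            block[rk] = tuple(block[rk])
                    kwargs[key] = klass(**block)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"bad {key}: {exc}") from exc
        return cls(**kwargs)

    def path(self, key: str, required: bool = True) -> Path | None:
        p = self.paths.get(key)
        if p is None:
            if required:
                raise ConfigError(f"missing input path {key!r}")
            return None
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"input {key} not found: {p}")
        return p


class RunManifest:
    """Checksums, row counts and wall-clock per stage."""

    def __init__(self, cfg: RunConfig):
        self.data = {
            "package_version": __version__,
            "seed": cfg.seed,
            "config_hash": hashlib.sha256(
                json.dumps(str(cfg.__dict__), sort_keys=True).encode()
            ).hexdigest(),
            "stages": {},
        }

    def record(self, stage: str, outputs: dict[str, Path], elapsed: float) -> None:
        files = {}
        for name, path in outputs.items():
            blob = Path(path).read_bytes()
            files[name] = {
                "path": str(path),
                "sha256": hashlib.sha256(blob).hexdigest(),
                "n_lines": blob.count(b"\n"),
            }
        self.data["stages"][stage] = {"elapsed_s": round(elapsed, 3), "files": files}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def _stage_dir(cfg: RunConfig, stage: str) -> Path:
    d = Path(cfg.outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_prediction(cfg: RunConfig, manifest: RunManifest,
                   *, mode: str = "both") -> tuple[list, list]:
    """Target prediction for the plant transcriptome and/or human UTRome."""
    t0 = time.time()
    out = _stage_dir(cfg, "predict")
    mirnas = read_mirna_fasta(cfg.path("mirnas"))
    plant_hits, human_hits = [], []
    outputs = {}
    if mode in ("plant", "both"):
        transcripts = read_transcript_fasta(cfg.path("plant_transcripts"))
        plant_hits = scan_plant_targets(mirnas, transcripts, cfg.plant_params)
        write_hits(plant_hits, out / "plant_hits.tsv")
        outputs["plant_hits"] = out / "plant_hits.tsv"
        logger.info("plant scan: %d hits, %d unique transcripts, %d unique genes",
                    len(plant_hits), len({h.transcript_id for h in plant_hits}),
                    len({h.gene_id for h in plant_hits}))
    if mode in ("human", "both"):
        utrs = read_transcript_fasta(cfg.path("human_utrs"), region=Region.UTR3)
        human_hits = scan_human_targets(mirnas, utrs, cfg.duplex_params)
        write_hits(human_hits, out / "human_hits.tsv")
        outputs["human_hits"] = out / "human_hits.tsv"
        logger.info("human scan: %d hits, %d unique transcripts",
                    len(human_hits), len({h.transcript_id for h in human_hits}))
    manifest.record("predict", outputs, time.time() - t0)
    return plant_hits, human_hits


def _load_seq_map(cds_path, protein_path) -> dict[str, dict[str, str]]:
    cds = read_transcript_fasta(cds_path, region=Region.CDS)
    prot = read_transcript_fasta(protein_path, region=Region.PROTEIN)
    out: dict[str, dict[str, str]] = {}
    for r in cds:
        out.setdefault(r.gene_id, {})["cds"] = r.sequence
    for r in prot:
        out.setdefault(r.gene_id, {})["protein"] = r.sequence
    return out


def run_alignment_strategy(cfg: RunConfig) -> dict:
    """Plant x human target pairing with permutation-tested alignments."""
    manifest = RunManifest(cfg)
    plant_hits, human_hits = run_prediction(cfg, manifest)
    t0 = time.time()
    out = _stage_dir(cfg, "xalign")
    plant_seqs = _load_seq_map(cfg.path("plant_cds"), cfg.path("plant_proteins"))
    human_seqs = _load_seq_map(cfg.path("human_cds"), cfg.path("human_proteins"))
    pairs = cross_kingdom_pairs(plant_hits, human_hits, plant_seqs, human_seqs,
                                n_perm=cfg.n_perm, seed=cfg.seed)
    write_pairs(pairs, out / "pairs.tsv")
    report = {}
    outputs = {"pairs": out / "pairs.tsv"}
    for mode in ("nt", "protein", "both"):
        kept, tallies = significant_pairs(pairs, cfg.alpha, mode)
        write_pairs(kept, out / f"significant_{mode}.tsv")
        outputs[f"significant_{mode}"] = out / f"significant_{mode}.tsv"
        report[mode] = tallies
    if not pairs:
        logger.warning("no cross-kingdom pairs could be formed")
    manifest.record("xalign", outputs, time.time() - t0)
    manifest.write(Path(cfg.outdir) / "manifest_alignment.json")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _cluster_and_enrich(net, annot: AnnotationTable, target_genes, cfg: RunConfig,
                        out: Path, label: str):
    import dataclasses

    clusters = cluster_modularity(net) + cluster_one(net, cfg.cluster_one_params)
    clusters = [dataclasses.replace(c, cluster_id=f"{label}-{c.cluster_id}")
                for c in clusters]
    write_clusters(clusters, out / f"{label}_clusters.tsv")
    records = []
    for c in clusters:
        records.extend(enrich(c, annot))
    write_enrichment(records, out / f"{label}_enrichment.tsv")
    retained = retain_terms(records, target_genes, cfg.alpha)
    write_enrichment(retained, out / f"{label}_retained.tsv")
    return clusters, retained


def run_network_strategy(cfg: RunConfig) -> list:
    """Interaction-network clustering + enrichment for both species, then
    cross-species shared-process intersection."""
    manifest = RunManifest(cfg)
    plant_hits, human_hits = run_prediction(cfg, manifest)
    t0 = time.time()
    out = _stage_dir(cfg, "modules")
    shared = []
    if not plant_hits and not human_hits:
        logger.warning("empty hit tables; empty shared-process report")
        write_shared([], out / "shared_processes.tsv")
        manifest.record("modules", {"shared": out / "shared_processes.tsv"},
                        time.time() - t0)
        manifest.write(Path(cfg.outdir) / "manifest_network.json")
        return shared
    net_a = read_network(cfg.path("plant_network"))
    net_b = read_network(cfg.path("human_network"))
    annot_a = AnnotationTable.from_gmt(cfg.path("plant_annotations"))
    annot_b = AnnotationTable.from_gmt(cfg.path("human_annotations"))
    targets_a = {h.gene_id for h in plant_hits}
    targets_b = {h.gene_id for h in human_hits}
    _, retained_a = _cluster_and_enrich(net_a, annot_a, targets_a, cfg, out, "plant")
    _, retained_b = _cluster_and_enrich(net_b, annot_b, targets_b, cfg, out, "human")
    shared = shared_processes(retained_a, retained_b, plant_hits, human_hits)
    write_shared(shared, out / "shared_processes.tsv")
    manifest.record("modules", {
        "shared": out / "shared_processes.tsv",
        "plant_retained": out / "plant_retained.tsv",
        "human_retained": out / "human_retained.tsv",
    }, time.time() - t0)
    manifest.write(Path(cfg.outdir) / "manifest_network.json")
    return shared


def run_coexnet_strategy(cfg: RunConfig) -> dict:
    """Expression matrix -> MI -> DPI -> target sub-network -> components ->
    clustering -> enrichment."""
    manifest = RunManifest(cfg)
    plant_hits, _ = run_prediction(cfg, manifest, mode="plant")
    t0 = time.time()
    out = _stage_dir(cfg, "coexnet")
    expr = ExpressionMatrix.from_tsv(cfg.path("expression"))
    mim = spearman_mi(expr)
    thr = cfg.mi_threshold
    if thr is None:
        thr = permutation_mi_threshold(expr, seed=cfg.seed)
        logger.info("permutation MI threshold: %.4f", thr)
    net = dpi_prune(mim, eps=cfg.dpi_eps, mi_threshold=thr)
    write_edge_list(net, out / "network_full.tsv")
    targets = sorted({h.gene_id for h in plant_hits})
    report: dict = {"mi_threshold": thr,
                    "full_network": {"n_nodes": net.number_of_nodes(),
                                     "n_edges": net.number_of_edges()}}
    if targets:
        sub = extract_target_subnetwork(net, targets)
        giant, comp_report = filter_components(sub, cfg.min_component)
        report["components"] = comp_report
        write_edge_list(giant, out / "giant_component.tsv")
        write_graphml(giant, out / "giant_component.graphml")
        annot_path = cfg.path("plant_annotations", required=False)
        if annot_path and giant.number_of_nodes():
            annot = AnnotationTable.from_gmt(annot_path)
            clusters = cluster_modularity(giant)
            write_clusters(clusters, out / "clusters.tsv")
            records = []
            for c in clusters:
                records.extend(enrich(c, annot))
            retained = retain_terms(records, targets, cfg.alpha)
            write_enrichment(retained, out / "retained.tsv")
            report["n_retained_terms"] = len(retained)
    manifest.record("coexnet", {"network": out / "network_full.tsv"},
                    time.time() - t0)
    manifest.write(Path(cfg.outdir) / "manifest_coexnet.json")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
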