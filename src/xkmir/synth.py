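"""Synthetic inputs with planted ground truth.

Every downstream stage of the pipeline can be exercised without any
download: miRNA sets, transcriptomes with planted (reverse-complement)
target sites, ortholog pairs at controlled nucleotide identity, expression
matrices with planted co-expression modules, and annotation tables with
planted enriched terms. One global seed drives a per-stream RNG hierarchy
(mirnas / plant / human / orthologs / expression / annotations), so
regenerating one stream does not perturb the others, and identical configs
produce byte-identical files.

Background nucleotide composition is uniform unless a GC range is
configured; ortholog mutations are substitution-only so the nominal
identity is exact.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .seqs import MiRNA, Region, TranscriptRecord, gc_fraction, revcomp_rna, translate_cds, write_fasta
from .coexnet import ExpressionMatrix
from .netmodules import AnnotationTable

_STREAMS = {"mirnas": 1, "plant": 2, "human": 3, "orthologs": 4,
            "expression": 5, "annotations": 6}

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SiteMutationSpec:
    """How planted plant sites are perturbed relative to the perfect
    reverse complement. ``region`` restricts mutated miRNA positions."""

    n_mismatches: int = 0
    n_gu: int = 0
    region: str = "any"  # "any" | "seed" | "non_seed"
    seed_range: tuple[int, int] = (2, 13)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    # miRNAs
    n_mirnas: int = 10
    mirna_length_range: tuple[int, int] = (20, 22)
    gc_range: tuple[float, float] = (0.2, 0.8)
    # transcriptomes
    n_plant_transcripts: int = 30
    n_human_utrs: int = 30
    transcript_length: int = 400
    utr_length: int = 300
    sites_per_mirna: int = 1
    site_mutation_spec: SiteMutationSpec = SiteMutationSpec()
    # orthologs
    ortholog_identities: tuple[float, ...] = (0.9,)
    cds_length: int = 300
    # expression
    n_genes: int = 200
    n_samples: int = 80
    n_modules: int = 3
    module_size_range: tuple[int, int] = (15, 25)
    within_module_correlation: float = 0.9
    noise_sd: float = 1.0
    # annotations
    n_terms: int = 30
    term_size_range: tuple[int, int] = (10, 30)
    enrichment_overlap_fraction: float = 1.0
    ensure_coverage: bool = False

    def __post_init__(self) -> None:
        counts = ("n_mirnas", "n_plant_transcripts", "n_human_utrs", "n_genes",
                  "n_samples", "n_modules", "n_terms", "transcript_length",
                  "utr_length", "cds_length")
        for name in counts:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not (0 < self.within_module_correlation < 1):
            raise ConfigurationError("within_module_correlation must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if any(not 0 <= x <= 1 for x in self.ortholog_identities):
            raise ConfigurationError("ortholog identities must lie in [0, 1]")
        lo, hi = self.mirna_length_range
        if lo > hi or lo < 15:
            raise ConfigurationError("invalid mirna_length_range")
        glo, ghi = self.gc_range
        if not (0 <= glo <= ghi <= 1):
            raise ConfigurationError("invalid gc_range")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed & 0xFFFFFFFF, _STREAMS[stream]])


@dataclass
class TruthTable:
    planted_targets: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    ortholog_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    modules: dict[str, list[str]] = field(default_factory=dict)
    enriched_terms: dict[str, str] = field(default_factory=dict)  # module -> term

    def merge(self, other: "TruthTable") -> "TruthTable":
        return TruthTable(
            self.planted_targets + other.planted_targets,
            self.ortholog_pairs + other.ortholog_pairs,
            {**self.modules, **other.modules},
            {**self.enriched_terms, **other.enriched_terms},
        )

    def validate(self, transcripts: dict[str, str] | None = None) -> None:
        for _, tid, start, end, _ in self.planted_targets:
            if start < 0 or end <= start:
                raise ValueError(f"bad site coordinates on {tid}")
            if transcripts is not None and end > len(transcripts[tid]):
                raise ValueError(f"site extends past transcript {tid}")
        for _, _, ident in self.ortholog_pairs:
            if not 0 <= ident <= 1:
                raise ValueError("ortholog identity outside [0, 1]")
        all_genes = [g for genes in self.modules.values() for g in genes]
        if len(all_genes) != len(set(all_genes)):
            raise ValueError("modules are not disjoint")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        raw = json.loads(Path(path).read_text())
        return cls(
            [tuple(row) for row in raw["planted_targets"]],
            [tuple(row) for row in raw["ortholog_pairs"]],
            raw["modules"],
            raw["enriched_terms"],
        )


# --------------------------------------------------------------------------


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, length)])


def gen_mirnas(cfg: GeneratorConfig) -> list[MiRNA]:
    """miRNA sequences with lengths and GC fractions inside the configured
    ranges; deterministic given the seed."""
    rng = cfg.rng("mirnas")
    lo, hi = cfg.mirna_length_range
    glo, ghi = cfg.gc_range
    out = []
    for i in range(cfg.n_mirnas):
        length = int(rng.integers(lo, hi + 1))
        gc_min = math.ceil(glo * length - 1e-9)
        gc_max = math.floor(ghi * length + 1e-9)
        if gc_min > gc_max:
            raise ConfigurationError(
                f"gc_range {cfg.gc_range} infeasible for length {length}"
            )
        n_gc = int(rng.integers(gc_min, gc_max + 1))
        bases = ["G" if rng.random() < 0.5 else "C" for _ in range(n_gc)]
        bases += ["A" if rng.random() < 0.5 else "U" for _ in range(length - n_gc)]
        rng.shuffle(bases)
        out.append(MiRNA(f"syn-miR{i + 1:03d}", "".join(bases)))
    return out


def _mutate_site(site: str, mirna: MiRNA, spec: SiteMutationSpec,
                 rng: np.random.Generator) -> str:
    """Inject mismatches / G:U wobbles at chosen miRNA positions.

    miRNA position p (1-based from 5') corresponds to site index L - p in
    the 5'->3' site string (antiparallel pairing)."""
    L = len(mirna)
    lo, hi = spec.seed_range
    if spec.region == "seed":
        allowed = [p for p in range(1, L + 1) if lo <= p <= hi]
    elif spec.region == "non_seed":
        allowed = [p for p in range(1, L + 1) if not lo <= p <= hi]
    else:
        allowed = list(range(1, L + 1))
    gu_capable = [p for p in allowed if mirna.sequence[p - 1] in "GU"]
    if spec.n_gu > len(gu_capable):
        raise ConfigurationError("not enough G/U positions for requested wobbles")
    if spec.n_mismatches + spec.n_gu > len(allowed):
        raise ConfigurationError("mutation spec exceeds available positions")

    site_list = list(site)
    gu_positions = sorted(rng.choice(gu_capable, size=spec.n_gu, replace=False)) if spec.n_gu else []
    remaining = [p for p in allowed if p not in gu_positions]
    mm_positions = sorted(rng.choice(remaining, size=spec.n_mismatches, replace=False)) if spec.n_mismatches else []
    for p in gu_positions:
        site_list[L - p] = "U" if mirna.sequence[p - 1] == "G" else "G"
    for p in mm_positions:
        base = mirna.sequence[p - 1]
        forbidden = {_WC[base]}
        if base == "G":
            forbidden.add("U")
        if base == "U":
            forbidden.add("G")
        choices = sorted(set("ACGU") - forbidden)
        site_list[L - p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(site_list)


def _plant_sites(
    mirnas: list[MiRNA],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    n_transcripts: int,
    length: int,
    prefix: str,
    region: Region,
    kind: str,
    mutate: bool,
) -> tuple[list[TranscriptRecord], TruthTable]:
    if not mirnas:
        raise ValueError("need at least one miRNA")
    max_len = max(len(m) for m in mirnas)
    if max_len > length:
        raise ConfigurationError("planted site longer than transcript")
    seqs = [list(_random_rna(rng, length)) for _ in range(n_transcripts)]
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_transcripts)}
    truth = TruthTable()
    for mirna in mirnas:
        L = len(mirna)
        for _ in range(cfg.sites_per_mirna):
            for _attempt in range(1000):
                ti = int(rng.integers(0, n_transcripts))
                start = int(rng.integers(0, length - L + 1))
                span = (start, start + L)
                if all(span[1] <= a or span[0] >= b for a, b in occupied[ti]):
                    break
            else:
                raise ConfigurationError("could not place all sites; transcripts too small")
            site = revcomp_rna(mirna.sequence)
            if mutate:
                site = _mutate_site(site, mirna, cfg.site_mutation_spec, rng)
            seqs[ti][span[0]: span[1]] = list(site)
            occupied[ti].append(span)
            truth.planted_targets.append(
                (mirna.id, f"{prefix}{ti + 1:04d}", span[0], span[1], kind)
            )
    records = [
        TranscriptRecord(f"{prefix}{i + 1:04d}", "".join(s), region=region)
        for i, s in enumerate(seqs)
    ]
    return records, truth


def gen_plant_transcriptome(
    mirnas: list[MiRNA], cfg: GeneratorConfig
) -> tuple[list[TranscriptRecord], TruthTable]:
    """Random-background transcripts with ``sites_per_mirna`` planted sites
    per miRNA: the reverse complement of the miRNA, perturbed according to
    ``site_mutation_spec``. Exact coordinates are recorded in the truth."""
    rng = cfg.rng("plant")
    return _plant_sites(
        mirnas, cfg, rng, cfg.n_plant_transcripts, cfg.transcript_length,
        "PT", Region.TRANSCRIPT, "plant_complement", mutate=True,
    )


def gen_human_utrome(
    mirnas: list[MiRNA], cfg: GeneratorConfig
) -> tuple[list[TranscriptRecord], TruthTable]:
    """UTR-labelled records with planted perfect-complement (hence low-MFE)
    sites for every miRNA."""
    rng = cfg.rng("human")
    return _plant_sites(
        mirnas, cfg, rng, cfg.n_human_utrs, cfg.utr_length,
        "HU", Region.UTR3, "human_mfe_site", mutate=False,
    )


_STOPS = {"UAA", "UAG", "UGA"}


def _random_cds(rng: np.random.Generator, length: int) -> str:
    codons = []
    while len(codons) * 3 < length:
        c = _random_rna(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)[:length]


def _mutate_cds(cds: str, identity: float, rng: np.random.Generator) -> str:
    n_mut = round((1.0 - identity) * len(cds))
    positions = sorted(rng.choice(len(cds), size=n_mut, replace=False)) if n_mut else []
    seq = list(cds)
    for pos in positions:
        choices = sorted(set("ACGU") - {seq[pos]})
        for _ in range(20):
            cand = choices[int(rng.integers(0, 3))]
            codon_start = pos - pos % 3
            trial = seq.copy()
            trial[pos] = cand
            if "".join(trial[codon_start: codon_start + 3]) not in _STOPS:
                seq[pos] = cand
                break
        else:  # every alternative creates a stop codon (cannot happen for single subs)
            seq[pos] = choices[0]
    return "".join(seq)


def gen_ortholog_pairs(
    cfg: GeneratorConfig,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord],
           list[TranscriptRecord], list[TranscriptRecord], TruthTable]:
    """CDS + protein pairs at controlled nucleotide identity.

    Returns (plant CDS, plant proteins, human CDS, human proteins, truth).
    The human CDS is a substitution-only perturbation of the plant CDS, so
    the nominal identity is exact; proteins are the translations.
    """
    rng = cfg.rng("orthologs")
    length = cfg.cds_length - cfg.cds_length % 3
    p_cds, p_prot, h_cds, h_prot = [], [], [], []
    truth = TruthTable()
    for i, ident in enumerate(cfg.ortholog_identities):
        pg, hg = f"PGENE{i + 1:03d}", f"HGENE{i + 1:03d}"
        plant = _random_cds(rng, length)
        human = _mutate_cds(plant, ident, rng)
        p_cds.append(TranscriptRecord(pg, plant, region=Region.CDS))
        h_cds.append(TranscriptRecord(hg, human, region=Region.CDS))
        p_prot.append(TranscriptRecord(pg, translate_cds(plant).rstrip("*"),
                                       region=Region.PROTEIN))
        h_prot.append(TranscriptRecord(hg, translate_cds(human).rstrip("*"),
                                       region=Region.PROTEIN))
        truth.ortholog_pairs.append((pg, hg, float(ident)))
    return p_cds, p_prot, h_cds, h_prot, truth


def gen_expression(cfg: GeneratorConfig) -> tuple[ExpressionMatrix, TruthTable]:
    """Expression matrix with planted co-expression modules.

    Module genes load on a shared latent sample factor with loading
    ``sqrt(rho)`` so the expected pairwise Pearson correlation equals
    ``within_module_correlation``; background genes are independent noise
    with standard deviation ``noise_sd``.
    """
    rng = cfg.rng("expression")
    lo, hi = cfg.module_size_range
    if cfg.n_modules * hi > cfg.n_genes:
        raise ConfigurationError("modules do not fit in the gene universe")
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    samples = [f"S{j + 1:03d}" for j in range(cfg.n_samples)]
    values = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_samples))
    rho = cfg.within_module_correlation
    truth = TruthTable()
    cursor = 0
    for m in range(cfg.n_modules):
        size = int(rng.integers(lo, hi + 1))
        members = genes[cursor: cursor + size]
        cursor += size
        z = rng.normal(0.0, 1.0, size=cfg.n_samples)
        for g in members:
            eps = rng.normal(0.0, 1.0, size=cfg.n_samples)
            values[genes.index(g)] = math.sqrt(rho) * z + math.sqrt(1.0 - rho) * eps
        truth.modules[f"module{m + 1}"] = members
    return ExpressionMatrix(genes, samples, values), truth


def gen_annotations(
    genes: list[str],
    cfg: GeneratorConfig,
    modules: dict[str, list[str]] | None = None,
) -> tuple[AnnotationTable, TruthTable]:
    """Annotation table with uniformly drawn background terms plus one
    planted term per module overlapping it by ``enrichment_overlap_fraction``."""
    if not genes:
        raise ValueError("empty gene universe")
    rng = cfg.rng("annotations")
    lo, hi = cfg.term_size_range
    if hi > len(genes):
        raise ConfigurationError("term size exceeds the gene universe")
    universe = frozenset(genes)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(np.array(genes)[rng.choice(len(genes), size=size, replace=False)])
        terms[f"GO:{9000000 + t}"] = (f"background process {t + 1}", members)
    truth = TruthTable()
    for name, members in (modules or {}).items():
        n_in = round(cfg.enrichment_overlap_fraction * len(members))
        inside = list(rng.choice(members, size=n_in, replace=False)) if n_in else []
        outside_pool = sorted(universe - set(members))
        n_out = len(members) - n_in
        outside = list(np.array(outside_pool)[rng.choice(len(outside_pool), size=n_out, replace=False)]) if n_out else []
        tid = f"GO:{8000000 + len(truth.enriched_terms)}"
        terms[tid] = (f"planted process {name}", frozenset(inside) | frozenset(outside))
        truth.enriched_terms[name] = tid
    if cfg.ensure_coverage:
        covered = set().union(*(g for _, g in terms.values())) if terms else set()
        leftovers = universe - covered
        if leftovers:
            terms["GO:7000000"] = ("coverage catch-all", frozenset(leftovers))
    return AnnotationTable(terms, universe), truth


def write_synthetic_dataset(cfg: GeneratorConfig, outdir) -> dict[str, str]:
    """Generate every pipeline input under ``outdir``; returns file paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mirnas = gen_mirnas(cfg)
    plant, truth_p = gen_plant_transcriptome(mirnas, cfg)
    human, truth_h = gen_human_utrome(mirnas, cfg)
    p_cds, p_prot, h_cds, h_prot, truth_o = gen_ortholog_pairs(cfg)
    expr, truth_e = gen_expression(cfg)
    annot, truth_a = gen_annotations(expr.gene_ids, cfg, truth_e.modules)
    truth = truth_p.merge(truth_h).merge(truth_o).merge(truth_e).merge(truth_a)

    paths = {}

    def fasta(name, records):
        path = out / f"{name}.fasta"
        write_fasta(((r.id, r.sequence) for r in records), path)
        paths[name] = str(path)

    fasta("mirnas", mirnas)
    fasta("plant_transcripts", plant)
    fasta("human_utrs", human)
    fasta("plant_cds", p_cds)
    fasta("plant_proteins", p_prot)
    fasta("human_cds", h_cds)
    fasta("human_proteins", h_prot)
    expr.to_tsv(out / "expression.tsv")
    paths["expression"] = str(out / "expression.tsv")
    annot.to_gmt(out / "annotations.gmt")
    paths["annotations"] = str(out / "annotations.gmt")
    truth.to_json(out / "truth.json")
    paths["truth"] = str(out / "truth.json")
    return paths
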