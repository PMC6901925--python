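"""Local alignment, permutation significance, and cross-kingdom pairing.

Smith-Waterman alignment is delegated to Biopython's ``PairwiseAligner``
(NUC44 for nucleotides, BLOSUM50 for proteins, linear gap penalty 8 by
default) with an independent brute-force oracle kept in the test suite. The
permutation p-value shuffles the second (human-side) sequence only and
counts strictly greater scores, so significance does not depend on the
score's unit convention.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqs import TranscriptRecord

logger = logging.getLogger(__name__)

_MATRICES = {"nt": "NUC.4.4", "protein": "BLOSUM50"}


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    identity_pct: float  # over aligned columns (gaps included)
    matches: int
    alignment_length: int
    aligned_span_a: tuple[int, int]  # 0-based half-open on the input sequences
    aligned_span_b: tuple[int, int]
    p_value: float | None = None
    n_perm: int = 0

    @property
    def identity_vs_shorter(self) -> float:
        """Matches as a percentage of the shorter input sequence's length."""
        return 100.0 * self.matches / self._shorter if self._shorter else 0.0

    _shorter: int = 0


@dataclass(frozen=True)
class CrossKingdomPair:
    mirna_id: str
    plant_gene: str
    human_gene: str
    nt_result: AlignmentResult
    protein_result: AlignmentResult


@dataclass(frozen=True)
class HomologyEntry:
    query_gene: str
    reference_gene: str
    relative_similarity: float


def _make_aligner(
    alphabet: str,
    gap: float,
    match: float | None,
    mismatch: float | None,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if match is not None:
        aligner.match_score = match
        aligner.mismatch_score = mismatch if mismatch is not None else -match
    else:
        aligner.substitution_matrix = substitution_matrices.load(_MATRICES[alphabet])
    aligner.open_gap_score = -gap
    aligner.extend_gap_score = -gap
    return aligner


def _normalize(seq: str, alphabet: str) -> str:
    s = seq.upper()
    return s.replace("U", "T") if alphabet == "nt" else s


def smith_waterman(
    a: str,
    b: str,
    alphabet: str = "nt",
    *,
    gap: float = 8.0,
    match: float | None = None,
    mismatch: float | None = None,
) -> AlignmentResult:
    """Optimal local alignment of ``a`` vs ``b``.

    Nucleotide sequences are compared on the DNA-normalized alphabet (U->T)
    so that RNA and DNA inputs mix freely. ``match``/``mismatch`` override
    the substitution matrix with a simple scoring scheme (used by tests).
    The traceback is the aligner's canonical first alignment, which is
    deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    sa, sb = _normalize(a, alphabet), _normalize(b, alphabet)
    aligner = _make_aligner(alphabet, gap, match, mismatch)
    score = aligner.score(sa, sb)
    aln = next(iter(aligner.align(sa, sb)))
    ta, tb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(ta, tb) if x == y and x != "-")
    length = len(ta)
    blocks_a, blocks_b = aln.aligned
    span_a = (int(blocks_a[0][0]), int(blocks_a[-1][1])) if len(blocks_a) else (0, 0)
    span_b = (int(blocks_b[0][0]), int(blocks_b[-1][1])) if len(blocks_b) else (0, 0)
    return AlignmentResult(
        score=float(score),
        identity_pct=100.0 * matches / length if length else 0.0,
        matches=matches,
        alignment_length=length,
        aligned_span_a=span_a,
        aligned_span_b=span_b,
        _shorter=min(len(sa), len(sb)),
    )


def sw_score(
    a: str,
    b: str,
    alphabet: str = "nt",
    *,
    gap: float = 8.0,
    match: float | None = None,
    mismatch: float | None = None,
) -> float:
    """Score-only fast path (no traceback)."""
    aligner = _make_aligner(alphabet, gap, match, mismatch)
    return float(aligner.score(_normalize(a, alphabet), _normalize(b, alphabet)))


def _pair_rng(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-comparison RNG derived from the global seed."""
    digest = hashlib.sha256("|".join(labels).encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed & 0xFFFFFFFF, key]))


def permutation_pvalue(
    a: str,
    b: str,
    alphabet: str = "nt",
    n_perm: int = 200,
    seed: int = 0,
    *,
    gap: float = 8.0,
    count_ties: bool = False,
    rng: np.random.Generator | None = None,
) -> AlignmentResult:
    """Permutation p-value for the local alignment of ``a`` vs ``b``.

    ``b`` (the human-side sequence) is shuffled ``n_perm`` times preserving
    composition; p = #(shuffled score > original score) / n_perm. With
    ``count_ties`` the >= rule with the +1/(n+1) correction is used instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    result = smith_waterman(a, b, alphabet, gap=gap)
    rng = rng if rng is not None else np.random.default_rng(seed)
    aligner = _make_aligner(alphabet, gap, None, None)
    sa = _normalize(a, alphabet)
    chars = np.array(list(_normalize(b, alphabet)))
    exceed = 0
    for _ in range(n_perm):
        perm = "".join(rng.permutation(chars))
        s = aligner.score(sa, perm)
        if s > result.score or (count_ties and s == result.score):
            exceed += 1
    if count_ties:
        p = (exceed + 1) / (n_perm + 1)
    else:
        p = exceed / n_perm
    return replace(result, p_value=p, n_perm=n_perm)


def cross_kingdom_pairs(
    plant_hits,
    human_hits,
    plant_seqs: dict[str, dict[str, str]],
    human_seqs: dict[str, dict[str, str]],
    *,
    n_perm: int = 200,
    seed: int = 0,
    gap: float = 8.0,
) -> list[CrossKingdomPair]:
    """Per-miRNA Cartesian product of plant x human target genes, each pair
    aligned at CDS and protein level with permutation p-values.

    ``plant_seqs``/``human_seqs`` map gene id -> {"cds": ..., "protein": ...}.
    Pairs with missing sequences are skipped with a log line, not fatal.
    """
    by_mirna_plant: dict[str, list[str]] = {}
    by_mirna_human: dict[str, list[str]] = {}
    for h in plant_hits:
        genes = by_mirna_plant.setdefault(h.mirna_id, [])
        if h.gene_id not in genes:
            genes.append(h.gene_id)
    for h in human_hits:
        genes = by_mirna_human.setdefault(h.mirna_id, [])
        if h.gene_id not in genes:
            genes.append(h.gene_id)

    pairs: list[CrossKingdomPair] = []
    for mirna_id in sorted(set(by_mirna_plant) & set(by_mirna_human)):
        for pg in sorted(by_mirna_plant[mirna_id]):
            for hg in sorted(by_mirna_human[mirna_id]):
                ps, hs = plant_seqs.get(pg), human_seqs.get(hg)
                if not ps or not hs or "cds" not in ps or "cds" not in hs:
                    logger.warning("missing sequence for pair (%s, %s, %s); skipped",
                                   mirna_id, pg, hg)
                    continue
                nt = permutation_pvalue(
                    ps["cds"], hs["cds"], "nt", n_perm, gap=gap,
                    rng=_pair_rng(seed, mirna_id, pg, hg, "nt"),
                )
                prot = permutation_pvalue(
                    ps["protein"], hs["protein"], "protein", n_perm, gap=gap,
                    rng=_pair_rng(seed, mirna_id, pg, hg, "protein"),
                )
                pairs.append(CrossKingdomPair(mirna_id, pg, hg, nt, prot))
    return pairs


def significant_pairs(
    pairs: list[CrossKingdomPair], alpha: float = 0.05, mode: str = "nt"
) -> tuple[list[CrossKingdomPair], dict[str, int]]:
    """Filter pairs by permutation p-value and tally unique ids.

    ``mode`` is one of ``nt`` (nucleotide p < alpha), ``protein``, or
    ``both`` (both levels significant).
    """
    if mode not in ("nt", "protein", "both"):
        raise ValueError(f"unknown mode {mode!r}")

    def keep(p: CrossKingdomPair) -> bool:
        nt_ok = p.nt_result.p_value is not None and p.nt_result.p_value < alpha
        pr_ok = p.protein_result.p_value is not None and p.protein_result.p_value < alpha
        return {"nt": nt_ok, "protein": pr_ok, "both": nt_ok and pr_ok}[mode]

    kept = [p for p in pairs if keep(p)]
    tallies = {
        "n_pairs": len(kept),
        "n_mirnas": len({p.mirna_id for p in kept}),
        "n_plant_genes": len({p.plant_gene for p in kept}),
        "n_human_genes": len({p.human_gene for p in kept}),
    }
    return kept, tallies


def map_homologs(
    query_proteins: list[TranscriptRecord],
    reference_proteins: list[TranscriptRecord],
    threshold: float = 0.85,
    *,
    metric: str = "score_ratio",
    gap: float = 8.0,
) -> list[HomologyEntry]:
    """Best-reference homology mapping by protein Smith-Waterman.

    ``relative_similarity`` is the SW score against the reference divided by
    the query's self-alignment score (``metric="identity"`` uses percent
    identity / 100 instead). One best mapping per query (ties broken by
    reference id); entries with similarity > ``threshold`` are retained.
    """
    if not reference_proteins:
        raise ValueError("empty reference protein set")
    entries: list[HomologyEntry] = []
    for q in query_proteins:
        self_score = sw_score(q.sequence, q.sequence, "protein", gap=gap)
        best: tuple[float, str] | None = None
        for r in sorted(reference_proteins, key=lambda t: t.gene_id):
            if metric == "identity":
                sim = smith_waterman(q.sequence, r.sequence, "protein", gap=gap).identity_pct / 100
            else:
                sim = sw_score(q.sequence, r.sequence, "protein", gap=gap) / self_score
            if best is None or sim > best[0]:
                best = (sim, r.gene_id)
        if best is not None and best[0] > threshold:
            entries.append(HomologyEntry(q.gene_id, best[1], best[0]))
    return entries


def family_identity(a: str, b: str, seed_range: tuple[int, int] = (2, 13)) -> dict:
    """Full-length comparison of two mature miRNA sequences.

    For equal-length sequences this is a position-by-position comparison
    over all columns; mismatch positions are reported 1-based from the 5'
    end of ``a`` together with how many fall inside ``seed_range``. The
    identity percentage equals local-alignment matches over the shorter
    sequence length for ungapped families.
    """
    sa, sb = _normalize(a, "nt"), _normalize(b, "nt")
    if len(sa) == len(sb):
        mism = [i + 1 for i, (x, y) in enumerate(zip(sa, sb)) if x != y]
        matches = len(sa) - len(mism)
        denom = len(sa)
    else:
        res = smith_waterman(sa, sb)
        matches = res.matches
        denom = min(len(sa), len(sb))
        mism = []
    lo, hi = seed_range
    return {
        "identity_pct": 100.0 * matches / denom,
        "n_mismatches": len(mism),
        "mismatch_positions": mism,
        "n_seed_mismatches": sum(1 for p in mism if lo <= p <= hi),
    }
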