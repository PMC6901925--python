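"""miRNA target scanning.

Two scanners live here:

* a plant-style complementarity scanner whose score is a weighted penalty
  sum ("expectation"): 0 for a Watson-Crick pair, a reduced penalty for G:U
  wobbles, 1 for other mismatches, affine gap costs, with penalties inside
  the seed region (miRNA positions 2-13 by default) multiplied by an extra
  weight; lower is better and 0 means perfect complementarity;
* an animal-style scanner that minimizes the nearest-neighbor free energy
  of the intermolecular miRNA:site duplex (see :mod:`xkmir.energy`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .energy import EnergyTable, load_energy_table, pair_type
from .seqs import MiRNA, Region, TranscriptRecord, normalize_rna

WC_PAIRS = {"AU", "UA", "CG", "GC"}
GU_PAIRS = {"GU", "UG"}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_ENC = np.full(256, -1, dtype=np.int8)
for _b, _c in _BASE_CODE.items():
    _ENC[ord(_b)] = _c

# pair-type codes per (miRNA base, site base); -1 = no canonical pair
_PT = np.full((4, 4), -1, dtype=np.int8)
for _x in "ACGU":
    for _y in "ACGU":
        _PT[_BASE_CODE[_x], _BASE_CODE[_y]] = pair_type(_x, _y)


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


class InputTypeError(TypeError):
    """Raised when a scanner receives records of the wrong region/alphabet."""


# --------------------------------------------------------------------------
# plant-style expectation scoring
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantScoringParams:
    expectation_max: float = 2.5
    gu_penalty: float = 0.5
    mismatch_penalty: float = 1.0
    gap_open: float = 2.0
    gap_extend: float = 0.5
    seed_weight: float = 1.5
    seed_range: tuple[int, int] = (2, 13)  # 1-based, inclusive, from miRNA 5' end
    seed_mismatches_allowed: int = 0
    seed_allow_gu: bool = False
    hsp_min_len: int = 19
    top_n: int = 50

    def __post_init__(self) -> None:
        for name in ("gu_penalty", "mismatch_penalty", "gap_open", "gap_extend"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seed_range[0] < 1 or self.seed_range[0] > self.seed_range[1]:
            raise ValueError("invalid seed_range")

    def weight(self, pos_1based: int) -> float:
        lo, hi = self.seed_range
        return self.seed_weight if lo <= pos_1based <= hi else 1.0

    def in_seed(self, pos_1based: int) -> bool:
        lo, hi = self.seed_range
        return lo <= pos_1based <= hi


@dataclass(frozen=True)
class PlantTargetHit:
    mirna_id: str
    transcript_id: str
    gene_id: str
    site_start: int  # 0-based half-open on the transcript, 5'->3'
    site_end: int
    expectation: float
    seed_violations: int
    alignment: str


def _pair_penalty(mi_base: str, site_base: str, params: PlantScoringParams) -> float:
    pair = mi_base + site_base
    if pair in WC_PAIRS:
        return 0.0
    if pair in GU_PAIRS:
        return params.gu_penalty
    return params.mismatch_penalty


def plant_site_score(
    mirna: MiRNA, site: str, params: PlantScoringParams | None = None
) -> tuple[float, int, str]:
    """Score one candidate site against a miRNA.

    The site is given 5'->3' as it appears on the transcript and is aligned
    antiparallel (read 3'->5') against the miRNA 5'->3'. A global affine-gap
    alignment minimizing the expectation is chosen by dynamic programming.

    Returns ``(expectation, seed_violations, alignment_rendering)`` where
    seed violations count every non-Watson-Crick event (mismatch, wobble
    unless ``seed_allow_gu``, or gap) at a seed-region miRNA position.
    """
    params = params or PlantScoringParams()
    if not mirna.sequence or not site:
        raise ValueError("empty miRNA or site")
    w = normalize_rna(site)[::-1]  # site read 3'->5'
    m = mirna.sequence
    M, W = len(m), len(w)

    INF = math.inf
    # three-state affine DP, minimizing; D consumes a miRNA base, I a site base
    S = [[INF] * (W + 1) for _ in range(M + 1)]
    D = [[INF] * (W + 1) for _ in range(M + 1)]
    I = [[INF] * (W + 1) for _ in range(M + 1)]
    S[0][0] = 0.0
    for i in range(1, M + 1):
        step = (params.gap_open if i == 1 else params.gap_extend) * params.weight(i)
        D[i][0] = (D[i - 1][0] if i > 1 else S[0][0]) + step
    for j in range(1, W + 1):
        step = (params.gap_open if j == 1 else params.gap_extend) * params.weight(1)
        I[0][j] = (I[0][j - 1] if j > 1 else S[0][0]) + step
    for i in range(1, M + 1):
        wi = params.weight(i)
        for j in range(1, W + 1):
            sub = _pair_penalty(m[i - 1], w[j - 1], params) * wi
            S[i][j] = min(S[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1]) + sub
            D[i][j] = min(
                min(S[i - 1][j], I[i - 1][j]) + params.gap_open * wi,
                D[i - 1][j] + params.gap_extend * wi,
            )
            wnext = params.weight(min(i + 1, M))
            I[i][j] = min(
                min(S[i][j - 1], D[i][j - 1]) + params.gap_open * wnext,
                I[i][j - 1] + params.gap_extend * wnext,
            )

    # traceback
    events: list[tuple[str, int, str, str]] = []  # (kind, mirna_pos, m_char, w_char)
    i, j = M, W
    state = min(("S", "D", "I"), key=lambda s: {"S": S, "D": D, "I": I}[s][i][j])
    expectation = {"S": S, "D": D, "I": I}[state][i][j]
    while i > 0 or j > 0:
        if state == "S" and i > 0 and j > 0:
            sub = _pair_penalty(m[i - 1], w[j - 1], params) * params.weight(i)
            events.append(("pair", i, m[i - 1], w[j - 1]))
            prev = S[i][j] - sub
            for cand in ("S", "D", "I"):
                if abs({"S": S, "D": D, "I": I}[cand][i - 1][j - 1] - prev) < 1e-9:
                    state = cand
                    break
            i, j = i - 1, j - 1
        elif state == "D" and i > 0:
            events.append(("del", i, m[i - 1], "-"))
            wi = params.weight(i)
            val = D[i][j]
            if i > 1 or j > 0:
                if abs(D[i - 1][j] + params.gap_extend * wi - val) < 1e-9:
                    state = "D"
                elif abs(S[i - 1][j] + params.gap_open * wi - val) < 1e-9:
                    state = "S"
                else:
                    state = "I"
            i -= 1
        else:  # insertion of a site base
            events.append(("ins", min(i + 1, M), "-", w[j - 1]))
            wnext = params.weight(min(i + 1, M))
            val = I[i][j]
            if abs(I[i][j - 1] + params.gap_extend * wnext - val) < 1e-9:
                state = "I"
            elif abs(S[i][j - 1] + params.gap_open * wnext - val) < 1e-9:
                state = "S"
            else:
                state = "D"
            j -= 1
    events.reverse()

    seed_violations = 0
    top, mid, bot = [], [], []
    for kind, pos, mc, wc in events:
        if kind == "pair":
            pair = mc + wc
            if pair in WC_PAIRS:
                mark = "|"
            elif pair in GU_PAIRS:
                mark = ":"
            else:
                mark = " "
            violation = mark == " " or (mark == ":" and not params.seed_allow_gu)
        else:
            mark = " "
            violation = True
        if violation and params.in_seed(pos):
            seed_violations += 1
        top.append(mc)
        mid.append(mark)
        bot.append(wc)
    alignment = (
        f"miRNA  5' {''.join(top)} 3'\n"
        f"          {''.join(mid)}\n"
        f"target 3' {''.join(bot)} 5'"
    )
    return expectation, seed_violations, alignment


def _ungapped_scan(
    mirna: MiRNA, enc_t: np.ndarray, params: PlantScoringParams
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized expectation + seed-violation count for every ungapped
    window of exactly miRNA length; miRNA position i pairs site position
    start + L-1-i (antiparallel)."""
    L = len(mirna)
    n_starts = len(enc_t) - L + 1
    if n_starts <= 0:
        return np.empty(0), np.empty(0, dtype=int)
    pen = np.zeros((4, 4))
    viol = np.zeros((4, 4), dtype=np.int64)
    for x in "ACGU":
        for y in "ACGU":
            p = _pair_penalty(x, y, params)
            pen[_BASE_CODE[x], _BASE_CODE[y]] = p
            is_gu = (x + y) in GU_PAIRS
            viol[_BASE_CODE[x], _BASE_CODE[y]] = int(
                p > 0 and not (is_gu and params.seed_allow_gu)
            )
    scores = np.zeros(n_starts)
    seedv = np.zeros(n_starts, dtype=np.int64)
    enc_m = _encode(mirna.sequence)
    for i in range(L):
        off = L - 1 - i
        col = enc_t[off : off + n_starts]
        scores += params.weight(i + 1) * pen[enc_m[i], col]
        if params.in_seed(i + 1):
            seedv += viol[enc_m[i], col]
    return scores, seedv


def scan_plant_targets(
    mirnas: list[MiRNA],
    transcripts: list[TranscriptRecord],
    params: PlantScoringParams | None = None,
    *,
    exhaustive: bool = False,
) -> list[PlantTargetHit]:
    """Scan transcripts for plant-style complementary sites.

    A fast vectorized ungapped pass proposes candidate windows; candidates
    within ``gap_open + 3 * gap_extend`` of the cutoff are re-scored with
    the full gapped DP over window lengths L-2..L+2 (a single gap already
    costs at least ``gap_open``, so sites needing deeper rescue cannot pass
    the expectation cutoff). ``exhaustive=True`` runs the gapped DP at every
    window position instead and is used as the reference in tests.

    Hits must satisfy ``expectation <= expectation_max``,
    ``seed_violations <= seed_mismatches_allowed`` and a window length of at
    least ``hsp_min_len``; overlapping windows are collapsed to their best
    position and at most ``top_n`` hits are kept per miRNA, ordered by
    (expectation, transcript id, site start).
    """
    params = params or PlantScoringParams()
    for rec in transcripts:
        if rec.region is Region.PROTEIN:
            raise InputTypeError(f"protein record {rec.id} passed to nucleotide scanner")

    hits: list[PlantTargetHit] = []
    margin = params.gap_open + 3 * params.gap_extend
    for mirna in mirnas:
        L = len(mirna)
        per_mirna: list[PlantTargetHit] = []
        for rec in transcripts:
            enc_t = _encode(rec.sequence)
            T = len(rec.sequence)
            if L > T or L < params.hsp_min_len:
                continue
            if exhaustive:
                cand_starts = list(range(T - L + 1))
            else:
                scores, _ = _ungapped_scan(mirna, enc_t, params)
                cand_starts = np.nonzero(scores <= params.expectation_max + margin)[0]
            best: dict[int, tuple[float, int, int, int, str]] = {}
            for s in cand_starts:
                s = int(s)
                chosen = None
                for wlen in range(max(params.hsp_min_len, L - 2), L + 3):
                    if s + wlen > T:
                        continue
                    exp, sv, aln = plant_site_score(
                        mirna, rec.sequence[s : s + wlen], params
                    )
                    key = (exp, wlen)
                    if chosen is None or key < (chosen[0], chosen[3] - chosen[2]):
                        chosen = (exp, sv, s, s + wlen, aln)
                if chosen is not None:
                    best[chosen[2]] = chosen
            # collapse overlapping candidate windows to the single best one
            ordered = sorted(best.values(), key=lambda c: (c[0], c[2]))
            taken: list[tuple[float, int, int, int, str]] = []
            for cand in ordered:
                if any(not (cand[3] <= t[2] or cand[2] >= t[3]) for t in taken):
                    continue
                taken.append(cand)
            for exp, sv, start, end, aln in taken:
                if exp <= params.expectation_max and sv <= params.seed_mismatches_allowed:
                    per_mirna.append(
                        PlantTargetHit(
                            mirna_id=mirna.id,
                            transcript_id=rec.id,
                            gene_id=rec.gene_id,
                            site_start=start,
                            site_end=end,
                            expectation=exp,
                            seed_violations=sv,
                            alignment=aln,
                        )
                    )
        per_mirna.sort(key=lambda h: (h.expectation, h.transcript_id, h.site_start))
        hits.extend(per_mirna[: params.top_n])
    return hits


# --------------------------------------------------------------------------
# duplex minimum free energy
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplexParams:
    mfe_threshold: float = -36.5  # network mode; alignment mode uses -34.7
    max_targets_per_mirna: int = 50
    energy_table_id: str = "turner1999"
    max_loop: int = 15  # max unpaired bases per strand between two pairs
    apply_terminal_au: bool = False
    apply_init: bool = False

    def __post_init__(self) -> None:
        if self.mfe_threshold >= 0:
            raise ValueError("mfe_threshold must be negative")
        if self.max_targets_per_mirna < 1:
            raise ValueError("max_targets_per_mirna must be >= 1")

    @property
    def table(self) -> EnergyTable:
        return load_energy_table(self.energy_table_id)


@dataclass(frozen=True)
class DuplexResult:
    mfe: float
    structure: str
    site_start: int  # 0-based half-open, paired span on the target, 5'->3'
    site_end: int
    mirna_start: int
    mirna_end: int
    pairs: tuple[tuple[int, int], ...] = ()  # (miRNA index, target index)

    @property
    def is_hit(self) -> bool:
        return math.isfinite(self.mfe)


NO_DUPLEX = DuplexResult(mfe=math.inf, structure="", site_start=0, site_end=0,
                         mirna_start=0, mirna_end=0)


@dataclass(frozen=True)
class DuplexTargetHit:
    mirna_id: str
    transcript_id: str
    gene_id: str
    site_start: int
    site_end: int
    mfe: float
    duplex_structure: str


def _end_terms(table: EnergyTable, params: DuplexParams, p_first: int, p_last: int) -> float:
    e = 0.0
    if params.apply_init:
        e += table.duplex_init
    e += table.end_penalty(p_first, apply_terminal_au=params.apply_terminal_au)
    e += table.end_penalty(p_last, apply_terminal_au=params.apply_terminal_au)
    return e


def duplex_mfe(
    mirna: MiRNA, site: str, params: DuplexParams | None = None
) -> DuplexResult:
    """Minimum free energy of the intermolecular miRNA:site duplex.

    Dynamic program over antiparallel pairings: ``E[i][j]`` is the best
    energy of a duplex whose 3'-most miRNA pair is (miRNA position i, target
    position j), extending a previous pair through a stack, bulge or
    interior loop (each strand's loop side capped at ``max_loop``).
    Unpaired overhangs are free. Returns the ``NO_DUPLEX`` sentinel when no
    canonical pair exists.
    """
    params = params or DuplexParams()
    table = params.table
    m = mirna.sequence
    t = normalize_rna(site)
    r = t[::-1]
    M, T = len(m), len(r)
    if M == 0 or T == 0:
        return NO_DUPLEX

    enc_m, enc_r = _encode(m), _encode(r)
    P = _PT[enc_m[:, None], enc_r[None, :]]  # (M, T) pair types
    if not (P >= 0).any():
        return NO_DUPLEX

    STK = np.array(table.stack)
    INF = math.inf
    E = np.full((M, T), INF)
    BDI = np.zeros((M, T), dtype=np.int16)
    BDJ = np.zeros((M, T), dtype=np.int16)
    ML = params.max_loop

    for i in range(M):
        valid = P[i] >= 0
        row = np.where(valid, 0.0, INF)
        bdi = np.zeros(T, dtype=np.int16)
        bdj = np.zeros(T, dtype=np.int16)
        for di in range(1, min(i, ML + 1) + 1):
            Eprev = E[i - di]
            Pprev = P[i - di]
            if not np.isfinite(Eprev).any():
                continue
            for dj in range(1, min(T - 1, ML + 1) + 1):
                n1, n2 = di - 1, dj - 1
                prev = Eprev[:-dj]
                if n1 == 0 and n2 == 0:
                    cost = STK[Pprev[:-dj], P[i][dj:]]
                elif n1 == 0 or n2 == 0:
                    n = n1 + n2
                    cost = table.bulge_energy(n)
                    if n == 1:
                        cost = cost + STK[Pprev[:-dj], P[i][dj:]]
                else:
                    cost = table.internal_energy(n1, n2)
                cand = prev + cost
                upd = valid[dj:] & (cand < row[dj:])
                if upd.any():
                    row[dj:][upd] = cand[upd]
                    bdi[dj:][upd] = di
                    bdj[dj:][upd] = dj
        E[i] = row
        BDI[i], BDJ[i] = bdi, bdj

    # best terminal pair, with optional helix-end terms on both closing pairs
    if params.apply_terminal_au or params.apply_init:
        best = (INF, -1, -1)
        for i in range(M):
            for j in np.nonzero(np.isfinite(E[i]))[0]:
                fi, fj = i, int(j)
                while BDI[fi][fj] != 0:
                    di, dj = BDI[fi][fj], BDJ[fi][fj]
                    fi, fj = fi - di, fj - dj
                total = E[i][j] + _end_terms(table, params, P[fi][fj], P[i][j])
                if total < best[0]:
                    best = (total, i, int(j))
    else:
        bi, bj = np.unravel_index(int(np.argmin(E)), E.shape)
        best = (float(E[bi][bj]), int(bi), int(bj))
    if not math.isfinite(best[0]):
        return NO_DUPLEX

    # traceback
    i, j = best[1], best[2]
    pairs_r = [(i, j)]
    while BDI[i][j] != 0:
        di, dj = int(BDI[i][j]), int(BDJ[i][j])
        i, j = i - di, j - dj
        pairs_r.append((i, j))
    pairs_r.reverse()
    # convert reversed-target coordinates back to the 5'->3' target frame
    pairs = tuple((pi, T - 1 - pj) for pi, pj in pairs_r)
    site_start = pairs[-1][1]
    site_end = pairs[0][1] + 1
    structure = _render_duplex(m, t, pairs)
    return DuplexResult(
        mfe=round(best[0], 10),
        structure=structure,
        site_start=site_start,
        site_end=site_end,
        mirna_start=pairs[0][0],
        mirna_end=pairs[-1][0] + 1,
        pairs=pairs,
    )


def _render_duplex(m: str, t: str, pairs: tuple[tuple[int, int], ...]) -> str:
    """Aligned two-strand rendering of the paired region (loops padded)."""
    top, mid, bot = [], [], []
    for k, (i, j) in enumerate(pairs):
        if k > 0:
            pi, pj = pairs[k - 1]
            gm = m[pi + 1 : i]
            gt = t[j + 1 : pj][::-1]
            width = max(len(gm), len(gt))
            top.append(gm.ljust(width, "-"))
            mid.append(" " * width)
            bot.append(gt.ljust(width, "-"))
        top.append(m[i])
        mid.append("|" if m[i] + t[j] in WC_PAIRS else ":")
        bot.append(t[j])
    return (
        f"miRNA  5' {''.join(top)} 3'\n"
        f"          {''.join(mid)}\n"
        f"target 3' {''.join(bot)} 5'"
    )


def scan_human_targets(
    mirnas: list[MiRNA],
    utrs: list[TranscriptRecord],
    params: DuplexParams | None = None,
) -> list[DuplexTargetHit]:
    """Duplex-MFE scan of each miRNA against each transcript.

    The duplex DP is already local in the target, so one pass per
    (miRNA, transcript) yields the minimal-MFE site. Hits with
    ``mfe <= mfe_threshold`` are kept; per miRNA the best
    ``max_targets_per_mirna`` by ascending MFE (ties by transcript id)
    are returned.
    """
    params = params or DuplexParams()
    for rec in utrs:
        if rec.region is Region.PROTEIN:
            raise InputTypeError(f"protein record {rec.id} passed to nucleotide scanner")
    out: list[DuplexTargetHit] = []
    for mirna in mirnas:
        per: list[DuplexTargetHit] = []
        for rec in utrs:
            res = duplex_mfe(mirna, rec.sequence, params)
            if res.is_hit and res.mfe <= params.mfe_threshold:
                per.append(
                    DuplexTargetHit(
                        mirna_id=mirna.id,
                        transcript_id=rec.id,
                        gene_id=rec.gene_id,
                        site_start=res.site_start,
                        site_end=res.site_end,
                        mfe=res.mfe,
                        duplex_structure=res.structure,
                    )
                )
        per.sort(key=lambda h: (h.mfe, h.transcript_id, h.site_start))
        out.extend(per[: params.max_targets_per_mirna])
    return out
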