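"""Translated protein-vs-genome homology search (transposase scan).

A self-contained seed-and-extend engine over six-frame translations: exact
4-mer protein seeds, two-hit confirmation on a diagonal within 40 residues,
ungapped X-drop extension under BLOSUM62, and Karlin-Altschul significance
(E = K*m*n*exp(-lambda*S), lambda=0.318, K=0.13, m = query residues,
n = genome bases).  Hits below the e-value ceiling are reported on both
strands; overlapping hits from one query are merged into a locus and
near-duplicate loci from different queries are collapsed to the best one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._engine import AA_K, AA_LAMBDA, evalue, resolve_overlaps
from ._motifs import blosum62
from .genome_io import GenomeIndex, Interval, six_frame_translate

__all__ = ["ProteinQuery", "TranslatedHit", "Locus", "search_transposase", "merge_hit_loci"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_ORD = np.full(128, -1, dtype=np.int64)
for _i, _a in enumerate(_AA):
    _AA_ORD[ord(_a)] = _i

WORD = 4
TWO_HIT_SPAN = 40
XDROP = 25
JOIN_GAP_NT = 30


@dataclass(frozen=True)
class ProteinQuery:
    id: str
    seq: str
    source_group: str | None = None

    def __post_init__(self):
        if len(self.seq) < 50:
            raise ValueError(f"query {self.id!r} shorter than 50 residues")


@dataclass
class TranslatedHit:
    interval: Interval
    query_id: str
    raw_score: float
    bitscore: float
    evalue: float
    frame: int  # 1..3, negated on the minus strand


@dataclass
class Locus:
    interval: Interval
    best_evalue: float


def _protein_codes(seq: str, k: int = WORD) -> np.ndarray:
    vals = _AA_ORD[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if len(vals) < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(vals, k)
    weights = 20 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ weights
    codes[np.any(win < 0, axis=1)] = -1
    return codes


def _extend_ungapped(qseq: str, fseq: str, qs: int, qe: int, diag: int):
    """X-drop extension of the [qs,qe) span along a fixed diagonal."""
    score = sum(blosum62(qseq[i], fseq[i + diag]) for i in range(qs, qe))
    # left
    best = 0.0
    cur = 0.0
    best_i = qs
    i = qs - 1
    while i >= 0 and i + diag >= 0:
        cur += blosum62(qseq[i], fseq[i + diag])
        if cur > best:
            best, best_i = cur, i
        if best - cur > XDROP:
            break
        i -= 1
    score += best
    qs = best_i
    # right
    best = 0.0
    cur = 0.0
    best_j = qe
    j = qe
    while j < len(qseq) and j + diag < len(fseq):
        cur += blosum62(qseq[j], fseq[j + diag])
        if cur > best:
            best, best_j = cur, j + 1
        if best - cur > XDROP:
            break
        j += 1
    score += best
    return qs, best_j, score


def _frame_to_genome(frame_idx: int, a: int, b: int, L: int) -> tuple[int, int, str, int]:
    """Protein span [a,b) on frame frame_idx (0-5) -> forward nt interval."""
    f = frame_idx % 3
    if frame_idx < 3:
        return f + 3 * a, f + 3 * b, "+", f + 1
    s, e = f + 3 * a, f + 3 * b  # on the revcomp
    return L - e, L - s, "-", -(f + 1)


def search_transposase(
    genome: GenomeIndex,
    queries: list[ProteinQuery],
    evalue_max: float = 1e-4,
) -> list[TranslatedHit]:
    """Candidate transposase loci with e-value below `evalue_max`."""
    if not queries:
        raise ValueError("empty query set")
    n_genome = genome.total_length

    # shared seed dictionary over all queries
    code_map: dict[int, list[tuple[int, int]]] = {}
    for qi, q in enumerate(queries):
        for qpos, c in enumerate(_protein_codes(q.seq)):
            if c >= 0:
                code_map.setdefault(int(c), []).append((qi, qpos))
    keys = np.fromiter(code_map.keys(), dtype=np.int64, count=len(code_map))

    raw_hits: list[TranslatedHit] = []
    for seq_id in genome.ids:
        seq = genome.sequence(seq_id)
        L = len(seq)
        frames = six_frame_translate(seq)
        for fidx, fseq in enumerate(frames):
            fcodes = _protein_codes(fseq)
            if fcodes.size == 0 or keys.size == 0:
                continue
            pos = np.nonzero(np.isin(fcodes, keys))[0]
            per_query: dict[int, dict[int, list[int]]] = {}
            for g in pos:
                for qi, qpos in code_map[int(fcodes[g])]:
                    per_query.setdefault(qi, {}).setdefault(int(g) - qpos, []).append(qpos)
            for qi, diags in per_query.items():
                qseq = queries[qi].seq
                spans: list[tuple[int, int, int]] = []  # (diag, qs, qe)
                for diag, qps in diags.items():
                    qps.sort()
                    run = [qps[0]]
                    for qp in qps[1:]:
                        if qp - run[-1] <= TWO_HIT_SPAN:
                            run.append(qp)
                        else:
                            if len(run) >= 2:
                                spans.append((diag, run[0], run[-1] + WORD))
                            run = [qp]
                    if len(run) >= 2:
                        spans.append((diag, run[0], run[-1] + WORD))
                for diag, qs, qe in spans:
                    qs2, qe2, score = _extend_ungapped(qseq, fseq, qs, qe, diag)
                    E = evalue(score, len(qseq), n_genome, AA_LAMBDA, AA_K)
                    if E >= evalue_max:
                        continue
                    a, b = qs2 + diag, qe2 + diag  # frame protein coords
                    nt_s, nt_e, strand, frame = _frame_to_genome(fidx, a, b, L)
                    bits = (AA_LAMBDA * score - math.log(AA_K)) / math.log(2)
                    raw_hits.append(
                        TranslatedHit(
                            Interval(seq_id, nt_s, nt_e, strand),
                            queries[qi].id, score, bits, E, frame,
                        )
                    )

    merged = _merge_same_query(raw_hits)
    return resolve_overlaps(merged, key=lambda h: h.raw_score)


def _merge_same_query(hits: list[TranslatedHit]) -> list[TranslatedHit]:
    """Union overlapping/adjacent hits of one query on one strand."""
    out: list[TranslatedHit] = []
    groups: dict[tuple, list[TranslatedHit]] = {}
    for h in hits:
        groups.setdefault((h.query_id, h.interval.seq_id, h.interval.strand), []).append(h)
    for key in sorted(groups):
        hs = sorted(groups[key], key=lambda h: h.interval.start)
        cur = hs[0]
        for h in hs[1:]:
            if h.interval.start <= cur.interval.end + JOIN_GAP_NT:
                best = h if h.raw_score > cur.raw_score else cur
                cur = TranslatedHit(
                    Interval(
                        cur.interval.seq_id,
                        cur.interval.start,
                        max(cur.interval.end, h.interval.end),
                        cur.interval.strand,
                    ),
                    cur.query_id,
                    max(cur.raw_score, h.raw_score),
                    max(cur.bitscore, h.bitscore),
                    min(cur.evalue, h.evalue),
                    best.frame,
                )
            else:
                out.append(cur)
                cur = h
        out.append(cur)
    out.sort(key=lambda h: (h.interval, h.query_id))
    return out


def merge_hit_loci(hits: list[TranslatedHit], max_gap_bp: int = 500) -> list[Locus]:
    """Merge same-strand hits within `max_gap_bp` into candidate loci."""
    loci: list[Locus] = []
    groups: dict[tuple, list[TranslatedHit]] = {}
    for h in hits:
        groups.setdefault((h.interval.seq_id, h.interval.strand), []).append(h)
    for key in sorted(groups):
        hs = sorted(groups[key], key=lambda h: h.interval.start)
        cur_iv = hs[0].interval
        cur_e = hs[0].evalue
        for h in hs[1:]:
            if h.interval.start <= cur_iv.end + max_gap_bp:
                cur_iv = Interval(
                    cur_iv.seq_id, cur_iv.start, max(cur_iv.end, h.interval.end), cur_iv.strand
                )
                cur_e = min(cur_e, h.evalue)
            else:
                loci.append(Locus(cur_iv, cur_e))
                cur_iv, cur_e = h.interval, h.evalue
        loci.append(Locus(cur_iv, cur_e))
    loci.sort(key=lambda l: (l.interval, l.best_evalue))
    return loci
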