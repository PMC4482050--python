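"""Shared seed-and-extend machinery for the nucleotide search engines.

Seeds are exact k-mer matches found by vectorised code comparison; candidate
loci are diagonal clusters of seeds; each cluster is aligned with edlib and the
unit-cost path is rescored with a BLAST-like affine scheme (+1 match, -2
mismatch, gap open -5 / extend -2) and trimmed to its maximum-scoring local
segment.  Significance uses the ungapped Karlin-Altschul formula
E = K * m * n * exp(-lambda * S).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import edlib
import numpy as np

# Ungapped Karlin-Altschul constants.
NT_LAMBDA = 1.33
NT_K = 0.621
AA_LAMBDA = 0.318
AA_K = 0.13

MATCH = 1
MISMATCH = -2
GAP_OPEN = -5
GAP_EXTEND = -2

_NT_ORD = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _NT_ORD[ord(_b)] = _i

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def evalue(score: float, m: int, n: int, lam: float = NT_LAMBDA, k: float = NT_K) -> float:
    return k * m * n * math.exp(-lam * score)


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Rolling k-mer codes base 4; windows containing non-ACGT get code -1."""
    vals = _NT_ORD[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(vals) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(vals, k)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ weights
    codes[np.any(win < 0, axis=1)] = -1
    return codes


def seed_matches(probe_codes: np.ndarray, target_codes: np.ndarray):
    """(target_pos, probe_pos) pairs of exact k-mer matches."""
    valid_probe = probe_codes >= 0
    code_to_q: dict[int, list[int]] = {}
    for q, c in enumerate(probe_codes):
        if c >= 0:
            code_to_q.setdefault(int(c), []).append(q)
    keys = np.fromiter(code_to_q.keys(), dtype=np.int64, count=len(code_to_q))
    if keys.size == 0:
        return []
    hit_pos = np.nonzero(np.isin(target_codes, keys))[0]
    out = []
    for g in hit_pos:
        for q in code_to_q[int(target_codes[g])]:
            out.append((int(g), q))
    return out


@dataclass
class SeedCluster:
    gmin: int
    gmax: int  # inclusive of seed start positions
    qmin: int
    qmax: int
    diag: int
    n_seeds: int


def cluster_seeds(
    seeds, max_diag_drift: int = 30, max_gap: int = 400, min_seeds: int = 2
) -> list[SeedCluster]:
    """Greedy chaining of (gpos, qpos) seeds into diagonal clusters."""
    if not seeds:
        return []
    seeds = sorted(seeds)
    open_clusters: list[SeedCluster] = []
    done: list[SeedCluster] = []
    for g, q in seeds:
        d = g - q
        best = None
        for c in open_clusters:
            if g - c.gmax > max_gap:
                continue
            if abs(d - c.diag) <= max_diag_drift and q >= c.qmin:
                if best is None or abs(d - c.diag) < abs(d - best.diag):
                    best = c
        # retire clusters that can no longer accept seeds
        still = []
        for c in open_clusters:
            if g - c.gmax > max_gap and c is not best:
                done.append(c)
            else:
                still.append(c)
        open_clusters = still
        if best is None:
            open_clusters.append(SeedCluster(g, g, q, q, d, 1))
        else:
            best.gmax = max(best.gmax, g)
            best.qmax = max(best.qmax, q)
            best.gmin = min(best.gmin, g)
            best.qmin = min(best.qmin, q)
            best.diag = g - q
            best.n_seeds += 1
    done.extend(open_clusters)
    return [c for c in done if c.n_seeds >= min_seeds]


@dataclass
class LocalAlignment:
    """Affine-rescored local alignment of probe vs a target window."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    columns: int
    score: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _parse_cigar(cigar: str):
    for m in _CIGAR_RE.finditer(cigar):
        yield int(m.group(1)), m.group(2)


def local_align(probe: str, window: str) -> LocalAlignment | None:
    """Best local alignment of probe within window along the edlib path.

    edlib gives the optimal unit-cost path with the probe as an infix query
    (mode HW); the path is then rescored column-by-column with the affine
    scheme and trimmed to the maximum-scoring contiguous segment (Kadane),
    which converts the semi-global path into a BLAST-like local hit.
    """
    if not probe or not window:
        return None
    res = edlib.align(probe, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t0 = res["locations"][0][0]
    # expand cigar into per-column (op, score)
    cols: list[tuple[str, int]] = []
    for length, op in _parse_cigar(res["cigar"]):
        if op in "ID":
            cols.append((op, GAP_OPEN))
            cols.extend((op, GAP_EXTEND) for _ in range(length - 1))
        else:
            s = MATCH if op == "=" else MISMATCH
            cols.extend((op, s) for _ in range(length))
    # Kadane over column scores
    best_s = cur_s = 0
    best_range = (0, 0)
    cur_start = 0
    for i, (_, s) in enumerate(cols):
        cur_s += s
        if cur_s <= 0:
            cur_s = 0
            cur_start = i + 1
        elif cur_s > best_s:
            best_s = cur_s
            best_range = (cur_start, i + 1)
    if best_s <= 0:
        return None
    a, b = best_range
    # walk the path to map trimmed columns to probe/target coordinates
    q = 0
    t = t0
    q_start = q_end = t_start = t_end = None
    matches = 0
    for i, (op, _) in enumerate(cols):
        if i == a:
            q_start, t_start = q, t
        if op == "=":
            matches += 1 if a <= i < b else 0
            q += 1
            t += 1
        elif op == "X":
            q += 1
            t += 1
        elif op == "I":  # in probe, not target
            q += 1
        else:  # 'D': in target, not probe
            t += 1
        if i == b - 1:
            q_end, t_end = q, t
            break
    columns = b - a
    # polish: the unit-cost path can trade exact-match edge columns for
    # mismatches against flanking sequence; greedy exact extension restores
    # the score-optimal local ends
    while q_start > 0 and t_start > 0 and probe[q_start - 1] == window[t_start - 1]:
        q_start -= 1
        t_start -= 1
        matches += 1
        columns += 1
        best_s += MATCH
    while q_end < len(probe) and t_end < len(window) and probe[q_end] == window[t_end]:
        q_end += 1
        t_end += 1
        matches += 1
        columns += 1
        best_s += MATCH
    return LocalAlignment(q_start, q_end, t_start, t_end, matches, columns, best_s)


def resolve_overlaps(hits, key, min_frac: float = 0.5):
    """Drop hits covered for >= min_frac of their span by a better hit.

    `hits` must expose .interval; `key` gives the quality (higher is better).
    Deterministic: quality-sorted with position as the tie-break, so partial
    re-alignments of an already-kept locus are discarded.
    """
    ordered = sorted(hits, key=lambda h: h.interval)
    ordered.sort(key=key, reverse=True)  # stable: ties stay in position order
    kept = []
    for h in ordered:
        ok = True
        for k in kept:
            if k.interval.seq_id != h.interval.seq_id:
                continue
            ov = min(k.interval.end, h.interval.end) - max(
                k.interval.start, h.interval.start
            )
            if ov > 0 and ov >= min_frac * len(h.interval):
                ok = False
                break
        if ok:
            kept.append(h)
    kept.sort(key=lambda h: h.interval)
    return kept
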