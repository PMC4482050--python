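"""Structural characterisation of element families.

Terminal inverted repeats (TIRs) are found by an end-anchored comparison of
the element's 5' prefix with the reverse complement of its 3' suffix: the
repeat must include both termini, interior-only inverted repeats are ignored.
Target site duplications (TSDs) are inferred by comparing, per full-length
copy, the last L bases of the left flank with the first L bases of the right
flank for L = 1..10 and choosing the largest L with majority support.  The
TSD-less Spy lineage is detected instead by its AAATTT insertion preference:
the two flanks must join across some split of the motif.  Paralogous empty
sites (related loci carrying the pre-insertion sequence) confirm the cut
mechanics; a site is reconstructed by joining the flanks with one copy of the
target retained.  Sequence logos are emitted as frequency/information
matrices (info = 2 - Shannon entropy in bits), not graphics.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._engine import cluster_seeds, kmer_codes, local_align, seed_matches
from ._motifs import iupac_for
from .family_builder import ExtendedCopy
from .genome_io import GenomeIndex, Interval, revcomp

__all__ = [
    "TIRModel",
    "TSDModel",
    "EmptySiteMatch",
    "LogoMatrix",
    "detect_tirs",
    "is_full_length",
    "infer_tsd",
    "test_spy_motif",
    "reconstruct_empty_site",
    "find_paralogous_empty_sites",
    "logo_matrix",
]

SPY_MOTIF = "AAATTT"


@dataclass
class TIRModel:
    tir5: str
    tir3: str
    length: int
    mismatches: int
    first_bases: str


@dataclass
class TSDModel:
    length: int
    consensus: str
    support: float
    outer5: str | None = None
    outer3: str | None = None
    alternative_length: int | None = None
    n_copies: int = 0


@dataclass
class EmptySiteMatch:
    interval: Interval
    identity: float
    reconstructed_seq: str


@dataclass
class LogoMatrix:
    positions: list[dict]
    info_bits: list[float]


def detect_tirs(
    element: str,
    min_len: int = 5,
    max_len: int = 1100,
    max_mismatch_frac: float = 0.2,
    window: int = 1200,
) -> TIRModel | None:
    """End-anchored TIR search; best-scoring terminal inverted repeat."""
    n = len(element)
    if n <= 2 * min_len:
        raise ValueError("element too short for TIR detection")
    w = min(window, max_len, n // 2)
    pre = element[:w]
    suf_rc = revcomp(element[-w:])  # aligned so index i pairs with terminus i
    match = np.fromiter((a == b for a, b in zip(pre, suf_rc)), dtype=np.int32)
    cum = np.concatenate([[0], np.cumsum(match)])
    best = None
    for L in range(min_len, w + 1):
        m = int(cum[L])
        mism = L - m
        if mism / L > max_mismatch_frac:
            continue
        score = m - mism
        if score <= 0:
            continue
        key = (score, -L)
        if best is None or key > best[0]:
            best = (key, L, mism)
    if best is None:
        return None
    _, L, mism = best
    return TIRModel(element[:L], element[-L:], L, mism, element[: min(3, L)])


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def is_full_length(copy: ExtendedCopy, tir: TIRModel, tol_mismatch: int = 2) -> bool:
    """Both termini of the copy carry the family TIRs (end-anchored)."""
    s = copy.core_seq
    L = tir.length
    if len(s) < 2 * L:
        return False
    return (
        _hamming(s[:L], tir.tir5) <= tol_mismatch
        and _hamming(s[-L:], tir.tir3) <= tol_mismatch
    )


def infer_tsd(
    full_length_copies: list[ExtendedCopy],
    max_len: int = 10,
    min_support: float = 0.5,
    mismatch_tol: int = 0,
    iupac_min_freq: float = 0.2,
    outer_min_freq: float = 0.8,
) -> TSDModel:
    """Duplication length, IUPAC consensus and outer-base conservation."""
    if len(full_length_copies) < 3:
        raise ValueError("insufficient copies: need >= 3 full-length copies")
    pairs = [(c.left_flank, c.right_flank) for c in full_length_copies]
    n = len(pairs)
    chosen = 0
    chosen_support = 0.0
    for L in range(1, max_len + 1):
        k = sum(
            1
            for l, r in pairs
            if len(l) >= L and len(r) >= L and _hamming(l[-L:], r[:L]) <= mismatch_tol
        )
        if k / n >= min_support:
            chosen, chosen_support = L, k / n
    if chosen == 0:
        return TSDModel(0, "", 0.0, n_copies=n)
    L = chosen
    supporting = [
        (l, r)
        for l, r in pairs
        if len(l) >= L + 1 and len(r) >= L + 1 and _hamming(l[-L:], r[:L]) <= mismatch_tol
    ]
    tsds = [l[-L:] for l, _ in supporting]
    consensus = []
    for i in range(L):
        freq = Counter(t[i] for t in tsds)
        total = sum(freq.values())
        bases = frozenset(b for b in "ACGT" if freq.get(b, 0) / total >= iupac_min_freq)
        if not bases:
            bases = frozenset([freq.most_common(1)[0][0]])
        consensus.append(iupac_for(bases))
    outer5 = outer3 = None
    o5 = Counter(l[-(L + 1)] for l, _ in supporting)
    o3 = Counter(r[L] for _, r in supporting)
    if o5 and o5.most_common(1)[0][1] / len(supporting) >= outer_min_freq:
        outer5 = o5.most_common(1)[0][0]
    if o3 and o3.most_common(1)[0][1] / len(supporting) >= outer_min_freq:
        outer3 = o3.most_common(1)[0][0]
    alt = L + 2 if (outer5 and outer3) else None
    return TSDModel(L, "".join(consensus), chosen_support, outer5, outer3, alt, n)


def test_spy_motif(
    full_length_copies: list[ExtendedCopy],
    motif: str = SPY_MOTIF,
    min_frac: float = 0.5,
) -> float:
    """Fraction of copies whose flanks join across a split of `motif`."""
    if not full_length_copies:
        return 0.0
    k = 0
    for c in full_length_copies:
        if any(
            c.left_flank.endswith(motif[:s]) and c.right_flank.startswith(motif[s:])
            for s in range(len(motif) + 1)
        ):
            k += 1
    return k / len(full_length_copies)


def reconstruct_empty_site(
    copy: ExtendedCopy, tsd: TSDModel, flank_used: int = 30
) -> str:
    """Pre-insertion sequence: flanks joined with one target copy retained."""
    L = tsd.length
    if len(copy.left_flank) < flank_used or len(copy.right_flank) < L + flank_used:
        raise ValueError("flanks shorter than flank_used")
    return copy.left_flank[-flank_used:] + copy.right_flank[L : L + flank_used]


def find_paralogous_empty_sites(
    reconstructed: str,
    genome: GenomeIndex,
    family_copies: list[ExtendedCopy],
    min_identity: float = 0.85,
    junction: int | None = None,
    min_side: int = 15,
    word: int = 11,
) -> list[EmptySiteMatch]:
    """Matches of the reconstructed site elsewhere, spanning the junction."""
    if len(reconstructed) < 40:
        raise ValueError("reconstruction too short (need >= 40 bp)")
    if junction is None:
        junction = len(reconstructed) // 2
    exclude = [c.core.interval for c in family_copies]
    out: list[EmptySiteMatch] = []
    for seq_id in genome.ids:
        gseq = genome.sequence(seq_id)
        gcodes = kmer_codes(gseq, word)
        for strand in "+-":
            p = reconstructed if strand == "+" else revcomp(reconstructed)
            jpos = junction if strand == "+" else len(reconstructed) - junction
            for cl in cluster_seeds(seed_matches(kmer_codes(p, word), gcodes)):
                pad = 20
                ws = max(0, cl.gmin - cl.qmin - pad)
                we = min(len(gseq), cl.gmax + word + (len(p) - cl.qmax) + pad)
                aln = local_align(p, gseq[ws:we])
                if aln is None or aln.identity < min_identity:
                    continue
                if not (aln.q_start <= jpos - min_side and aln.q_end >= jpos + min_side):
                    continue
                iv = Interval(seq_id, ws + aln.t_start, ws + aln.t_end, strand)
                if any(iv.overlaps(e) for e in exclude):
                    continue
                out.append(EmptySiteMatch(iv, aln.identity, genome.extract(iv)))
    # deduplicate identical intervals found from both strands of a palindrome
    seen = set()
    uniq = []
    for m in sorted(out, key=lambda m: (m.interval, -m.identity)):
        k = (m.interval.seq_id, m.interval.start, m.interval.end)
        if k not in seen:
            seen.add(k)
            uniq.append(m)
    return uniq


def logo_matrix(seqs: list[str]) -> LogoMatrix:
    """Per-position base frequencies and information content (bits)."""
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("sequences must have equal length")
    positions = []
    info = []
    for i in range(n):
        col = [s[i] for s in seqs]
        bad = set(col) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT character in column {i}: {sorted(bad)}")
        cnt = Counter(col)
        freq = {b: cnt.get(b, 0) / len(col) for b in "ACGT"}
        h = -sum(f * math.log2(f) for f in freq.values() if f > 0)
        positions.append(freq)
        info.append(2.0 - h)
    return LogoMatrix(positions, info)
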