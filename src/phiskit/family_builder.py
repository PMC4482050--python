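"""From candidate loci to families: copy recruitment, flank extension,
multiple alignment, element boundary definition, consensus building.

Copy recruitment applies the classical family-membership thresholds strictly:
e-value < 1e-5, aligned length > 50 bp, nucleotide identity > 80% ("larger
than", so exact boundary values are excluded).  Identity is matches divided by
alignment columns, gaps included.  Element boundaries are defined on a
flank-extended multiple alignment: a smoothed column-consistency score finds
the conserved block, and the edges are then refined by maximising per-copy
target-site-duplication (or Spy AAA|TTT junction) support, the package's
automated stand-in for manual boundary curation.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._engine import (
    NT_K,
    NT_LAMBDA,
    cluster_seeds,
    evalue,
    kmer_codes,
    local_align,
    resolve_overlaps,
    seed_matches,
)
from .genome_io import GenomeIndex, Interval, SequenceRecord, read_fasta, revcomp

__all__ = [
    "CopyHit",
    "ExtendedCopy",
    "Family",
    "recruit_copies",
    "extend_and_orient",
    "align_copies",
    "define_boundaries",
    "build_consensus",
]

WORD = 11
SPY_MOTIF = "AAATTT"


@dataclass
class CopyHit:
    interval: Interval
    identity: float
    aln_length: int
    evalue: float
    score: int = 0


@dataclass
class ExtendedCopy:
    core: CopyHit
    left_flank: str
    right_flank: str
    oriented_seq: str
    core_seq: str
    left_truncated: bool = False  # flank clipped at a contig end
    right_truncated: bool = False


@dataclass
class Family:
    name: str
    consensus: str
    copies: list[ExtendedCopy] = field(default_factory=list)
    tir: object | None = None
    tsd: object | None = None
    orfs: list = field(default_factory=list)
    group: str = "unclassified"
    potential_active: bool = False
    spy_fraction: float = 0.0
    notes: list[str] = field(default_factory=list)


def recruit_copies(
    probe: str,
    genome: GenomeIndex,
    evalue_max: float = 1e-5,
    min_len: int = 50,
    min_identity: float = 0.80,
    word: int = WORD,
) -> list[CopyHit]:
    """Genomic copies of `probe` passing all three thresholds strictly."""
    if len(probe) < word:
        raise ValueError(f"probe shorter than word size {word}")
    n_genome = genome.total_length
    hits: list[CopyHit] = []
    for seq_id in genome.ids:
        gseq = genome.sequence(seq_id)
        gcodes = kmer_codes(gseq, word)
        for strand in "+-":
            p = probe if strand == "+" else revcomp(probe)
            pcodes = kmer_codes(p, word)
            for cl in cluster_seeds(seed_matches(pcodes, gcodes)):
                pad = 30
                ws = max(0, cl.gmin - cl.qmin - pad)
                we = min(len(gseq), cl.gmax + word + (len(p) - cl.qmax - word) + pad)
                aln = local_align(p, gseq[ws:we])
                if aln is None:
                    continue
                E = evalue(aln.score, len(probe), n_genome, NT_LAMBDA, NT_K)
                if not (E < evalue_max and aln.columns > min_len and aln.identity > min_identity):
                    continue
                hits.append(
                    CopyHit(
                        Interval(seq_id, ws + aln.t_start, ws + aln.t_end, strand),
                        aln.identity,
                        aln.columns,
                        E,
                        aln.score,
                    )
                )
    # score-ranked so a fragment re-alignment of a locus never outranks the
    # full-span hit that contains it; ties fall back to identity
    return resolve_overlaps(hits, key=lambda h: (h.score, h.identity))


def extend_and_orient(
    copies: list[CopyHit], genome: GenomeIndex, flank: int = 2000
) -> list[ExtendedCopy]:
    """Extend copies by `flank` bp each side, oriented to the element strand."""
    if not copies:
        raise ValueError("no copies to extend")
    out = []
    for c in copies:
        iv = c.interval
        glen = genome.length(iv.seq_id)
        ls = max(0, iv.start - flank)
        re_ = min(glen, iv.end + flank)
        left_g = genome.sequence(iv.seq_id)[ls : iv.start]
        right_g = genome.sequence(iv.seq_id)[iv.end : re_]
        core = genome.extract(iv)
        if iv.strand == "+":
            left, right = left_g, right_g
            lt, rt = len(left_g) < flank, len(right_g) < flank
        else:
            left, right = revcomp(right_g), revcomp(left_g)
            lt, rt = len(right_g) < flank, len(left_g) < flank
        out.append(ExtendedCopy(c, left, right, left + core + right, core, lt, rt))
    return out


def align_copies(copies: list[ExtendedCopy], mafft_path: str | None = None):
    """Multiple alignment of the flank-extended copies (delegated to MAFFT)."""
    if len(copies) < 2:
        raise ValueError("single copy: use the single-copy path (no alignment)")
    mafft = mafft_path or shutil.which("mafft")
    if mafft is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fa"
        outp = Path(tmp) / "out.fa"
        with open(inp, "w") as fh:
            for i, c in enumerate(copies):
                fh.write(f">row{i}\n{c.oriented_seq}\n")
        with open(outp, "w") as fh:
            subprocess.run(
                [mafft, "--retree", "2", "--maxiterate", "0", "--quiet",
                 "--thread", "1", str(inp)],
                stdout=fh,
                stderr=subprocess.DEVNULL,
                check=True,
            )
        recs = read_fasta(outp, dna=False)
    # restore input order and uppercase
    by_id = {r.id: r.seq.upper() for r in recs}
    return [SequenceRecord(f"row{i}", by_id[f"row{i}"]) for i in range(len(copies))]


def _column_scores(rows: list[str]) -> np.ndarray:
    """(occupancy x majority agreement) per alignment column."""
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    ncols = arr.shape[1]
    counts = np.zeros((4, ncols), dtype=np.int32)
    for i, b in enumerate("ACGT"):
        counts[i] = (arr == ord(b)).sum(axis=0)
    nongap = counts.sum(axis=0)
    maj = counts.max(axis=0)
    occ = nongap / len(rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        agr = np.where(nongap > 0, maj / np.maximum(nongap, 1), 0.0)
    return occ * agr


def _row_maps(rows: list[str]):
    """Per row: de-gapped sequence and column -> de-gapped index mapping."""
    seqs, maps = [], []
    for r in rows:
        idx = np.cumsum([c != "-" for c in r])
        maps.append(np.concatenate([[0], idx]))  # maps[col] = chars before col
        seqs.append(r.replace("-", ""))
    return seqs, maps


def _junction_support(seqs, maps, rows_ok, c1, c2, max_tsd=10):
    """Best (support, tsd_len) for an element spanning columns [c1, c2)."""
    lefts, rights = [], []
    for ri in rows_ok:
        s, m = seqs[ri], maps[ri]
        li = int(m[c1])
        ri_ = int(m[c2])
        lefts.append(s[max(0, li - 12) : li])
        rights.append(s[ri_ : ri_ + 12])
    n = len(lefts)
    if n == 0:
        return 0.0, 0
    best = (0.0, 0)
    for L in range(1, max_tsd + 1):
        k = sum(
            1
            for l, r in zip(lefts, rights)
            if len(l) >= L and len(r) >= L and l[-L:] == r[:L]
        )
        cand = (k / n, L)
        if cand >= best:
            best = cand
    # Spy-style junction: flanks join across a split of the AAATTT motif
    k = 0
    for l, r in zip(lefts, rights):
        if any(
            l.endswith(SPY_MOTIF[:s]) and r.startswith(SPY_MOTIF[s:])
            for s in range(len(SPY_MOTIF) + 1)
        ):
            k += 1
    if (k / n, 0) > best:
        best = (k / n, 0)
    return best


_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _binom_sf(k: int, n: int, p: float) -> float:
    """P(X > k) for X ~ Binomial(n, p)."""
    from scipy.stats import binom

    return float(binom.sf(k, n, p))


def _terminal_ir_score(seqs, maps, rows_ok, a: int, b: int, max_len: int = 40,
                       min_len: int = 5) -> float:
    """Mean per-row inverted-repeat score of the candidate element termini.

    For each covered row the candidate element is de-gapped and its prefix is
    compared, end-anchored, with the complement of its reversed suffix; the
    score is the best running (matches - mismatches).  Scoring each row on its
    own sequence keeps random flank columns from faking a repeat: chance
    matches do not replicate across copies.
    """
    total = 0.0
    for ri in rows_ok:
        s = seqs[ri][int(maps[ri][a]) : int(maps[ri][b])]
        n = len(s)
        best = 0
        m = 0
        for i in range(min(max_len, n // 2)):
            m += 1 if s[i] == _COMPL.get(s[n - 1 - i], "?") else -1
            if i + 1 >= min_len and m > best:
                best = m
        total += best
    return total / max(1, len(rows_ok))


def define_boundaries(
    alignment,
    threshold: float = 0.6,
    smooth: int = 11,
    refine: bool = True,
    refine_window: int = 15,
    min_block: int = 50,
) -> tuple[int, int] | None:
    """Element start/end columns of a flank-extended alignment, or None.

    The maximal contiguous block of smoothed column consistency >= `threshold`
    is taken as the rough element; its edges are then shifted (within
    `refine_window` columns) to the position with the strongest per-copy
    TSD/junction support, which peels conserved target-site bases off the
    element.  Returns None when no block clears the threshold.
    """
    rows = [r.seq for r in alignment]
    score = _column_scores(rows)
    # low-occupancy columns are single-row insertions; runs are found on the
    # occupied columns only, then mapped back to alignment coordinates
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    occ = (arr != ord("-")).sum(axis=0) / len(rows)
    keep = np.nonzero(occ >= 0.5)[0]
    if keep.size == 0:
        return None
    kernel = np.ones(smooth) / smooth
    sm = np.convolve(score[keep], kernel, mode="same")
    above = sm >= threshold
    if not above.any():
        return None
    # longest run of True
    best_run = None
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if best_run is None or j - i > best_run[1] - best_run[0]:
                best_run = (i, j)
            i = j
        else:
            i += 1
    if best_run[1] - best_run[0] < min_block:
        return None  # shorter than any credible element: alignment noise
    c1, c2 = int(keep[best_run[0]]), int(keep[best_run[1] - 1]) + 1
    if not refine:
        return c1, c2

    seqs, maps = _row_maps(rows)
    w = refine_window

    def covered_rows(a, b):
        out = []
        for ri, r in enumerate(rows):
            if r[a] != "-" and r[b - 1] != "-":
                out.append(ri)
        return out

    # A candidate edge pair must show per-copy junction support (a TSD shared
    # by the two flanks, or a Spy-style motif join); among those the combined
    # terminal-inverted-repeat score plus TSD length decides.  The TSD bonus
    # resolves the parse ambiguity of palindromic targets (reading TWA + el +
    # TWA as W + [A el T] + W gains one complementary terminal pair but loses
    # two duplicated bases), while the per-row repeat score rejects conserved
    # target bases absorbed into the element, which break the TIR register.
    # The bonus is capped at 3 because PHIS duplications are at most 3 bp: an
    # element with GG...CC termini in a C|TNA|G site parses equally well as a
    # 5 bp CTNAG duplication around a one-base-trimmed element, and the cap
    # settles that tie in favour of the short duplication.
    # candidate edges step over occupied columns so a shift of k corresponds
    # to k consensus bases even where the alignment is gap-riddled
    ki1 = int(np.searchsorted(keep, c1))
    ki2 = int(np.searchsorted(keep, c2 - 1))
    best_key = None
    best_edges = (c1, c2)
    for dl in range(-w, w + 1):
        i1 = ki1 + dl
        if i1 < 1 or i1 >= len(keep):
            continue
        a = int(keep[i1])
        for dr in range(-w, w + 1):
            i2 = ki2 + dr
            if i2 <= i1 + 10 or i2 >= len(keep) - 1:
                continue
            b = int(keep[i2]) + 1
            rows_ok = covered_rows(a, b)
            if len(rows_ok) < 2:
                continue
            sup, L = _junction_support(seqs, maps, rows_ok, a, b)
            # the junction must be both majority-supported and significant
            # against its chance rate: a 1 bp flank match occurs in a quarter
            # of copies by chance, so short-junction support needs to be
            # near-unanimous before it counts as evidence
            if sup < 0.5:
                continue
            n_ok = len(rows_ok)
            k_ok = int(round(sup * n_ok))
            chance = 0.25**L if L > 0 else 7 * 0.25**6
            if _binom_sf(k_ok - 1, n_ok, chance) > 1e-4:
                continue
            ts = _terminal_ir_score(seqs, maps, rows_ok, a, b)
            # a supported Spy-motif join (L = 0) constrains six flank bases,
            # worth as much as a full-length TSD; ties (an element whose
            # palindromic termini also read as a short TSD) go to the longer
            # element, i.e. the maximal terminal repeat
            bonus = min(L, 3) if L > 0 else 3
            key = (ts + bonus, sup, b - a, -(abs(dl) + abs(dr)), -dl, -dr)
            if best_key is None or key > best_key:
                best_key = key
                best_edges = (a, b)
    if best_key is None:
        return c1, c2
    return best_edges


def build_consensus(alignment, boundaries: tuple[int, int]) -> str:
    """Majority-rule consensus over the element columns.

    Columns with non-gap occupancy below 50% are dropped; ties resolve by the
    fixed base order A < C < G < T.
    """
    c1, c2 = boundaries
    rows = [r.seq[c1:c2] for r in alignment]
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    out = []
    order = [ord(b) for b in "ACGT"]
    for col in arr.T:
        counts = [(int((col == o).sum()), -i) for i, o in enumerate(order)]
        nongap = sum(c for c, _ in counts)
        if nongap / len(rows) < 0.5:
            continue
        cnt, negi = max(counts)
        if cnt == 0:
            continue
        out.append("ACGT"[-negi])
    return "".join(out)
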