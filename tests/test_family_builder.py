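import numpy as np
import pytest

from phiskit.family_builder import (
    ExtendedCopy,
    align_copies,
    build_consensus,
    define_boundaries,
    extend_and_orient,
    recruit_copies,
)
from phiskit.genome_io import GenomeIndex, Interval, SequenceRecord, revcomp
from phiskit.synthetic_data import mutate_copy, random_dna

FLIP = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _flip_safe(seq, p):
    avoid = {seq[p], seq[p - 1], seq[p + 1]}
    return next(b for b in "ACGT" if b not in avoid)


def planted_identity_copy(probe, n_mismatch, island=(92, 108)):
    """Copy of probe with `n_mismatch` isolated substitutions and one clean
    seed island, so exclusion can only come from the identity threshold."""
    c = list(probe)
    pos, p, k = [], 3, 0
    while len(pos) < n_mismatch:
        if not (island[0] <= p < island[1]):
            pos.append(p)
        p += 5 if (k % 4 == 3) else 4
        k += 1
    for q in pos:
        c[q] = _flip_safe(c, q)
    return "".join(c)


@pytest.fixture(scope="module")
def threshold_genome():
    rng = np.random.default_rng(0)
    bg = random_dna(20_000, 0.42, rng)
    probe = random_dna(200, 0.42, rng)
    parts = {
        "at80": planted_identity_copy(probe, 40),
        "at81": planted_identity_copy(probe, 38),
        "len50": probe[50:100],
        "len51": probe[50:101],
    }
    seq = (
        bg[:3000] + parts["at80"] + bg[3000:6000] + parts["at81"]
        + bg[6000:9000] + parts["len50"] + bg[9000:12000] + parts["len51"]
        + bg[12000:15000]
    )
    starts = {"at80": 3000, "at81": 3000 + 200 + 3000}
    return probe, GenomeIndex([SequenceRecord("c", seq)]), starts


def test_exact_planted_copies_all_recruited(rng):
    bg = random_dna(60_000, 0.42, rng)
    probe = random_dna(400, 0.42, rng)
    pieces, pos, off = [], [], 0
    cur = 0
    for site in (5_000, 17_000, 29_000, 41_000, 53_000):
        pieces.append(bg[cur:site])
        pos.append(site + off)
        pieces.append(probe)
        off += len(probe)
        cur = site
    pieces.append(bg[cur:])
    genome = GenomeIndex([SequenceRecord("c", "".join(pieces))])
    hits = recruit_copies(probe, genome)
    assert len(hits) == 5
    assert all(h.identity == 1.0 for h in hits)
    assert sorted(h.interval.start for h in hits) == pos


def test_threshold_semantics_strictly_greater(threshold_genome):
    probe, genome, _ = threshold_genome
    hits = recruit_copies(probe, genome)
    idents = sorted(round(h.identity, 4) for h in hits)
    lengths = sorted(h.aln_length for h in hits)
    # the 80.0%-identity and 50 bp copies are excluded; 81% and 51 bp stay
    assert idents == [0.81, 1.0]
    assert lengths == [51, 200]


def test_probe_shorter_than_word_rejected(rng):
    genome = GenomeIndex([SequenceRecord("c", random_dna(1000, 0.5, rng))])
    with pytest.raises(ValueError):
        recruit_copies("ACGTACGT", genome)


def test_truncated_copies_below_length_cutoff_excluded(rng):
    bg = random_dna(80_000, 0.42, rng)
    probe = random_dna(300, 0.42, rng)
    pieces, cur = [], 0
    n_long, n_short = 0, 0
    sites = range(3_000, 78_000, 3_800)
    for i, site in enumerate(sites):
        pieces.append(bg[cur:site])
        if i % 10 == 0:
            pieces.append(probe[:40])  # truncated to 40 bp: excluded
            n_short += 1
        else:
            pieces.append(mutate_copy(probe, 0.10, np.random.default_rng(i)))
            n_long += 1
        cur = site
    pieces.append(bg[cur:])
    genome = GenomeIndex([SequenceRecord("c", "".join(pieces))])
    hits = recruit_copies(probe, genome)
    assert len(hits) == n_long


def test_extend_and_orient_plus_strand_coordinates(rng):
    seq = random_dna(20_000, 0.42, rng)
    genome = GenomeIndex([SequenceRecord("c", seq)])
    from phiskit.family_builder import CopyHit

    c = CopyHit(Interval("c", 10_000, 12_000, "+"), 1.0, 2000, 0.0)
    (ext,) = extend_and_orient([c], genome, flank=2000)
    assert ext.left_flank == seq[8_000:10_000]
    assert ext.right_flank == seq[12_000:14_000]
    assert ext.oriented_seq == seq[8_000:14_000]


def test_extend_and_orient_minus_strand_swaps_flanks(rng):
    seq = random_dna(20_000, 0.42, rng)
    genome = GenomeIndex([SequenceRecord("c", seq)])
    from phiskit.family_builder import CopyHit

    c = CopyHit(Interval("c", 10_000, 12_000, "-"), 1.0, 2000, 0.0)
    (ext,) = extend_and_orient([c], genome, flank=1500)
    assert ext.left_flank == revcomp(seq[12_000:13_500])
    assert ext.right_flank == revcomp(seq[8_500:10_000])
    assert ext.core_seq == revcomp(seq[10_000:12_000])


def _as_copies(seqs):
    from phiskit.family_builder import CopyHit

    return [
        ExtendedCopy(
            CopyHit(Interval("c", 1 + i, 1 + i + len(s), "+"), 1.0, len(s), 0.0),
            "", "", s, s,
        )
        for i, s in enumerate(seqs)
    ]


def test_align_identical_sequences_gap_free(rng):
    s = random_dna(300, 0.42, rng)
    aln = align_copies(_as_copies([s, s]))
    assert [r.seq for r in aln] == [s, s]


def test_align_renders_deletion_as_gap_block(rng):
    s = random_dna(300, 0.42, rng)
    d = s[:150] + s[160:]
    aln = align_copies(_as_copies([s, d, s]))
    assert aln[1].seq.count("-") == 10
    assert aln[0].seq.replace("-", "") == s


def test_single_copy_alignment_rejected(rng):
    with pytest.raises(ValueError, match="single copy"):
        align_copies(_as_copies([random_dna(100, 0.5, rng)]))


# --- center-star oracle ------------------------------------------------------

MATCH, MIS, GAP = 1, -1, -2


def _nw(a, b):
    n, m = len(a), len(b)
    S = np.zeros((n + 1, m + 1))
    S[:, 0] = np.arange(n + 1) * GAP
    S[0, :] = np.arange(m + 1) * GAP
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = S[i - 1, j - 1] + (MATCH if a[i - 1] == b[j - 1] else MIS)
            S[i, j] = max(d, S[i - 1, j] + GAP, S[i, j - 1] + GAP)
    i, j = n, m
    aa, bb = [], []
    while i or j:
        if i and j and S[i, j] == S[i - 1, j - 1] + (
            MATCH if a[i - 1] == b[j - 1] else MIS
        ):
            aa.append(a[i - 1]); bb.append(b[j - 1]); i -= 1; j -= 1
        elif i and S[i, j] == S[i - 1, j] + GAP:
            aa.append(a[i - 1]); bb.append("-"); i -= 1
        else:
            aa.append("-"); bb.append(b[j - 1]); j -= 1
    return "".join(reversed(aa)), "".join(reversed(bb)), S[n, m]


def _center_star(seqs):
    scores = np.zeros((len(seqs), len(seqs)))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            s = _nw(seqs[i], seqs[j])[2]
            scores[i, j] = scores[j, i] = s
    center = int(np.argmax(scores.sum(axis=1)))
    msa = [seqs[center]]
    order = [center]
    for j in range(len(seqs)):
        if j == center:
            continue
        ac, aj, _ = _nw(msa[0].replace("-", ""), seqs[j])
        # re-project existing gaps ("once a gap, always a gap")
        merged = []
        src = iter(range(len(ac)))
        out_rows = [[] for _ in msa] + [[]]
        ci = 0
        for k in range(len(ac)):
            if ac[k] == "-":
                for r, row in enumerate(msa):
                    out_rows[r].append("-")
                out_rows[-1].append(aj[k])
            else:
                while msa[0][ci] == "-":
                    for r, row in enumerate(msa):
                        out_rows[r].append(row[ci])
                    out_rows[-1].append("-")
                    ci += 1
                for r, row in enumerate(msa):
                    out_rows[r].append(row[ci])
                out_rows[-1].append(aj[k])
                ci += 1
        while ci < len(msa[0]):
            for r, row in enumerate(msa):
                out_rows[r].append(row[ci])
            out_rows[-1].append("-")
            ci += 1
        msa = ["".join(r) for r in out_rows]
        order.append(j)
    return msa


def _sp_score(rows):
    total = 0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            for a, b in zip(rows[i], rows[j]):
                if a == "-" and b == "-":
                    continue
                if a == "-" or b == "-":
                    total += GAP
                else:
                    total += MATCH if a == b else MIS
    return total


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_alignment_sum_of_pairs_beats_center_star(seed):
    rng = np.random.default_rng(seed)
    base = random_dna(300, 0.42, rng)
    seqs = [mutate_copy(base, 0.03, np.random.default_rng(seed * 10 + k)) for k in range(5)]
    aln = align_copies(_as_copies(seqs))
    assert _sp_score([r.seq for r in aln]) >= _sp_score(_center_star(seqs))


# --- boundaries and consensus ------------------------------------------------


def _planted_alignment(rng, n_copies=10, elem_len=400, flank=150, divergence=0.0):
    # element with 12 bp TIRs, as a real cut-and-paste element would carry
    tir = "GG" + random_dna(10, 0.42, rng)
    body = random_dna(elem_len - 24, 0.42, rng)
    elem = tir + "C" + body[1:-1] + "C" + revcomp(tir)
    copies = []
    for k in range(n_copies):
        tsd = "T" + "AT"[int(rng.integers(2))] + "A"
        left = random_dna(flank, 0.42, rng) + tsd
        right = tsd + random_dna(flank, 0.42, rng)
        body = mutate_copy(elem, divergence, np.random.default_rng(500 + k))
        copies.append(left + body + right)
    aln = align_copies(_as_copies(copies))
    return elem, aln, flank + 3


def test_boundaries_exact_on_perfect_copies(rng):
    elem, aln, true_start = _planted_alignment(rng, divergence=0.0)
    bounds = define_boundaries(aln)
    assert bounds is not None
    consensus = build_consensus(aln, bounds)
    assert consensus == elem


def test_boundaries_near_truth_under_divergence():
    ok = 0
    for seed in range(20):
        rng = np.random.default_rng(3000 + seed)
        elem, aln, true_start = _planted_alignment(rng, divergence=0.05)
        bounds = define_boundaries(aln)
        if bounds is None:
            continue
        consensus = build_consensus(aln, bounds)
        if abs(len(consensus) - len(elem)) <= 10:
            ok += 1
    assert ok >= 18  # >= 90% of replicates


def test_unrelated_sequences_give_no_element(rng):
    seqs = [random_dna(400, 0.42, np.random.default_rng(i)) for i in range(6)]
    aln = align_copies(_as_copies(seqs))
    assert define_boundaries(aln) is None


def test_consensus_majority_and_ties():
    rows = [
        SequenceRecord("r0", "AACT"),
        SequenceRecord("r1", "AAGT"),
        SequenceRecord("r2", "AALT".replace("L", "C")),
        SequenceRecord("r3", "GACT"),
    ]
    assert build_consensus(rows, (0, 4)) == "AACT"
    # 2:2 tie resolves by base order A < C < G < T
    tie = [SequenceRecord(f"r{i}", s) for i, s in enumerate(["A", "A", "G", "G"])]
    assert build_consensus(tie, (0, 1)) == "A"


def test_consensus_drops_low_occupancy_columns():
    rows = [
        SequenceRecord("r0", "A-CT"),
        SequenceRecord("r1", "A-CT"),
        SequenceRecord("r2", "AGCT"),
    ]
    assert build_consensus(rows, (0, 4)) == "ACT"


def test_consensus_close_to_truth_at_five_percent_divergence(rng):
    elem, aln, _ = _planted_alignment(rng, n_copies=20, divergence=0.05)
    bounds = define_boundaries(aln)
    consensus = build_consensus(aln, bounds)
    import edlib

    d = edlib.align(consensus, elem, mode="NW")["editDistance"]
    assert d / len(elem) < 0.01
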