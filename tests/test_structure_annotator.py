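import numpy as np
import pytest

from phiskit._motifs import GROUPS
from phiskit.family_builder import CopyHit, ExtendedCopy, extend_and_orient
from phiskit.genome_io import Interval, revcomp
from phiskit.structure_annotator import test_spy_motif as spy_motif_fraction
from phiskit.structure_annotator import (
    TSDModel,
    detect_tirs,
    find_paralogous_empty_sites,
    infer_tsd,
    is_full_length,
    logo_matrix,
    reconstruct_empty_site,
)
from phiskit.synthetic_data import (
    FamilySpec,
    SimulationConfig,
    make_element,
    random_dna,
    simulate,
)


def _copy(left, core, right):
    return ExtendedCopy(
        CopyHit(Interval("c", 1000, 1000 + len(core), "+"), 1.0, len(core), 0.0),
        left, right, left + core + right, core,
    )


# --- TIR detection -----------------------------------------------------------


def test_constructed_exact_tir(rng):
    tir = "GGGCCTATAGGCCC"[:14]
    body = random_dna(500, 0.42, rng)
    elem = tir + "C" + body + "C" + revcomp(tir)
    m = detect_tirs(elem)
    assert m is not None
    assert m.length == 14 and m.mismatches == 0
    assert m.tir5 == tir and m.tir3 == revcomp(tir)


def test_tir_null_on_random_sequence():
    n_none = sum(
        detect_tirs(random_dna(2000, 0.42, np.random.default_rng(4000 + s)), min_len=10)
        is None
        for s in range(50)
    )
    assert n_none >= 48


def test_planted_nuwai_tir_first_bases_ggg(rng):
    elem, _ = make_element("NuwaI", 2500, 24, rng)
    m = detect_tirs(elem)
    assert m.length == 24
    assert m.first_bases == "GGG"


def test_tir_strand_symmetry(rng):
    elem, _ = make_element("Pangu", 2500, 20, rng)
    m = detect_tirs(elem)
    m_rc = detect_tirs(revcomp(elem))
    assert m_rc.length == m.length
    assert m_rc.tir5 == revcomp(m.tir3) and m_rc.tir3 == revcomp(m.tir5)


def test_tir_rejects_too_short_element():
    with pytest.raises(ValueError):
        detect_tirs("ACGTACGT", min_len=5)


# --- full-length calls -------------------------------------------------------


def test_full_length_and_truncation(rng):
    elem, _ = make_element("Pangu", 2500, 20, rng)
    tir = detect_tirs(elem)
    flank = random_dna(50, 0.42, rng)
    assert is_full_length(_copy(flank, elem, flank), tir)
    assert not is_full_length(_copy(flank, elem[30:], flank), tir)
    assert not is_full_length(_copy(flank, elem[:-30], flank), tir)


def test_full_length_counts_match_planted_truth(small_sim):
    genome = small_sim.genome
    for fam in small_sim.truth.families:
        tir = detect_tirs(fam.element)
        ins = [t for t in small_sim.truth.insertions if t.family == fam.name]
        hits = [CopyHit(t.interval, 1.0, len(t.interval), 0.0) for t in ins]
        ext = extend_and_orient(hits, genome, flank=50)
        called = [is_full_length(c, tir) for c in ext]
        truth = [t.full_length for t in ins]
        assert called == truth


# --- TSD inference -----------------------------------------------------------


def test_tsd_twa_consensus(rng):
    copies = []
    for tsd in ("TTA", "TAA", "TTA", "TAA", "TTA"):
        left = random_dna(30, 0.42, rng) + tsd
        right = tsd + random_dna(30, 0.42, rng)
        copies.append(_copy(left, "X" * 10, right))
    m = infer_tsd(copies)
    assert m.length == 3 and m.consensus == "TWA"
    assert m.support == 1.0
    assert m.outer5 is None and m.outer3 is None


def test_tsd_absent_for_random_flanks(rng):
    copies = [
        _copy(random_dna(30, 0.42, rng), "X" * 10, random_dna(30, 0.42, rng))
        for _ in range(10)
    ]
    m = infer_tsd(copies)
    assert m.length == 0 and m.consensus == ""


def test_tsd_isl2eu_outer_bases(rng):
    copies = []
    for _ in range(6):
        left = random_dna(30, 0.42, rng) + "AAT"
        right = "ATT" + random_dna(30, 0.42, rng)
        copies.append(_copy(left, "X" * 10, right))
    m = infer_tsd(copies)
    assert (m.length, m.consensus) == (2, "AT")
    assert (m.outer5, m.outer3) == ("A", "T")
    assert m.alternative_length == 4


def test_tsd_requires_three_copies(rng):
    with pytest.raises(ValueError, match="insufficient"):
        infer_tsd([_copy("AAATTA", "X", "TTAAAA")] * 2)


# --- Spy motif ---------------------------------------------------------------


def test_spy_motif_central_split(rng):
    copies = [
        _copy(random_dna(20, 0.42, rng) + "AAA", "X" * 10, "TTT" + random_dna(20, 0.42, rng))
        for _ in range(5)
    ]
    assert spy_motif_fraction(copies) == 1.0


def test_spy_motif_boundary_split(rng):
    # insertion directly after the complete motif (split k = 6)
    copies = [
        _copy(random_dna(20, 0.42, rng) + "AAATTT", "X" * 10, random_dna(20, 0.42, rng))
        for _ in range(5)
    ]
    assert spy_motif_fraction(copies) == 1.0


def test_spy_motif_null(rng):
    copies = [
        _copy(random_dna(20, 0.42, rng), "X" * 10, random_dna(20, 0.42, rng))
        for _ in range(20)
    ]
    assert spy_motif_fraction(copies) <= 0.2


# --- empty-site reconstruction ----------------------------------------------


def test_reconstruct_inverts_insertion(rng):
    x, y = random_dna(40, 0.42, rng), random_dna(40, 0.42, rng)
    site = x + "TTA" + y  # pre-insertion locus
    left = x + "TTA"
    right = "TTA" + y
    rec = reconstruct_empty_site(_copy(left, "E" * 20, right), TSDModel(3, "TWA", 1.0), 30)
    assert rec == site[13:73]  # one copy of the target retained, exactly


def test_reconstruct_isl2eu_restores_aatt(rng):
    x, y = random_dna(30, 0.42, rng), random_dna(30, 0.42, rng)
    left = x + "AAT"
    right = "ATT" + y
    rec = reconstruct_empty_site(_copy(left, "E" * 20, right), TSDModel(2, "AT", 1.0), 30)
    assert rec == (x + "AATT" + y)[3 : 3 + 60]
    assert "AATT" in rec


def test_reconstruct_round_trip_all_mechanics(clean_sim):
    """Removing the element and one TSD copy restores the background."""
    f = 30
    for ins in clean_sim.truth.insertions:
        hit = CopyHit(ins.interval, 1.0, len(ins.interval), 0.0)
        (ext,) = extend_and_orient([hit], clean_sim.genome, flank=60)
        L = GROUPS[ins.group].tsd_len
        rec = reconstruct_empty_site(ext, TSDModel(L, "", 1.0), flank_used=f)
        cut = ins.bg_cut
        if ins.strand == "+":
            expect = clean_sim.background[cut - f : cut + f]
        else:
            expect = revcomp(clean_sim.background[cut - f - L : cut + f - L])
        assert rec == expect


def test_reconstruct_rejects_short_flanks(rng):
    with pytest.raises(ValueError):
        reconstruct_empty_site(_copy("AAA", "E" * 10, "TTT"), TSDModel(0, "", 1.0), 30)


# --- paralogous empty sites --------------------------------------------------


@pytest.fixture(scope="module")
def dup_sim():
    cfg = SimulationConfig(
        genome_length=300_000,
        seed=9,
        segmental_duplication=(400, 1),
        families=[FamilySpec(group="Pangu", n_copies=6, divergence=0.0, truncated_fraction=0.0)],
    )
    return simulate(cfg)


def _family_copies(sim):
    return [
        extend_and_orient(
            [CopyHit(i.interval, 1.0, len(i.interval), 0.0)], sim.genome, flank=60
        )[0]
        for i in sim.truth.insertions
    ]


def test_unoccupied_duplicate_found(dup_sim):
    src, dst, dlen = dup_sim.truth.duplications[0]
    ins = next(i for i in dup_sim.truth.insertions if src <= i.bg_cut < src + dlen)
    (ext,) = extend_and_orient(
        [CopyHit(ins.interval, 1.0, len(ins.interval), 0.0)], dup_sim.genome, flank=60
    )
    rec = reconstruct_empty_site(ext, TSDModel(3, "ANT", 1.0), 30)
    matches = find_paralogous_empty_sites(rec, dup_sim.genome, _family_copies(dup_sim))
    assert len(matches) >= 1
    expected = dup_sim.truth.bg_to_final(dst + (ins.bg_cut - src))
    assert any(
        m.interval.start <= expected <= m.interval.end and m.identity >= 0.85
        for m in matches
    )


def test_unique_junction_yields_no_matches(dup_sim):
    ins = next(
        i
        for i in dup_sim.truth.insertions
        if not any(s <= i.bg_cut < s + l for s, d, l in dup_sim.truth.duplications)
    )
    (ext,) = extend_and_orient(
        [CopyHit(ins.interval, 1.0, len(ins.interval), 0.0)], dup_sim.genome, flank=60
    )
    rec = reconstruct_empty_site(ext, TSDModel(3, "ANT", 1.0), 30)
    assert find_paralogous_empty_sites(rec, dup_sim.genome, _family_copies(dup_sim)) == []


def test_matches_overlapping_family_copies_excluded(dup_sim):
    # searching with a probe equal to a copy's own junction but without the
    # exclusion list would match the occupied locus; with it, never
    src, dst, dlen = dup_sim.truth.duplications[0]
    ins = next(i for i in dup_sim.truth.insertions if src <= i.bg_cut < src + dlen)
    (ext,) = extend_and_orient(
        [CopyHit(ins.interval, 1.0, len(ins.interval), 0.0)], dup_sim.genome, flank=60
    )
    rec = reconstruct_empty_site(ext, TSDModel(3, "ANT", 1.0), 30)
    matches = find_paralogous_empty_sites(rec, dup_sim.genome, _family_copies(dup_sim))
    for m in matches:
        for i in dup_sim.truth.insertions:
            assert not m.interval.overlaps(i.interval)


# --- logos -------------------------------------------------------------------


def test_logo_closed_forms():
    m = logo_matrix(["AA", "AC", "AG", "AT"])
    assert m.info_bits[0] == pytest.approx(2.0)
    assert m.info_bits[1] == pytest.approx(0.0)
    m2 = logo_matrix(["A", "T"])
    assert m2.info_bits[0] == pytest.approx(1.0)


def test_logo_frequencies_sum_to_one_and_bounded(rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(30)]
    m = logo_matrix(seqs)
    for freq, bits in zip(m.positions, m.info_bits):
        assert sum(freq.values()) == pytest.approx(1.0)
        assert -1e-12 <= bits <= 2.0


def test_logo_invariant_under_row_permutation(rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(10)]
    m1 = logo_matrix(seqs)
    m2 = logo_matrix(list(reversed(seqs)))
    assert m1.info_bits == m2.info_bits


def test_logo_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        logo_matrix(["AAA", "AA"])
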