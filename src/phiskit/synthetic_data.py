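"""Synthetic genomes with planted PHIS elements and full ground truth.

The generator emulates the study conditions the pipeline is aimed at: a
background genome carrying multi-copy element families, one insertion
mechanics per group --

* PIF/Harbinger  ...TWA...   -> TWA + element + TWA   (3 bp TSD)
* ISL2EU         ...AATT...  -> A AT + element + AT T (2 bp TSD, outer A/T)
* Spy            ...AAATTT...-> AAA + element + TTT   (no TSD)
* Pangu          ...ANT...   -> ANT + element + ANT   (3 bp TSD)
* NuwaI          ...CWG...   -> CWG + element + CWG   (3 bp TSD)
* NuwaII         ...CTNAG... -> C TNA + element + TNA G (3 bp TSD, outer C/G)

-- with per-copy divergence, optional terminal truncation, random strand, and
TIR first-base biases per group.  Elements carry real ORFs emitted from the
package's domain profiles, so the ORF/domain annotator is testable end to end.
Insertions never nest; ground truth records every planted copy.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

from . import _motifs
from ._motifs import GROUPS, GROUP_NAMES, OrfLayout, group_domain
from .genome_io import _CODONS, GenomeIndex, Interval, SequenceRecord, revcomp

__all__ = [
    "FamilySpec",
    "SimulationConfig",
    "OrfTruth",
    "FamilyTruth",
    "InsertionTruth",
    "GroundTruth",
    "SimulationResult",
    "slug",
    "random_dna",
    "build_protein",
    "back_translate",
    "make_element",
    "mutate_copy",
    "insert_element",
    "simulate",
    "reference_transposases",
    "write_truth",
]

_NT = np.array(list("ACGT"))

# inverse codon table (stops excluded; used for back-translation)
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODONS.items()):
    if _aa != "*":
        _AA_TO_CODONS.setdefault(_aa, []).append(_codon)


def slug(group: str) -> str:
    return group.replace("/", "_")


def random_dna(n: int, gc_content: float, rng: np.random.Generator) -> str:
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    return "".join(rng.choice(_NT, size=n, p=[p_at, p_gc, p_gc, p_at]))


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous codon per residue (no stop appended)."""
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))] for aa in protein
    )


def back_translate_biased(protein: str, codon_shift: int) -> str:
    """Synonymous codon chosen by a fixed per-lineage rotation.

    Giving each group its own codon-usage bias guarantees that wobble
    positions differ between groups wherever the rotation does not wrap, so
    homologous domains of different groups stay well below the within-family
    nucleotide-identity threshold.
    """
    return "".join(
        _AA_TO_CODONS[aa][codon_shift % len(_AA_TO_CODONS[aa])] for aa in protein
    )


def build_protein(layout: OrfLayout, group: str, rng: np.random.Generator) -> str:
    """Met + padded group-variant domains, to the layout's fixed length."""
    domains = [group_domain(d, group) for d in layout.domains]
    pad_total = layout.aa_length - 1 - sum(len(d) for d in domains)
    if pad_total < 0:
        raise ValueError("ORF length too short for its domains")
    n_pads = len(domains) + 1
    base, extra = divmod(pad_total, n_pads)
    pad_lens = [base + (1 if i < extra else 0) for i in range(n_pads)]
    parts = ["M"]
    for i, plen in enumerate(pad_lens):
        parts.append("".join(rng.choice(list(_motifs.AA20), size=plen)))
        if i < len(domains):
            parts.append(domains[i])
    return "".join(parts)


def _canonical_rng(group: str, orf_index: int) -> np.random.Generator:
    gi = GROUP_NAMES.index(group)
    return np.random.default_rng(50_021 + 101 * gi + 17 * orf_index)


def canonical_proteins(group: str) -> list[str]:
    """The group's reference ORF proteins (fixed, independent of run seed)."""
    gdef = GROUPS[group]
    return [
        build_protein(layout, group, _canonical_rng(group, i))
        for i, layout in enumerate(gdef.orfs)
    ]


def reference_transposases():
    """Reference transposase queries, one per group (the fixture query set)."""
    from .homology_search import ProteinQuery

    out = []
    for group in GROUP_NAMES:
        prot = canonical_proteins(group)[0]
        out.append(ProteinQuery(f"{slug(group)}_tpase", prot, source_group=group))
    return out


@dataclass
class OrfTruth:
    start: int  # on the element, 0-based half-open
    end: int
    strand: str
    domains: tuple[str, ...]
    protein: str


@dataclass
class FamilyTruth:
    name: str
    group: str
    element: str
    tir_len: int
    orfs: list[OrfTruth]
    active: bool


def make_element(
    group: str,
    element_len: int,
    tir_len: int,
    rng: np.random.Generator,
    active: bool = True,
) -> tuple[str, list[OrfTruth]]:
    """One family's element: TIR5 + spacer + ORF(s) + spacer + revcomp(TIR5).

    The base just inside each TIR is fixed to 'C' on both sides so the planted
    TIR cannot be extended by a chance complementary pair; ORF coding sequence
    is a per-family random back-translation of the group's canonical proteins.
    """
    gdef = GROUPS[group]
    if tir_len <= 0:
        raise ValueError("all PHIS groups carry TIRs; tir_len must be positive")
    lo, hi = gdef.tir_range
    if not (lo <= tir_len <= hi):
        raise ValueError(f"{group} TIR length must be in [{lo},{hi}], got {tir_len}")
    prefix = gdef.tir_prefixes[rng.integers(len(gdef.tir_prefixes))]
    tir5 = prefix + "".join(rng.choice(_NT, size=tir_len - len(prefix)))

    proteins = canonical_proteins(group)
    gi = GROUP_NAMES.index(group)
    orf_nts = []
    for prot in proteins:
        orf_nts.append(back_translate_biased(prot, gi) + "TAA")
    min_spacer = 15
    coding = sum(len(s) for s in orf_nts)
    n_spacers = len(orf_nts) + 1
    budget = element_len - 2 * tir_len - coding
    if budget < n_spacers * min_spacer:
        raise ValueError(
            f"element_len {element_len} too short for {group} layout "
            f"(needs >= {2 * tir_len + coding + n_spacers * min_spacer})"
        )
    base, extra = divmod(budget, n_spacers)
    spacer_lens = [base + (1 if i < extra else 0) for i in range(n_spacers)]
    spacers = ["".join(rng.choice(_NT, size=n)) for n in spacer_lens]
    # pin four bases adjacent to each TIR so the inverted repeat stops
    # exactly: C opposite C can never pair, and a 4-mismatch wall keeps a
    # chance complementary run beyond it from outscoring the true repeat
    spacers[0] = "CCCC" + spacers[0][4:]
    spacers[-1] = spacers[-1][:-4] + "CCCC"

    parts = [tir5]
    orfs: list[OrfTruth] = []
    pos = tir_len
    for i, orf_nt in enumerate(orf_nts):
        parts.append(spacers[i])
        pos += spacer_lens[i]
        orfs.append(
            OrfTruth(pos, pos + len(orf_nt), "+", GROUPS[group].orfs[i].domains, proteins[i])
        )
        parts.append(orf_nt)
        pos += len(orf_nt)
    parts.append(spacers[-1])
    parts.append(revcomp(tir5))
    element = "".join(parts)
    assert len(element) == element_len

    if not active:
        # disrupt the last ORF with a premature stop near its middle
        tgt = orfs[-1]
        mid_codon = (tgt.end - tgt.start) // 6  # codon index ~ middle
        p = tgt.start + 3 * mid_codon
        element = element[:p] + "TAA" + element[p + 3 :]
    return element, orfs


def mutate_copy(
    seq: str,
    divergence: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
) -> str:
    """i.i.d. substitutions at the given per-site rate; optional rare indels."""
    if not 0.0 <= divergence <= 0.2:
        raise ValueError("divergence must be in [0, 0.2]")
    if divergence == 0 and indel_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    vals = code[arr]
    ok = vals >= 0
    hit = (rng.random(len(arr)) < divergence) & ok
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        vals[hit] = (vals[hit] + shift) % 4
        arr[hit] = np.frombuffer("ACGT".encode(), dtype=np.uint8)[vals[hit]]
    out = arr.tobytes().decode()
    if indel_rate > 0:
        chars = list(out)
        pos = np.nonzero(rng.random(len(chars)) < indel_rate)[0]
        for p in reversed(pos):
            if rng.random() < 0.5:
                del chars[p]
            else:
                chars.insert(p, str(rng.choice(_NT)))
        out = "".join(chars)
    return out


def _instantiate_motif(regex: str, rng: np.random.Generator) -> str:
    """A concrete DNA string matching one of the group target regexes."""
    out = []
    i = 0
    while i < len(regex):
        if regex[i] == "[":
            j = regex.index("]", i)
            choices = regex[i + 1 : j]
            out.append(choices[rng.integers(len(choices))])
            i = j + 1
        else:
            out.append(regex[i])
            i += 1
    return "".join(out)


@dataclass
class InsertionTruth:
    family: str
    group: str
    interval: Interval  # element span in the final genome (TSDs excluded)
    strand: str
    tsd: str
    full_length: bool
    bg_cut: int  # background coordinate of the staggered cut


@dataclass
class GroundTruth:
    insertions: list[InsertionTruth]
    families: list[FamilyTruth]
    duplications: list[tuple[int, int, int]] = field(default_factory=list)
    # (src_start, dst_start, length) in background coordinates
    _cuts: list[tuple[int, int]] = field(default_factory=list)  # (bg_cut, chunk_len)

    def bg_to_final(self, pos: int) -> int:
        """Map a background coordinate to the post-insertion genome."""
        off = 0
        for cut, ln in self._cuts:
            if cut <= pos:
                off += ln
        return pos + off


@dataclass
class SimulationResult:
    genome: GenomeIndex
    background: str
    truth: GroundTruth
    config: "SimulationConfig"


@dataclass
class FamilySpec:
    group: str
    n_copies: int = 20
    tir_len: int | None = None
    element_len: int = 2500
    divergence: float = 0.01
    truncated_fraction: float = 0.2
    active: bool = True
    name: str | None = None


@dataclass
class SimulationConfig:
    genome_length: int = 1_000_000
    gc_content: float = 0.42
    families: list[FamilySpec] | None = None
    seed: int = 42
    segmental_duplication: tuple[int, int] | None = None  # (length, count)
    min_separation: int = 500
    edge_margin: int = 3000
    indel_rate: float = 0.0
    flank_divergence: float = 0.0
    chrom_name: str = "chr1"

    def resolved_families(self) -> list[FamilySpec]:
        fams = self.families
        if fams is None:
            fams = [FamilySpec(group=g) for g in GROUP_NAMES]
        out = []
        counters: dict[str, int] = {}
        for fs in fams:
            if fs.group not in GROUPS:
                raise ValueError(f"unknown group {fs.group!r}")
            tir = fs.tir_len if fs.tir_len is not None else GROUPS[fs.group].tir_default
            counters[fs.group] = counters.get(fs.group, 0) + 1
            name = fs.name or f"{slug(fs.group)}-{counters[fs.group]}"
            out.append(
                FamilySpec(fs.group, fs.n_copies, tir, fs.element_len,
                           fs.divergence, fs.truncated_fraction, fs.active, name)
            )
        return out


def insert_element(
    genome: str, element: str, group: str, rng: np.random.Generator,
    site: int | None = None, strand: str = "+",
) -> tuple[str, InsertionTruth]:
    """Insert one element at a (seeded) uniformly chosen target occurrence."""
    gdef = GROUPS[group]
    if site is None:
        occ = [m.start() for m in re.finditer(gdef.target_regex, genome)]
        if not occ:
            raise ValueError(f"no target site for {group} ({gdef.target_regex})")
        site = occ[rng.integers(len(occ))]
    cut = site + gdef.cut_offset
    dup = genome[cut - gdef.tsd_len : cut] if gdef.tsd_len else ""
    oriented = element if strand == "+" else revcomp(element)
    new = genome[:cut] + oriented + dup + genome[cut:]
    truth = InsertionTruth(
        family="", group=group,
        interval=Interval("chr1", cut, cut + len(element), strand),
        strand=strand, tsd=dup, full_length=True, bg_cut=cut,
    )
    return new, truth


def _select_sites(
    background: str,
    fam_specs: list[FamilySpec],
    rng: np.random.Generator,
    min_sep: int,
    margin: int,
    forced: dict[int, list[int]],
) -> tuple[str, list[list[int]]]:
    """Pick per-family target-motif occurrences, seeding motifs if scarce."""
    bg = background
    n = len(bg)
    # seeding pass: guarantee enough occurrences per group
    for fi, fs in enumerate(fam_specs):
        gdef = GROUPS[fs.group]
        occ = [m.start() for m in re.finditer(gdef.target_regex, bg)]
        need = 4 * fs.n_copies
        guard = 0
        while len(occ) < need and guard < 10 * need:
            guard += 1
            p = int(rng.integers(margin, n - margin))
            motif = _instantiate_motif(gdef.target_regex, rng)
            bg = bg[:p] + motif + bg[p + len(motif) :]
            occ = [m.start() for m in re.finditer(gdef.target_regex, bg)]
    chosen: list[int] = []

    def far_enough(p):
        return all(abs(p - c) >= min_sep for c in chosen)

    selections: list[list[int]] = []
    for fi, fs in enumerate(fam_specs):
        gdef = GROUPS[fs.group]
        occ = [
            m.start()
            for m in re.finditer(gdef.target_regex, bg)
            if margin <= m.start() < n - margin
        ]
        rng.shuffle(occ)
        for p in forced.get(fi, []):
            occ.insert(0, p)
        picked = []
        for p in occ:
            if len(picked) == fs.n_copies:
                break
            if far_enough(p):
                picked.append(p)
                chosen.append(p)
        if len(picked) < fs.n_copies:
            raise ValueError(
                f"cannot place {fs.n_copies} copies of {fs.name}: genome too "
                "short for the requested families; increase genome_length"
            )
        selections.append(picked)
    return bg, selections


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate (genome, ground truth) under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    fam_specs = config.resolved_families()
    bg = random_dna(config.genome_length, config.gc_content, rng)

    duplications: list[tuple[int, int, int]] = []
    forced: dict[int, list[int]] = {}
    if config.segmental_duplication is not None:
        dlen, dcount = config.segmental_duplication
        gdef0 = GROUPS[fam_specs[0].group]
        for _ in range(dcount):
            src = int(rng.integers(config.edge_margin, config.genome_length - 2 * config.edge_margin - 2 * dlen))
            motif = _instantiate_motif(gdef0.target_regex, rng)
            mid = src + dlen // 2
            bg = bg[:mid] + motif + bg[mid + len(motif) :]
            block = bg[src : src + dlen]
            dst = src + dlen + int(rng.integers(config.min_separation, config.edge_margin))
            bg = bg[:dst] + block + bg[dst + dlen :]
            duplications.append((src, dst, dlen))
            forced.setdefault(0, []).append(mid)

    bg, selections = _select_sites(
        bg, fam_specs, rng, config.min_separation, config.edge_margin, forced
    )
    if config.flank_divergence > 0:
        bg = mutate_copy(bg, config.flank_divergence, rng)

    families: list[FamilyTruth] = []
    pending = []  # (cut, chunk, element_len_inserted, truth fields...)
    for fi, fs in enumerate(fam_specs):
        element, orfs = make_element(fs.group, fs.element_len, fs.tir_len, rng, fs.active)
        families.append(FamilyTruth(fs.name, fs.group, element, fs.tir_len, orfs, fs.active))
        gdef = GROUPS[fs.group]
        n_trunc = int(np.floor(fs.truncated_fraction * fs.n_copies))
        trunc_idx = set(
            int(i) for i in rng.choice(fs.n_copies, size=n_trunc, replace=False)
        ) if n_trunc else set()
        for ci, site in enumerate(selections[fi]):
            inst = mutate_copy(element, fs.divergence, rng, config.indel_rate)
            full = ci not in trunc_idx
            if not full:
                frac = rng.uniform(0.2, 0.5)
                k = max(60, int(len(inst) * (1 - frac)))
                inst = inst[-k:] if rng.random() < 0.5 else inst[:k]
            strand = "+" if rng.random() < 0.5 else "-"
            cut = site + gdef.cut_offset
            dup = bg[cut - gdef.tsd_len : cut] if gdef.tsd_len else ""
            oriented = inst if strand == "+" else revcomp(inst)
            chunk = oriented + dup
            pending.append((cut, chunk, len(inst), fs.name, fs.group, strand, dup, full))

    pending.sort(key=lambda t: t[0])
    pieces = []
    insertions: list[InsertionTruth] = []
    cuts: list[tuple[int, int]] = []
    prev = 0
    offset = 0
    for cut, chunk, elen, name, group, strand, dup, full in pending:
        pieces.append(bg[prev:cut])
        pieces.append(chunk)
        start = cut + offset
        insertions.append(
            InsertionTruth(
                name, group,
                Interval(config.chrom_name, start, start + elen, strand),
                strand, dup, full, cut,
            )
        )
        cuts.append((cut, len(chunk)))
        offset += len(chunk)
        prev = cut
    pieces.append(bg[prev:])
    genome_seq = "".join(pieces)

    genome = GenomeIndex([SequenceRecord(config.chrom_name, genome_seq)])
    truth = GroundTruth(insertions, families, duplications, cuts)
    return SimulationResult(genome, bg, truth, config)


def write_truth(result: SimulationResult, bed_path, json_path) -> None:
    from .genome_io import write_bed

    write_bed(
        [(ins.interval, f"{ins.family}", 0.0) for ins in result.truth.insertions],
        bed_path,
    )
    payload = {
        "families": [
            {
                "name": f.name, "group": f.group, "tir_len": f.tir_len,
                "active": f.active, "element": f.element,
                "orfs": [
                    {"start": o.start, "end": o.end, "strand": o.strand,
                     "domains": list(o.domains)}
                    for o in f.orfs
                ],
            }
            for f in result.truth.families
        ],
        "insertions": [
            {
                "family": i.family, "group": i.group,
                "seq_id": i.interval.seq_id, "start": i.interval.start,
                "end": i.interval.end, "strand": i.strand, "tsd": i.tsd,
                "full_length": i.full_length, "bg_cut": i.bg_cut,
            }
            for i in result.truth.insertions
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)
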