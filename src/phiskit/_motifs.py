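"""Group definitions shared across the package.

Each of the six PHIS groups is described by its target-site mechanics (the
motif the transposase cuts, how much of it is duplicated), its TIR length
range and first-base bias, and its ORF/domain layout.  The diagnostic protein
domains (DDE transposase core, helix-turn-helix, Myb/SANT, THAP, YqaJ) are
represented by short consensus motifs from which both the shipped PSSM
profiles and the simulator's synthetic transposases are built.  Per-group
domain variants (conservative substitutions away from the profile consensus,
catalytic triad untouched) keep the groups' coding sequences divergent at the
nucleotide level, mirroring the fact that the groups are distinct transposase
lineages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"

PIF = "PIF/Harbinger"
ISL2EU = "ISL2EU"
SPY = "Spy"
PANGU = "Pangu"
NUWA1 = "NuwaI"
NUWA2 = "NuwaII"

GROUP_NAMES = [PIF, ISL2EU, SPY, PANGU, NUWA1, NUWA2]

# --- domain consensus motifs (synthetic, hand-built fixtures) --------------

DDE_CONSENSUS = "GKEV" + "D" + "LIVGSHTGWKPNQVARAMG" + "D" + "SRQTVYNWIKRFNT" + "E" + "GGLKA"
DDE_TRIAD = (4, 24, 39)  # columns of the catalytic D..D..E
assert [DDE_CONSENSUS[i] for i in DDE_TRIAD] == ["D", "D", "E"]

HTH_CONSENSUS = "LSQREIARILGISQSTVSRVLK"
MYB_CONSENSUS = "WTKEERLLLIQLVKQYGPKNWSLIARHLPG"
THAP_CONSENSUS = "MPKSCAAVNCSNRQSKGFKLHRFPKNPKRRKIWLQ"
YQAJ_CONSENSUS = "GGSEASRIGASPNGLVGASGLLNIKCPYSAREMGL"

DOMAIN_CONSENSUS = {
    "DDE": DDE_CONSENSUS,
    "HTH": HTH_CONSENSUS,
    "Myb/SANT": MYB_CONSENSUS,
    "THAP": THAP_CONSENSUS,
    "YqaJ": YQAJ_CONSENSUS,
}

_BLOSUM = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    return float(_BLOSUM[a, b])


def _ranked_partners(aa: str) -> list[str]:
    """Substitutions for `aa`, best BLOSUM62 score first (self excluded)."""
    others = [o for o in AA20 if o != aa]
    others.sort(key=lambda o: (-blosum62(aa, o), o))
    return others


def group_domain(domain: str, group: str, frac: float = 0.30) -> str:
    """Deterministic per-group variant of a domain consensus.

    ~`frac` of positions are replaced by a conservative BLOSUM62 partner; for
    the DDE domain the catalytic triad columns are never touched.  Each group
    substitutes with a different-ranked partner, so two groups never converge
    on the same residue even when they mutate the same position — this keeps
    the groups' coding sequences below the within-family nucleotide-identity
    threshold, as separate transposase lineages should be.  The variant is a
    pure function of (domain, group).
    """
    cons = DOMAIN_CONSENSUS[domain]
    gi = GROUP_NAMES.index(group)
    rng = np.random.default_rng(100_003 + 61 * gi + 7 * list(DOMAIN_CONSENSUS).index(domain))
    protected = set(DDE_TRIAD) if domain == "DDE" else set()
    out = list(cons)
    candidates = [i for i in range(len(cons)) if i not in protected]
    n_mut = int(round(frac * len(candidates)))
    for i in rng.choice(len(candidates), size=n_mut, replace=False):
        pos = candidates[int(i)]
        partners = _ranked_partners(cons[pos])
        out[pos] = partners[gi % 6]
    return "".join(out)


# --- group signatures -------------------------------------------------------


@dataclass(frozen=True)
class OrfLayout:
    """Domains expected in one ORF; empty tuple means no known domain."""

    domains: tuple[str, ...]
    aa_length: int  # synthetic protein length used by the simulator


@dataclass(frozen=True)
class GroupDef:
    name: str
    # target-site mechanics: regex of the cut motif, cut offset within the
    # motif, and length of the duplicated block ending at the cut
    target_regex: str
    cut_offset: int
    tsd_len: int
    # TSD classification pattern (IUPAC) and required conserved outer bases
    tsd_pattern: str
    outer5: str | None
    outer3: str | None
    spy_motif: str | None
    # TIR geometry
    tir_range: tuple[int, int]
    tir_default: int
    tir_prefixes: tuple[str, ...]
    orfs: tuple[OrfLayout, ...]


GROUPS: dict[str, GroupDef] = {
    PIF: GroupDef(
        PIF, "T[AT]A", 3, 3, "TWA", None, None, None,
        (5, 60), 14, ("A", "G"),
        (OrfLayout(("HTH", "DDE"), 230), OrfLayout(("Myb/SANT",), 150)),
    ),
    ISL2EU: GroupDef(
        ISL2EU, "AATT", 3, 2, "AT", "A", "T", None,
        (6, 259), 16, ("GG",),
        (OrfLayout(("THAP", "HTH", "DDE"), 260), OrfLayout(("YqaJ",), 150)),
    ),
    SPY: GroupDef(
        SPY, "AAATTT", 3, 0, "", None, None, "AAATTT",
        (5, 100), 15, ("G",),
        (OrfLayout(("DDE",), 250),),
    ),
    PANGU: GroupDef(
        PANGU, "A[ACGT]T", 3, 3, "ANT", None, None, None,
        (11, 40), 20, ("AG", "GG"),
        (OrfLayout(("DDE",), 230), OrfLayout((), 130)),
    ),
    NUWA1: GroupDef(
        NUWA1, "C[AT]G", 3, 3, "CWG", None, None, None,
        (12, 61), 24, ("GGG",),
        (OrfLayout(("DDE",), 230), OrfLayout(("Myb/SANT",), 150)),
    ),
    NUWA2: GroupDef(
        NUWA2, "CT[ACGT]AG", 4, 3, "TNA", "C", "G", None,
        (13, 46), 18, ("GG",),
        (OrfLayout(("DDE",), 230), OrfLayout(("Myb/SANT",), 150)),
    ),
}


IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

IUPAC_INV = {v: k for k, v in IUPAC.items()}


def iupac_for(bases: frozenset) -> str:
    return IUPAC_INV[frozenset(bases)]
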