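"""ORF discovery on family consensus sequences and diagnostic domain calls.

ORFs are Met-to-stop over all six frames, at least 100 codons by default;
overlapping same-frame ORFs reduce to the longest.  Domains (DDE transposase
core, helix-turn-helix, Myb/SANT, THAP, YqaJ exonuclease) are detected with
small position-specific scoring matrices shipped as TSV fixtures; a call
requires the best window to reach the profile threshold, and the DDE call
additionally requires the catalytic D..D..E triad at its expected columns.
A family is potentially active when its intact ORFs realise the group's
expected layout (two intact ORFs for all groups except Spy's single
DDE-transposase ORF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from ._motifs import AA20, GROUPS, blosum62
from .genome_io import six_frame_translate

__all__ = [
    "OrfAnnotation",
    "DomainProfile",
    "build_profile",
    "load_profiles",
    "find_orfs",
    "scan_domains",
    "annotate_orfs",
    "call_potential_active",
]

_AA_IDX = {a: i for i, a in enumerate(AA20)}


@dataclass
class OrfAnnotation:
    start: int  # on the consensus, 0-based half-open, includes the stop codon
    end: int
    strand: str
    frame: int
    protein: str
    intact: bool
    domains: set = field(default_factory=set)


@dataclass
class DomainProfile:
    name: str
    matrix: np.ndarray  # (length, 20), columns in AA20 order
    threshold: float
    triad: tuple[int, int, int] | None = None
    triad_tol: int = 1

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def build_profile(
    name: str,
    consensus: str,
    threshold_frac: float = 0.55,
    triad: tuple[int, int, int] | None = None,
) -> DomainProfile:
    """PSSM from a consensus motif: BLOSUM62 row per position.

    The threshold is a fixed fraction of the self-score, placed between the
    scores of true (possibly diverged) motif instances and shuffled decoys.
    """
    mat = np.array([[blosum62(c, a) for a in AA20] for c in consensus])
    self_score = sum(blosum62(c, c) for c in consensus)
    return DomainProfile(name, mat, threshold_frac * self_score, triad)


def write_profile(profile: DomainProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name: {profile.name}\n")
        fh.write(f"# threshold: {profile.threshold:g}\n")
        if profile.triad:
            fh.write(f"# triad: {','.join(map(str, profile.triad))}\n")
        fh.write("pos\t" + "\t".join(AA20) + "\n")
        for i, row in enumerate(profile.matrix):
            fh.write(f"{i}\t" + "\t".join(f"{v:g}" for v in row) + "\n")


def read_profile(path) -> DomainProfile:
    name = None
    threshold = None
    triad = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# name:"):
                name = line.split(":", 1)[1].strip()
            elif line.startswith("# threshold:"):
                threshold = float(line.split(":", 1)[1])
            elif line.startswith("# triad:"):
                triad = tuple(int(x) for x in line.split(":", 1)[1].split(","))
            elif line.startswith("pos\t") or not line.strip():
                continue
            else:
                rows.append([float(v) for v in line.split("\t")[1:]])
    return DomainProfile(name, np.array(rows), threshold, triad)


def load_profiles() -> dict[str, DomainProfile]:
    """The shipped domain PSSM fixtures (profiles/*.tsv)."""
    out = {}
    pdir = resources.files("phiskit") / "profiles"
    for entry in sorted(pdir.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".tsv"):
            with resources.as_file(entry) as p:
                prof = read_profile(p)
            out[prof.name] = prof
    return out


def find_orfs(consensus: str, min_orf_aa: int = 100) -> list[OrfAnnotation]:
    """Met-to-stop ORFs on all six frames of the consensus."""
    n = len(consensus)
    orfs: list[OrfAnnotation] = []
    frames = six_frame_translate(consensus)
    for fidx, prot in enumerate(frames):
        f = fidx % 3
        strand = "+" if fidx < 3 else "-"
        seg_start = 0
        i = 0
        while i <= len(prot):
            if i == len(prot) or prot[i] == "*":
                seg = prot[seg_start:i]
                m = seg.find("M")
                if m >= 0:
                    aa_len = len(seg) - m
                    has_stop = i < len(prot)
                    if aa_len >= min_orf_aa:
                        a = seg_start + m
                        b = i + 1 if has_stop else i
                        if strand == "+":
                            s, e = f + 3 * a, f + 3 * b
                        else:
                            s, e = n - (f + 3 * b), n - (f + 3 * a)
                        orfs.append(
                            OrfAnnotation(
                                s, e, strand, f + 1, seg[m:], has_stop
                            )
                        )
                seg_start = i + 1
            i += 1
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def scan_domains(protein: str, profiles: dict[str, DomainProfile]) -> set:
    """Domains whose best PSSM window clears the threshold (plus DDE triad)."""
    if not protein:
        raise ValueError("empty protein")
    idx = np.array([_AA_IDX.get(a, -1) for a in protein])
    found = set()
    for prof in profiles.values():
        L = prof.length
        if len(protein) < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(idx, L)
        valid = win >= 0
        safe = np.where(valid, win, 0)
        pos_scores = prof.matrix[np.arange(L)[None, :], safe] * valid
        totals = pos_scores.sum(axis=1)
        best_w = int(np.argmax(totals))
        if totals[best_w] < prof.threshold:
            continue
        if prof.triad:
            ok = True
            window = protein[best_w : best_w + L]
            for col, residue in zip(prof.triad, "DDE"):
                lo = max(0, col - prof.triad_tol)
                hi = min(L, col + prof.triad_tol + 1)
                if residue not in window[lo:hi]:
                    ok = False
                    break
            if not ok:
                continue
        found.add(prof.name)
    return found


def annotate_orfs(
    consensus: str,
    profiles: dict[str, DomainProfile],
    min_orf_aa: int = 100,
) -> list[OrfAnnotation]:
    orfs = find_orfs(consensus, min_orf_aa)
    for o in orfs:
        o.domains = scan_domains(o.protein, profiles)
    return orfs


def call_potential_active(family, group: str | None = None) -> bool:
    """True iff intact ORFs realise the group's expected layout.

    The expected ORFs must lie on one strand and not overlap each other, as
    in the elements' canonical architecture; this keeps chance open frames on
    the antisense strand from standing in for a disrupted accessory ORF.
    """
    grp = group or getattr(family, "group", None)
    if grp is None or grp == "unclassified":
        raise ValueError("classify first: family has no group label")
    gdef = GROUPS[grp]
    layouts = sorted(gdef.orfs, key=lambda l: -len(l.domains))
    for strand in "+-":
        intact = [o for o in family.orfs if o.intact and o.strand == strand]
        used: set[int] = set()
        ok = True
        for layout in layouts:
            match = None
            for i, o in enumerate(intact):
                if i in used:
                    continue
                if any(
                    o.start < intact[j].end and intact[j].start < o.end for j in used
                ):
                    continue
                if set(layout.domains) <= o.domains:
                    match = i
                    break
            if match is None:
                ok = False
                break
            used.add(match)
        if ok:
            return True
    return False
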