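"""Sequence I/O and coordinate utilities.

All internal coordinates are 0-based half-open on the forward strand; strand is
carried separately and conversion to 1-based (GFF3) or BED happens only at the
file boundary. Soft-masked (lowercase) genome bases are uppercased and kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "SequenceRecord",
    "Interval",
    "GenomeIndex",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "translate",
    "six_frame_translate",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "write_tsv",
]

_DNA = set("ACGTN")

_COMP = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code (table 1). Codons containing N translate to 'X'.
_CODONS = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODONS[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence (DNA or protein)."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open span on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.seq_id}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


class GenomeIndex:
    """Named DNA sequences with clamped interval extraction.

    ``extract`` returns the forward-strand slice reverse-complemented when the
    interval is on the minus strand, so extract/revcomp commute.
    """

    def __init__(self, records: Iterable[SequenceRecord]):
        self._seqs: dict[str, str] = {}
        self._order: list[str] = []
        for rec in records:
            if rec.id in self._seqs:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            self._seqs[rec.id] = rec.seq.upper()
            self._order.append(rec.id)
        if not self._seqs:
            raise ValueError("empty genome")

    @property
    def ids(self) -> list[str]:
        return list(self._order)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._seqs

    def length(self, seq_id: str) -> int:
        return len(self._seqs[seq_id])

    def sequence(self, seq_id: str) -> str:
        return self._seqs[seq_id]

    def records(self) -> list[SequenceRecord]:
        return [SequenceRecord(i, self._seqs[i]) for i in self._order]

    def extract(self, iv: Interval) -> str:
        seq = self._seqs[iv.seq_id]
        s = max(0, min(iv.start, len(seq)))
        e = max(0, min(iv.end, len(seq)))
        frag = seq[s:e]
        return revcomp(frag) if iv.strand == "-" else frag


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters: {sorted(bad)}")
    return seq.translate(_COMP)[::-1]


def translate(seq: str) -> str:
    """Translate one forward frame; stops as '*', ambiguous codons as 'X'."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(_CODONS.get(seq[i : i + 3], "X"))
    return "".join(out)


def six_frame_translate(seq: str) -> list[str]:
    """All six reading frames: forward 1-3 then reverse 1-3 (on the revcomp)."""
    rc = revcomp(seq)
    return [translate(seq[f:]) for f in range(3)] + [translate(rc[f:]) for f in range(3)]


# ---------------------------------------------------------------------------
# FASTA


def _parse_fasta(handle, path: str) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    header_line = 0

    def flush(lineno: int):
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"{path}: empty sequence for {header!r} (line {header_line})")
        records.append(SequenceRecord(header, seq, desc))
        header, chunks = None, []

    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            flush(lineno)
            parts = line[1:].split(None, 1)
            if not parts:
                raise FastaParseError(f"{path}: empty header at line {lineno}")
            header = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            header_line = lineno
            if header in seen:
                raise FastaParseError(f"{path}: duplicate id {header!r} at line {lineno}")
            seen.add(header)
        else:
            if header is None:
                raise FastaParseError(f"{path}: sequence before header at line {lineno}")
            chunks.append(line.strip())
    flush(-1)
    if not records:
        raise FastaParseError(f"{path}: no records")
    return records


def read_fasta(path, dna: bool = True) -> list[SequenceRecord]:
    """Read FASTA; DNA records are uppercased on load."""
    with open(path) as fh:
        records = _parse_fasta(fh, str(path))
    if dna:
        records = [SequenceRecord(r.id, r.seq.upper(), r.description) for r in records]
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / GFF3 / TSV

_BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand"


def write_bed(features: Sequence[tuple[Interval, str, float]], path) -> None:
    """BED6; features are (interval, name, score). 0-based half-open."""
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for iv, name, score in features:
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def read_bed(path) -> list[tuple[Interval, str, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                (Interval(f[0], int(f[1]), int(f[2]), f[5]), f[3], float(f[4]))
            )
    return out


def write_gff3(
    features: Sequence[tuple[Interval, str, dict]],
    path,
    lengths: dict[str, int] | None = None,
    source: str = "phiskit",
) -> None:
    """GFF3 (1-based inclusive); features are (interval, type, attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, ftype, attrs in features:
            if lengths is not None and iv.end > lengths.get(iv.seq_id, iv.end):
                raise ValueError(f"interval {iv} beyond sequence end")
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                f"{iv.seq_id}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attr_s}\n"
            )


def read_gff3(path) -> list[tuple[Interval, str, dict]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = {}
            if f[8] != ".":
                for kv in f[8].split(";"):
                    k, _, v = kv.partition("=")
                    attrs[k] = v
            out.append((Interval(f[0], int(f[3]) - 1, int(f[4]), f[6]), f[2], attrs))
    return out


def write_tsv(rows: Sequence[dict], path, columns: Sequence[str] | None = None) -> None:
    """Plain TSV with header; column order fixed by `columns` or first row."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
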