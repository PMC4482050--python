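"""End-to-end orchestration: search -> build -> annotate -> classify -> census.

Every stage is a pure function of (inputs, config); the run directory carries
a JSON manifest with per-stage parameters, counts and output checksums, so a
rerun on the same inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import structure_annotator
from .classifier_census import census as run_census
from .classifier_census import classify_family
from .family_builder import (
    Family,
    align_copies,
    build_consensus,
    define_boundaries,
    extend_and_orient,
    recruit_copies,
)
from .genome_io import GenomeIndex, Interval, write_fasta, write_gff3, write_tsv
from .genome_io import SequenceRecord
from .homology_search import ProteinQuery, merge_hit_loci, search_transposase
from .orf_domain_annotator import annotate_orfs, call_potential_active, load_profiles
from .structure_annotator import detect_tirs, infer_tsd, is_full_length, test_spy_motif

__all__ = ["PipelineConfig", "RunResult", "run_pipeline"]

REPORT_COLUMNS = [
    "family", "group", "tsd_len", "tsd_consensus", "outer5", "outer3",
    "tir_len", "n_copies", "n_full_length", "potential_active",
]


@dataclass
class PipelineConfig:
    """All stage thresholds; defaults reproduce the standard study settings."""

    search_evalue: float = 1e-4
    recruit_evalue: float = 1e-5
    min_len: int = 50
    min_identity: float = 0.80
    flank: int = 2000
    locus_gap: int = 500
    tir_min_len: int = 5
    tir_max_len: int = 1100
    tir_max_mismatch_frac: float = 0.2
    tsd_max_len: int = 10
    tsd_min_support: float = 0.5
    min_orf_aa: int = 100
    max_align_copies: int = 15
    min_consensus_len: int = 100
    boundary_threshold: float = 0.6
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunResult:
    families: list[Family]
    report_rows: list[dict]
    census: object
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(stage: str, msg: str) -> None:
    print(f"[phis:{stage}] {msg}", file=sys.stderr)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def build_family(
    probe: str,
    genome: GenomeIndex,
    cfg: PipelineConfig,
    name: str,
) -> Family | None:
    """One candidate locus -> one Family, or None if no element emerges."""
    try:
        hits = recruit_copies(
            probe, genome, cfg.recruit_evalue, cfg.min_len, cfg.min_identity
        )
    except ValueError:
        return None
    if not hits:
        return None
    extended = extend_and_orient(hits, genome, cfg.flank)
    rows = sorted(extended, key=lambda c: -len(c.core_seq))[: cfg.max_align_copies]
    if len(rows) < 2:
        consensus = rows[0].oriented_seq if rows else None
        if consensus is None:
            return None
        # single-copy path: the recruited core is the provisional consensus
        consensus = rows[0].core_seq
    else:
        aln = align_copies(rows)
        bounds = define_boundaries(aln, cfg.boundary_threshold)
        if bounds is None:
            return None
        consensus = build_consensus(aln, bounds)
    if len(consensus) < cfg.min_consensus_len:
        return None

    # final copy set recruited with the consensus itself
    copies = recruit_copies(
        consensus, genome, cfg.recruit_evalue, cfg.min_len, cfg.min_identity
    )
    if not copies:
        return None
    extended = extend_and_orient(copies, genome, cfg.flank)
    fam = Family(name=name, consensus=consensus, copies=extended)

    try:
        fam.tir = detect_tirs(
            consensus, cfg.tir_min_len, cfg.tir_max_len, cfg.tir_max_mismatch_frac
        )
    except ValueError:
        fam.tir = None
    full = [c for c in extended if fam.tir and is_full_length(c, fam.tir)]
    if len(full) >= 3:
        fam.tsd = infer_tsd(full, cfg.tsd_max_len, cfg.tsd_min_support)
        if fam.tsd.length == 0:
            fam.spy_fraction = test_spy_motif(full)
    else:
        fam.tsd = structure_annotator.TSDModel(0, "", 0.0)
        fam.notes.append("fewer than 3 full-length copies; TSD not inferred")
    return fam


def run_pipeline(
    genome: GenomeIndex,
    queries: list[ProteinQuery],
    config: PipelineConfig | None = None,
    outdir=None,
) -> RunResult:
    cfg = config or PipelineConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        (out / "families").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "config": dataclasses.asdict(cfg)}
    profiles = load_profiles()

    # -- search ------------------------------------------------------------
    try:
        hits = search_transposase(genome, queries, cfg.search_evalue)
    except ValueError as e:
        if genome.total_length == 0:
            hits = []
        else:
            raise StageError("search", str(e))
    loci = merge_hit_loci(hits, cfg.locus_gap)
    _log("search", f"{len(hits)} hits -> {len(loci)} candidate loci")
    manifest["stages"]["search"] = {"hits": len(hits), "loci": len(loci)}

    # -- build -------------------------------------------------------------
    families: list[Family] = []
    claimed: list[Interval] = []
    loci_sorted = sorted(loci, key=lambda l: (l.best_evalue, l.interval))
    for locus in loci_sorted:
        iv = locus.interval
        cov = 0
        for c in claimed:
            if c.overlaps(iv):
                cov += min(c.end, iv.end) - max(c.start, iv.start)
        if cov >= 0.5 * len(iv):
            continue
        probe = genome.extract(iv)
        if len(probe) < cfg.min_len:
            continue
        fam = build_family(probe, genome, cfg, name=f"fam{len(families) + 1}")
        if fam is None:
            continue
        families.append(fam)
        claimed.extend(c.core.interval for c in fam.copies)
    _log("build", f"{len(families)} families")
    manifest["stages"]["build"] = {"families": len(families)}

    # -- annotate / classify ----------------------------------------------
    for fam in families:
        if len(fam.consensus) >= 3 * cfg.min_orf_aa:
            fam.orfs = annotate_orfs(fam.consensus, profiles, cfg.min_orf_aa)
        fam.group, notes = classify_family(fam.tsd, fam.spy_fraction, orfs=None)
        fam.notes.extend(notes)
        if fam.group != "unclassified":
            fam.potential_active = call_potential_active(fam, fam.group)
    n_classified = sum(f.group != "unclassified" for f in families)
    _log("classify", f"{n_classified}/{len(families)} families classified")
    manifest["stages"]["classify"] = {"classified": n_classified}

    # -- census ------------------------------------------------------------
    report = run_census(
        families, genome, cfg.recruit_evalue, cfg.min_len, cfg.min_identity
    )
    # keep family copy counts in sync with the census
    by_name = {r["family"]: r for r in report.family_rows}
    report_rows = []
    for fam in families:
        crow = by_name[fam.name]
        report_rows.append(
            {
                "family": fam.name,
                "group": fam.group,
                "tsd_len": fam.tsd.length if fam.tsd else "",
                "tsd_consensus": fam.tsd.consensus if fam.tsd else "",
                "outer5": (fam.tsd.outer5 or "") if fam.tsd else "",
                "outer3": (fam.tsd.outer3 or "") if fam.tsd else "",
                "tir_len": fam.tir.length if fam.tir else 0,
                "n_copies": crow["n_copies"],
                "n_full_length": crow["n_full_length"],
                "potential_active": fam.potential_active,
            }
        )
    _log("census", f"{sum(r['n_copies'] for r in report_rows)} copies total")
    manifest["stages"]["census"] = {
        "copies": sum(r["n_copies"] for r in report_rows)
    }

    # -- outputs -----------------------------------------------------------
    if out is not None:
        write_tsv(
            [
                {
                    "query": h.query_id,
                    "seq_id": h.interval.seq_id,
                    "start": h.interval.start,
                    "end": h.interval.end,
                    "strand": h.interval.strand,
                    "frame": h.frame,
                    "bitscore": f"{h.bitscore:.2f}",
                    "evalue": f"{h.evalue:.3g}",
                }
                for h in hits
            ],
            out / "hits.tsv",
            columns=["query", "seq_id", "start", "end", "strand", "frame", "bitscore", "evalue"],
        )
        for fam in families:
            write_fasta(
                [SequenceRecord(fam.name, fam.consensus)],
                out / "families" / f"{fam.name}.fa",
            )
            write_gff3(
                [
                    (c.core.interval, "dispersed_repeat",
                     {"ID": f"{fam.name}_c{i}", "identity": f"{c.core.identity:.3f}"})
                    for i, c in enumerate(fam.copies)
                ],
                out / "families" / f"{fam.name}.copies.gff3",
            )
        write_tsv(report_rows, out / "report.tsv", columns=REPORT_COLUMNS)
        cfg.to_yaml(out / "config.yaml")
        checksums = {}
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                checksums[str(p.relative_to(out))] = _sha256(p)
        manifest["outputs"] = checksums
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    return RunResult(families, report_rows, report, manifest)
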