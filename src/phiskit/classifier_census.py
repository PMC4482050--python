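"""Group assignment from structural evidence, census statistics, and the
activity-abundance correlation.

A family's group is defined by its target-site duplication composition:

* ISL2EU        2 bp "AT" duplication with conserved outer A...T (A|AT|T)
* NuwaII        3 bp duplication within TNA with conserved outer C...G (C|TNA|G)
* PIF/Harbinger 3 bp TWA
* NuwaI         3 bp CWG
* Pangu         3 bp ANT
* Spy           no duplication, insertion within the AAATTT motif

Outer-conserved signatures take precedence over plain 3-bp patterns because
TWA is a subset of TNA; a family whose evidence fits none of the six stays
"unclassified".  The census re-counts copies per family with the standard
recruitment thresholds and tallies full-length and potentially active
families per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats as _st

from ._motifs import GROUPS, IUPAC, NUWA1, NUWA2, PANGU, PIF, SPY, ISL2EU
from .family_builder import Family, extend_and_orient, recruit_copies
from .structure_annotator import TSDModel, is_full_length

__all__ = [
    "GroupSignature",
    "SIGNATURES",
    "CensusReport",
    "CorrelationResult",
    "classify_family",
    "census",
    "pearson_correlation",
]


@dataclass(frozen=True)
class GroupSignature:
    group: str
    tsd_len: int
    tsd_pattern: str
    outer5: str | None
    outer3: str | None
    spy_motif: bool
    expected_orf_layout: tuple


SIGNATURES: dict[str, GroupSignature] = {
    name: GroupSignature(
        name, g.tsd_len, g.tsd_pattern, g.outer5, g.outer3,
        g.spy_motif is not None, g.orfs,
    )
    for name, g in GROUPS.items()
}


def _compatible(consensus: str, pattern: str) -> bool:
    """Every observed per-position base set within the pattern's IUPAC set."""
    if len(consensus) != len(pattern):
        return False
    return all(IUPAC[c] <= IUPAC[p] for c, p in zip(consensus, pattern))


def classify_family(
    tsd: TSDModel, spy_fraction: float = 0.0, orfs=None
) -> tuple[str, list[str]]:
    """(group label, notes); "unclassified" is a value, never an error."""
    notes: list[str] = []
    group = "unclassified"
    if tsd.length == 2 and _compatible(tsd.consensus, "AT") and tsd.outer5 == "A" and tsd.outer3 == "T":
        group = ISL2EU
    elif tsd.length == 3 and _compatible(tsd.consensus, "TNA") and tsd.outer5 == "C" and tsd.outer3 == "G":
        group = NUWA2
        if tsd.alternative_length:
            notes.append(
                f"duplication could also be read as {tsd.alternative_length} bp "
                f"({tsd.outer5}{tsd.consensus}{tsd.outer3}); 3 bp preferred"
            )
    elif tsd.length == 3:
        plain = [(PIF, "TWA"), (NUWA1, "CWG"), (PANGU, "ANT")]
        matches = [g for g, pat in plain if _compatible(tsd.consensus, pat)]
        if matches:
            group = matches[0]
            if len(matches) > 1:
                notes.append(f"ambiguous 3 bp pattern, also compatible with {matches[1:]}")
            if _compatible(tsd.consensus, "TNA") and group == PIF:
                notes.append(
                    f"{tsd.consensus} within TNA: NuwaII excluded by missing outer C/G"
                )
    elif tsd.length == 0 and spy_fraction >= 0.5:
        group = SPY
    if group != "unclassified" and orfs is not None:
        from .orf_domain_annotator import call_potential_active

        class _Tmp:
            pass

        tmp = _Tmp()
        tmp.orfs = orfs
        if not call_potential_active(tmp, group):
            notes.append("ORF layout does not match the group's expected layout")
    return group, notes


@dataclass
class CensusReport:
    family_rows: list[dict] = field(default_factory=list)

    def group_totals(self) -> dict[str, dict]:
        out: dict[str, dict] = {}
        for row in self.family_rows:
            g = row["group"]
            acc = out.setdefault(
                g, {"families": 0, "potential_active": 0, "copies": 0, "full_length": 0}
            )
            acc["families"] += 1
            acc["potential_active"] += int(row["potential_active"])
            acc["copies"] += row["n_copies"]
            acc["full_length"] += row["n_full_length"]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.family_rows)


def census(
    families: list[Family],
    genome,
    evalue_max: float = 1e-5,
    min_len: int = 50,
    min_identity: float = 0.80,
    flank: int = 60,
) -> CensusReport:
    """Copy and full-length counts per family, re-recruited from scratch."""
    rows = []
    for fam in families:
        try:
            hits = recruit_copies(fam.consensus, genome, evalue_max, min_len, min_identity)
        except ValueError:
            hits = []
        n_full = 0
        if hits and fam.tir is not None:
            for c in extend_and_orient(hits, genome, flank=flank):
                if is_full_length(c, fam.tir):
                    n_full += 1
        rows.append(
            {
                "family": fam.name,
                "group": fam.group,
                "n_copies": len(hits),
                "n_full_length": n_full,
                "potential_active": fam.potential_active,
            }
        )
    report = CensusReport(rows)
    totals = report.group_totals()
    assert sum(t["copies"] for t in totals.values()) == sum(
        r["n_copies"] for r in rows
    )
    return report


@dataclass
class CorrelationResult:
    r: float
    t: float
    df: int
    p: float


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test.

    r = cov(x, y) / (sd_x * sd_y); t = r * sqrt(df) / sqrt(1 - r^2) with
    df = n - 2; p from the t distribution, two-sided.
    """
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance")
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    r = sxy / math.sqrt(sxx * syy)
    df = n - 2
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = math.inf
        p = 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1 - r * r)
        p = 2 * _st.t.sf(abs(t), df)
    return CorrelationResult(r, t, df, p)
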