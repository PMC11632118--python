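"""Instrument selection: significance filtering, distance/LD clumping,
confounder exclusion.

Instruments must be strongly associated with the exposure (p < 5e-8 by
default), approximately independent (no same-chromosome pair closer than
10,000 kb, no known pairwise r-squared >= 0.001), and not associated with
confounders (a user-supplied exclusion list, since confounder screening
is done against external GWASs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .gwas_io import LdTable, SummaryStatRecord

P_THRESHOLD = 5e-8
CLUMP_KB = 10_000
CLUMP_R2 = 0.001


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for the three instrument criteria."""

    p_threshold: float = P_THRESHOLD
    clump_kb: float = CLUMP_KB
    clump_r2: float = CLUMP_R2
    exclusion_list: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError(f"p_threshold outside (0,1): {self.p_threshold}")
        if self.clump_kb <= 0:
            raise ValueError(f"clump_kb must be > 0: {self.clump_kb}")
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ValueError(f"clump_r2 outside [0,1]: {self.clump_r2}")


@dataclass
class SelectionReport:
    """Per-stage drop accounting: (rsid, stage, reason) rows."""

    dropped: list[tuple[str, str, str]] = field(default_factory=list)

    def tally(self, stage: str) -> int:
        return sum(1 for _, s, _ in self.dropped if s == stage)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rsid\tstage_dropped\treason\n")
            for rsid, stage, reason in self.dropped:
                fh.write(f"{rsid}\t{stage}\t{reason}\n")


def filter_significant(
    records: Sequence[SummaryStatRecord],
    p_threshold: float = P_THRESHOLD,
    report: SelectionReport | None = None,
) -> list[SummaryStatRecord]:
    """Keep records with pval strictly below the threshold, in order.

    Records with missing pval are excluded and tallied.
    """
    out = []
    for r in records:
        if r.pval is None:
            if report is not None:
                report.dropped.append((r.rsid, "significance", "missing-pval"))
        elif r.pval < p_threshold:
            out.append(r)
        elif report is not None:
            report.dropped.append((r.rsid, "significance", "above-threshold"))
    return out


def clump(
    records: Sequence[SummaryStatRecord],
    clump_kb: float = CLUMP_KB,
    clump_r2: float = CLUMP_R2,
    ld: LdTable | None = None,
    report: SelectionReport | None = None,
) -> list[SummaryStatRecord]:
    """Greedy distance/LD clumping.

    Repeatedly takes the most significant unclaimed SNP as the index and
    discards every unclaimed SNP on the same chromosome closer than
    ``clump_kb`` kilobases, or with known r-squared >= ``clump_r2`` to the
    index. Ties on pval break by rsid lexicographic order, so the result
    is invariant to input row order. SNPs with missing position or pval
    are dropped with a reason. Returns survivors in the order claimed
    (ascending pval).
    """
    ld = ld if ld is not None else LdTable()
    usable = []
    for r in records:
        if r.pos is None or r.chrom is None:
            if report is not None:
                report.dropped.append((r.rsid, "clump", "missing-position"))
        elif r.pval is None:
            if report is not None:
                report.dropped.append((r.rsid, "clump", "missing-pval"))
        else:
            usable.append(r)

    pool = sorted(usable, key=lambda r: (r.pval, r.rsid))
    claimed: set[str] = set()
    kept: list[SummaryStatRecord] = []
    for index in pool:
        if index.rsid in claimed:
            continue
        claimed.add(index.rsid)
        kept.append(index)
        for other in pool:
            if other.rsid in claimed:
                continue
            near = (other.chrom == index.chrom
                    and abs(other.pos - index.pos) < clump_kb * 1000)
            r2 = ld.get(index.rsid, other.rsid)
            in_ld = r2 is not None and r2 >= clump_r2
            if near or in_ld:
                claimed.add(other.rsid)
                if report is not None:
                    reason = "distance" if near else "ld"
                    report.dropped.append(
                        (other.rsid, "clump", f"{reason}:{index.rsid}"))
    return kept


def apply_exclusions(
    records: Sequence[SummaryStatRecord],
    exclusion_list: frozenset[str] | set[str] = frozenset(),
    report: SelectionReport | None = None,
) -> list[SummaryStatRecord]:
    """Remove confounder-associated rsids (user-supplied list)."""
    out = []
    for r in records:
        if r.rsid in exclusion_list:
            if report is not None:
                report.dropped.append((r.rsid, "exclusion", "confounder-associated"))
        else:
            out.append(r)
    return out


def select_instruments(
    records: Sequence[SummaryStatRecord],
    config: SelectionConfig = SelectionConfig(),
    ld: LdTable | None = None,
) -> tuple[list[SummaryStatRecord], SelectionReport]:
    """Full selection pipeline: significance -> clump -> exclusions."""
    report = SelectionReport()
    sig = filter_significant(records, config.p_threshold, report)
    clumped = clump(sig, config.clump_kb, config.clump_r2, ld, report)
    final = apply_exclusions(clumped, config.exclusion_list, report)
    return final, report


def read_exclusion_list(path: str | Path) -> frozenset[str]:
    """One rsid per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.split()[0])
    return frozenset(out)


__all__ = [
    "SelectionConfig", "SelectionReport", "filter_significant", "clump",
    "apply_exclusions", "select_instruments", "read_exclusion_list",
    "P_THRESHOLD", "CLUMP_KB", "CLUMP_R2",
]
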