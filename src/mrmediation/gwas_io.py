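"""Reading, validating and writing GWAS summary-statistics tables.

The on-disk dialect is tab-separated text with one header row. Missing
values are written as ``NA``; both ``NA`` and ``.`` are accepted on read.
Mandatory columns are ``rsid``, ``effect_allele``, ``other_allele``,
``beta`` and ``se``; ``chrom``, ``pos``, ``eaf``, ``pval`` and ``n`` are
optional and yield missing-valued fields when absent. Positions are
1-based. Alleles are uppercased on read; indels are kept as
multi-character strings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: Canonical column order of the dialect.
COLUMNS = ("rsid", "chrom", "pos", "effect_allele", "other_allele",
           "eaf", "beta", "se", "pval", "n")

MANDATORY = ("rsid", "effect_allele", "other_allele", "beta", "se")

MISSING_SENTINELS = {"", "NA", "."}


class ConfigurationError(ValueError):
    """A required column or configuration key could not be resolved."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (log-odds for binary traits, SD units for quantitative ones); ``se``
    its standard error. ``pval_inconsistent`` is set when the reported
    p-value disagrees with 2*Phi(-|beta/se|) by more than a factor of two
    (the record is flagged, never dropped, for this).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    pval: float | None = None
    n: float | None = None
    pval_inconsistent: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValueError(f"{self.rsid}: se must be > 0, got {self.se}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele identical")


@dataclass
class ReadReport:
    """Row-level accounting of one read: rejects carry (row, reason)."""

    path: str
    n_read: int = 0
    n_kept: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)
    n_flagged_inconsistent: int = 0

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


def wald_pvalue(beta: float, se: float) -> float:
    """Two-sided normal p-value for beta/se."""
    return float(2.0 * norm.sf(abs(beta) / se))


def _pval_consistent(pval: float, beta: float, se: float) -> bool:
    expected = wald_pvalue(beta, se)
    if expected == 0.0:  # underflow: any tiny reported p is consistent
        return pval < 1e-300
    return expected / 2.0 <= pval <= min(1.0, expected * 2.0)


def _parse_float(token: object) -> float | None:
    if token is None:
        return None
    s = str(token).strip()
    if s in MISSING_SENTINELS or s.lower() == "nan":
        return None
    return float(s)  # raises ValueError for garbage


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[SummaryStatRecord], ReadReport]:
    """Read a summary-statistics TSV into validated records.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    column_map
        Optional mapping from canonical names (``rsid``, ``beta`` ...) to
        the column names used in the file.

    Returns
    -------
    records, report
        Records in file order (invalid rows skipped and tallied in the
        report) and the row-level accounting.

    Raises
    ------
    ConfigurationError
        If a mandatory column cannot be resolved.
    """
    path = Path(path)
    colmap = {c: c for c in COLUMNS}
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for name in MANDATORY:
        if colmap[name] not in df.columns:
            raise ConfigurationError(
                f"{path}: mandatory column {name!r} (file name {colmap[name]!r}) not found"
            )
    present = {c: colmap[c] for c in COLUMNS if colmap[c] in df.columns}

    report = ReadReport(path=str(path), n_read=len(df))
    records: list[SummaryStatRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        raw = dict(zip(df.columns, row))
        try:
            beta = _parse_float(raw[present["beta"]])
            se = _parse_float(raw[present["se"]])
            if beta is None or se is None:
                raise ValueError("missing beta or se")
            if se <= 0:
                raise ValueError(f"se must be > 0, got {se}")
            ea = str(raw[present["effect_allele"]]).strip().upper()
            oa = str(raw[present["other_allele"]]).strip().upper()
            if not ea or not oa or ea in MISSING_SENTINELS or oa in MISSING_SENTINELS:
                raise ValueError("missing allele")
            if ea == oa:
                raise ValueError("effect_allele equals other_allele")
            rsid = str(raw[present["rsid"]]).strip()
            if not rsid or rsid in MISSING_SENTINELS:
                raise ValueError("missing rsid")

            def opt(name: str) -> float | None:
                return _parse_float(raw[present[name]]) if name in present else None

            eaf = opt("eaf")
            if eaf is not None and not 0.0 <= eaf <= 1.0:
                raise ValueError(f"eaf outside [0,1]: {eaf}")
            pval = opt("pval")
            if pval is not None and not 0.0 < pval <= 1.0:
                raise ValueError(f"pval outside (0,1]: {pval}")
            n = opt("n")
            if n is not None and n <= 0:
                raise ValueError(f"n must be > 0: {n}")
            pos_f = opt("pos")
            pos = int(pos_f) if pos_f is not None else None
            chrom_raw = str(raw[present["chrom"]]).strip() if "chrom" in present else ""
            chrom = chrom_raw if chrom_raw not in MISSING_SENTINELS else None

            flagged = pval is not None and not _pval_consistent(pval, beta, se)
            records.append(SummaryStatRecord(
                rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
                chrom=chrom, pos=pos, eaf=eaf, pval=pval, n=n,
                pval_inconsistent=flagged,
            ))
            if flagged:
                report.n_flagged_inconsistent += 1
        except (ValueError, KeyError) as exc:
            report.rejects.append((i, str(exc)))
    report.n_kept = len(records)
    logger.info("read %s: %d rows, %d kept, %d rejected, %d flagged",
                path, report.n_read, report.n_kept, report.n_rejected,
                report.n_flagged_inconsistent)
    return records, report


def _fmt(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return format(value, ".17g")
    return str(value)


def write_summary_stats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    """Write records in the TSV dialect; round-trips at full precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for rec in records:
            fh.write("\t".join(_fmt(getattr(rec, c)) for c in COLUMNS) + "\n")


class LdTable:
    """Symmetric lookup of pairwise LD r-squared by rsid pair.

    Self-LD is 1 by definition; unlisted pairs return ``None``.
    """

    def __init__(self) -> None:
        self._r2: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 outside [0,1]: {r2}")
        self._r2[self._key(a, b)] = r2

    def get(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b))

    def __len__(self) -> int:
        return len(self._r2)


def read_ld_table(path: str | Path) -> tuple[LdTable, ReadReport]:
    """Read a three-column (rsid_a, rsid_b, r2) TSV into an LdTable.

    Rows with r2 outside [0,1] or unparseable are rejected and tallied.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("rsid_a", "rsid_b", "r2"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: mandatory column {col!r} not found")
    table = LdTable()
    report = ReadReport(path=str(path), n_read=len(df))
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw = dict(zip(df.columns, row))
        try:
            r2 = _parse_float(raw["r2"])
            if r2 is None:
                raise ValueError("missing r2")
            table.set(str(raw["rsid_a"]).strip(), str(raw["rsid_b"]).strip(), r2)
            report.n_kept += 1
        except ValueError as exc:
            report.rejects.append((i, str(exc)))
    return table, report


def records_to_frame(records: Sequence[SummaryStatRecord]) -> pd.DataFrame:
    """Tabular view of records (one row per SNP, canonical columns)."""
    return pd.DataFrame([{c: getattr(r, c) for c in COLUMNS} for r in records],
                        columns=list(COLUMNS))


__all__ = [
    "SummaryStatRecord", "LdTable", "ReadReport", "ConfigurationError",
    "read_summary_stats", "write_summary_stats", "read_ld_table",
    "records_to_frame", "wald_pvalue", "COLUMNS", "MANDATORY", "replace",
]
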