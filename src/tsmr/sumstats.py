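"""Reading, validation, and writing of GWAS summary-statistics tables.

A summary-statistics table holds one row per variant with the effect/other
allele, the per-allele effect estimate (SD units for continuous traits,
log odds ratio for binary traits), its standard error, and optional
frequency, p-value and sample-size columns.  Input files are delimited
text (tab or comma, auto-detected) with a user-supplied column map; all
downstream modules consume the in-memory table, never the file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryRecord",
    "SummaryStatsTable",
    "read_sumstats",
    "write_sumstats",
    "write_report",
    "load_column_map",
    "CANONICAL_COLUMNS",
]

#: canonical field names; a column map translates file headers onto these
CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_cases",
)

MANDATORY_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se")

_NUMERIC_COLUMNS = ("pos", "eaf", "beta", "se", "pval", "n", "n_cases")


@dataclass
class SummaryRecord:
    """One variant's association record for a single trait and sample."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    pval: float | None = None
    n: int | None = None
    n_cases: int | None = None

    def validate(self) -> str | None:
        """Return a reason string if the record violates an invariant, else None."""
        if not self.snp_id:
            return "empty snp_id"
        if not self.effect_allele or not self.other_allele:
            return "empty allele"
        if self.effect_allele == self.other_allele:
            return "effect_allele == other_allele"
        if not math.isfinite(self.beta):
            return "non-finite beta"
        if not math.isfinite(self.se) or self.se <= 0:
            return "se <= 0"
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            return "eaf outside [0, 1]"
        if self.pval is not None and not (0.0 < self.pval <= 1.0):
            return "pval outside (0, 1]"
        return None

    @property
    def zsq(self) -> float:
        return (self.beta / self.se) ** 2


@dataclass
class SummaryStatsTable:
    """Ordered collection of :class:`SummaryRecord` for one trait/sample.

    ``trait_type`` is ``"continuous"`` (beta in SD units) or ``"binary"``
    (beta on the log-OR scale).  SNP identifiers are unique within a table.
    """

    records: list[SummaryRecord]
    trait_name: str = "trait"
    trait_type: str = "continuous"
    unit_note: str = ""
    audit: dict | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate snp_id in table {self.trait_name!r}: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SummaryRecord]:
        return iter(self.records)

    def by_id(self) -> dict[str, SummaryRecord]:
        return {r.snp_id: r for r in self.records}

    def with_records(self, records: Sequence[SummaryRecord]) -> "SummaryStatsTable":
        return SummaryStatsTable(
            records=list(records),
            trait_name=self.trait_name,
            trait_type=self.trait_type,
            unit_note=self.unit_note,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({c: getattr(r, c) for c in CANONICAL_COLUMNS})
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _detect_sep(path: Path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_column_map(path: str | Path) -> dict[str, str]:
    """Load a ``canonical field -> file column`` map from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        mapping = yaml.safe_load(text)
    else:
        mapping = json.loads(text)
    if not isinstance(mapping, Mapping):
        raise ValueError(f"column map in {path} is not a mapping")
    unknown = set(mapping) - set(CANONICAL_COLUMNS)
    if unknown:
        raise ValueError(f"unknown canonical fields in column map: {sorted(unknown)}")
    return dict(mapping)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "trait",
    trait_type: str = "continuous",
    unit_note: str = "",
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    Parameters
    ----------
    path
        TSV or CSV file (delimiter auto-detected from the header line).
    column_map
        Mapping from canonical field names (:data:`CANONICAL_COLUMNS`) to
        the file's column headers.  ``None`` means the file already uses
        canonical names.
    trait_name, trait_type, unit_note
        Trait metadata attached to the returned table.

    Rows violating a record invariant (non-positive SE, frequency outside
    [0, 1], identical alleles, unparseable numerics) are dropped and
    counted in ``table.audit``.  A missing mandatory column is a hard
    error, as is a numeric column that fails to parse in more than half
    of the rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    df.columns = [str(c) for c in df.columns]

    if column_map:
        column_map = dict(column_map)
    else:
        # canonical headers: map whatever optional columns the file carries
        column_map = {c: c for c in CANONICAL_COLUMNS if c in df.columns or c in MANDATORY_COLUMNS}

    missing_mandatory = [c for c in MANDATORY_COLUMNS if c not in column_map]
    if missing_mandatory:
        raise ValueError(f"column map lacks mandatory fields: {missing_mandatory}")

    absent = [col for col in column_map.values() if col not in df.columns]
    if absent:
        raise ValueError(f"mapped columns not found in {path.name}: {absent}")

    # project onto canonical names, keeping only mapped fields
    data = pd.DataFrame({canon: df[col] for canon, col in column_map.items()})
    n_input = len(data)

    for col in _NUMERIC_COLUMNS:
        if col in data.columns:
            coerced = pd.to_numeric(data[col], errors="coerce")
            if col in ("beta", "se") and n_input > 0:
                frac_bad = float(coerced.isna().mean())
                if frac_bad > 0.5:
                    raise ValueError(
                        f"column {column_map[col]!r} ({col}) unparseable in "
                        f"{frac_bad:.0%} of rows"
                    )
            data[col] = coerced

    records: list[SummaryRecord] = []
    reasons: dict[str, int] = {}

    def _get(row, name, cast=float):
        if name not in data.columns:
            return None
        v = row[name]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return cast(v)

    for row in data.itertuples(index=False):
        row_d = row._asdict()
        beta = _get(row_d, "beta")
        se = _get(row_d, "se")
        if beta is None or se is None:
            reasons["unparseable numeric"] = reasons.get("unparseable numeric", 0) + 1
            continue
        rec = SummaryRecord(
            snp_id=str(row_d["snp_id"]).strip(),
            effect_allele=str(row_d["effect_allele"]).strip().upper(),
            other_allele=str(row_d["other_allele"]).strip().upper(),
            beta=beta,
            se=se,
            chrom=str(row_d["chrom"]).strip() if _get(row_d, "chrom", str) is not None else None,
            pos=_get(row_d, "pos", lambda v: int(float(v))),
            eaf=_get(row_d, "eaf"),
            pval=_get(row_d, "pval"),
            n=_get(row_d, "n", lambda v: int(float(v))),
            n_cases=_get(row_d, "n_cases", lambda v: int(float(v))),
        )
        reason = rec.validate()
        if reason is not None:
            reasons[reason] = reasons.get(reason, 0) + 1
            continue
        records.append(rec)

    table = SummaryStatsTable(
        records=records, trait_name=trait_name, trait_type=trait_type, unit_note=unit_note
    )
    table.audit = {
        "path": str(path),
        "n_input": n_input,
        "n_kept": len(records),
        "n_dropped": n_input - len(records),
        "dropped_reasons": reasons,
    }
    return table


def write_sumstats(table: SummaryStatsTable, path: str | Path) -> None:
    """Write a table as canonical TSV (round-trips through read_sumstats)."""
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_report(
    rows: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write report rows (estimates, diagnostics, audits) to disk.

    Floats are written at full precision so a read-back reproduces the
    written values to at least 12 significant digits.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        df = pd.DataFrame(rows)
    if len(df) == 0:
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "csv":
        df.to_csv(path, sep=",", index=False, float_format="%.17g")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=_json_default)
    else:
        raise ValueError(f"unknown report format {format!r}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
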