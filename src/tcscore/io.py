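"""Reading, validating, normalizing and writing clonotype tables.

Clonotype tables are consumed in the AIRR Rearrangement TSV dialect
(columns ``junction_aa``, ``v_call``, ``j_call``, ``duplicate_count``) or a
minimal 4-column fallback (``cdr3_aa``, ``v_gene``, ``j_gene``, ``count``),
auto-detected from the header.  Clonotype identity is
``(v_gene, j_gene, CDR3 amino-acid sequence)``: allele suffixes (``*01``) are
truncated to gene level, non-productive junctions (stop ``*`` or frameshift
``_``, or any character outside the 20 standard amino acids) are dropped,
and duplicate keys are merged by summing counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyRepertoireError,
    RepertoireFormatError,
)

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: canonical column names of the two accepted dialects
AIRR_COLUMNS = ("junction_aa", "v_call", "j_call", "duplicate_count")
MINIMAL_COLUMNS = ("cdr3_aa", "v_gene", "j_gene", "count")

TISSUES = ("blood", "thyroid")
LABELS = ("GO", "GH", "GH_to_GO", "unlabeled")

KeyMode = Literal["vj_cdr3aa", "cdr3aa_only"]


@dataclass(frozen=True)
class Clonotype:
    """One unique TCR-beta clonotype with its abundance in a sample."""

    cdr3_aa: str
    v_call: str
    j_call: str
    count: int
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if not self.cdr3_aa or not set(self.cdr3_aa) <= STANDARD_AA:
            raise ValueError(f"invalid CDR3 amino-acid sequence: {self.cdr3_aa!r}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass
class RepertoireSample:
    """All clonotypes of one sample, with normalized frequencies."""

    sample_id: str
    clonotypes: list[Clonotype]
    tissue: str = "blood"
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ConfigurationError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.label not in LABELS:
            raise ConfigurationError(f"unknown label {self.label!r}; expected one of {LABELS}")

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes)

    def frequencies(self, mode: KeyMode = "vj_cdr3aa") -> dict[tuple, float]:
        """Mapping clonotype key -> frequency."""
        return {clonotype_key(c, mode): c.frequency for c in self.clonotypes}

    def normalized(self) -> "RepertoireSample":
        """Return a copy with frequencies recomputed from counts (idempotent)."""
        total = self.total_count
        if total == 0:
            raise EmptyRepertoireError(f"sample {self.sample_id} has no clonotypes")
        clonotypes = [replace(c, frequency=c.count / total) for c in self.clonotypes]
        return replace(self, clonotypes=clonotypes)


@dataclass
class CohortMetadata:
    """Per-sample label, tissue and follow-up table for a cohort run."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("sample_id", "label", "tissue", "followup_months", "go_event")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise RepertoireFormatError(f"metadata missing column(s): {', '.join(missing)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise RepertoireFormatError(f"duplicate sample_id in metadata: {dup}")

    def label_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise RepertoireFormatError(f"sample {sample_id} has no metadata row")
        return str(row["label"].iloc[0])


def gene_level(call: str) -> str:
    """Truncate an IMGT gene call to gene level: 'TRBV6-1*01' -> 'TRBV6-1'."""
    return call.split("*", 1)[0].strip()


def clonotype_key(c: Clonotype, mode: KeyMode = "vj_cdr3aa") -> tuple:
    """Deterministic identity key used for deduplication and overlap."""
    if mode == "vj_cdr3aa":
        return (c.v_call, c.j_call, c.cdr3_aa)
    if mode == "cdr3aa_only":
        return (c.cdr3_aa,)
    raise ConfigurationError(f"unknown clonotype key mode: {mode!r}")


def _detect_dialect(columns: Iterable[str]) -> dict[str, str]:
    cols = set(columns)
    if set(AIRR_COLUMNS) <= cols:
        return dict(zip(AIRR_COLUMNS, AIRR_COLUMNS))
    if set(MINIMAL_COLUMNS) <= cols:
        return dict(zip(AIRR_COLUMNS, MINIMAL_COLUMNS))
    # name the first missing AIRR column for the error message
    missing = [c for c in AIRR_COLUMNS if c not in cols]
    raise RepertoireFormatError(
        f"clonotype table missing required column(s): {', '.join(missing)} "
        f"(neither AIRR nor minimal 4-column dialect)"
    )


def read_airr(
    path: str | Path,
    dedup_mode: KeyMode = "vj_cdr3aa",
    sample_id: str | None = None,
    tissue: str = "blood",
    label: str = "unlabeled",
) -> RepertoireSample:
    """Read one clonotype table, filter non-productive rows, merge duplicates.

    Rows with a missing or ambiguous (comma-separated) V/J call, or a
    junction containing anything but the 20 standard amino acids, are
    dropped with a logged count.  Frequencies are computed from the merged
    counts.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap = _detect_dialect(df.columns)
    df = df.rename(columns={v: k for k, v in colmap.items() if v != k})

    n_in = len(df)
    counts = pd.to_numeric(df["duplicate_count"], errors="coerce")
    junction = df["junction_aa"].fillna("")
    v = df["v_call"].fillna("").map(gene_level)
    j = df["j_call"].fillna("").map(gene_level)
    productive = junction.map(lambda s: bool(s) and set(s) <= STANDARD_AA)
    ok = (
        productive
        & (v != "")
        & (j != "")
        & ~v.str.contains(",")
        & ~j.str.contains(",")
        & counts.notna()
        & (counts >= 1)
    )
    n_dropped = int(n_in - ok.sum())
    if n_dropped:
        logger.info("%s: dropped %d of %d rows (non-productive/ambiguous/invalid)", path.name, n_dropped, n_in)

    kept = pd.DataFrame(
        {
            "cdr3_aa": junction[ok],
            "v_call": v[ok],
            "j_call": j[ok],
            "count": counts[ok].astype(int),
        }
    )
    if kept.empty:
        raise EmptyRepertoireError(f"{path}: no productive clonotypes after filtering")

    key_cols = ["v_call", "j_call", "cdr3_aa"] if dedup_mode == "vj_cdr3aa" else ["cdr3_aa"]
    if dedup_mode not in ("vj_cdr3aa", "cdr3aa_only"):
        raise ConfigurationError(f"unknown dedup mode: {dedup_mode!r}")
    merged = (
        kept.groupby(key_cols, as_index=False)
        .agg(count=("count", "sum"), v_call=("v_call", "first"), j_call=("j_call", "first"))
        .sort_values(key_cols, kind="mergesort")
        .reset_index(drop=True)
    )
    total = int(merged["count"].sum())
    clonotypes = [
        Clonotype(
            cdr3_aa=r.cdr3_aa,
            v_call=r.v_call,
            j_call=r.j_call,
            count=int(r.count),
            frequency=int(r.count) / total,
        )
        for r in merged.itertuples()
    ]
    logger.info("%s: read %d clonotypes (total count %d)", path.name, len(clonotypes), total)
    return RepertoireSample(
        sample_id=sample_id or path.stem,
        clonotypes=clonotypes,
        tissue=tissue,
        label=label,
    )


def write_airr(sample: RepertoireSample, path: str | Path) -> Path:
    """Write a sample as AIRR Rearrangement TSV; round-trips through read_airr."""
    if not sample.clonotypes:
        raise EmptyRepertoireError(f"refusing to write empty repertoire {sample.sample_id}")
    path = Path(path)
    df = pd.DataFrame(
        {
            "junction_aa": [c.cdr3_aa for c in sample.clonotypes],
            "v_call": [c.v_call for c in sample.clonotypes],
            "j_call": [c.j_call for c in sample.clonotypes],
            "duplicate_count": [c.count for c in sample.clonotypes],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    logger.info("%s: wrote %d clonotypes", path.name, len(df))
    return path


def sample_from_counts(
    sample_id: str,
    records: Mapping[tuple[str, str, str], int] | Sequence[tuple[str, str, str, int]],
    tissue: str = "blood",
    label: str = "unlabeled",
) -> RepertoireSample:
    """Build a normalized sample from (v_call, j_call, cdr3_aa) -> count records."""
    if isinstance(records, Mapping):
        items = list(records.items())
    else:
        items = [((v, j, c), n) for v, j, c, n in records]
    if not items:
        raise EmptyRepertoireError(f"sample {sample_id} has no clonotypes")
    merged: dict[tuple[str, str, str], int] = {}
    for key, n in items:
        merged[key] = merged.get(key, 0) + int(n)
    clonotypes = [
        Clonotype(cdr3_aa=c, v_call=v, j_call=j, count=n)
        for (v, j, c), n in sorted(merged.items())
    ]
    return RepertoireSample(sample_id, clonotypes, tissue=tissue, label=label).normalized()


def read_metadata(path: str | Path) -> CohortMetadata:
    """Read the cohort metadata CSV (sample_id,label,tissue,followup_months,go_event)."""
    df = pd.read_csv(path)
    meta = CohortMetadata(df)
    logger.info("%s: read metadata for %d samples", Path(path).name, len(df))
    return meta


def write_metadata(meta: CohortMetadata, path: str | Path) -> Path:
    path = Path(path)
    meta.table.to_csv(path, index=False)
    return path
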