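"""Readers, writers, validation filters, and the isomiR-specific primer rule.

IsomiR tables are tab-delimited long-format files in the dialect produced
by merging per-sample isomiR reports from upstream quantifiers: columns
``MIRNA, SAMPLE, SEQUENCE, LEN_TRIM, LEN_TAIL, READS, RATIO`` (header
matching is case-insensitive; ``LEN_TAIL`` stores the tail *sequence*, its
length being the numeric tail length; an optional signed ``LEN_5P`` column
carries 5'-end variation, positive = nucleotides trimmed from the 5' end).

Validation mirrors the upstream read filters: read length 17-26 nt,
|5' distance| <= 3, |3' distance| <= 5, and a per-isomiR minimum of 10
reads.  Records failing any filter are dropped and counted in a
:class:`DroppedReport`; ratios are renormalized over retained records.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    CanonicalMiRNA,
    EndScoreMatrix,
    FormatError,
    IsomiRTable,
    MiRNACatalog,
    RECORD_COLUMNS,
    validate_metadata,
)

logger = logging.getLogger(__name__)

# column aliases (upper-cased) -> internal names
_COLUMN_ALIASES = {
    "MIRNA": "mirna_id",
    "MIRNA_ID": "mirna_id",
    "SAMPLE": "sample_id",
    "SAMPLE_ID": "sample_id",
    "SEQUENCE": "sequence",
    "LEN_TRIM": "len_trim",
    "LEN_TAIL": "tail_seq",
    "TAIL_SEQ": "tail_seq",
    "LEN_5P": "len_5p",
    "READS": "reads",
    "RATIO": "ratio",
}


@dataclass
class ValidationThresholds:
    """Record-level filters applied while reading isomiR tables."""

    min_read_len: int = 17
    max_read_len: int = 26
    max_dist5: int = 3
    max_dist3: int = 5
    min_reads: int = 10


@dataclass
class DroppedReport:
    """Counts of records dropped per validation reason."""

    unknown_mirna: int = 0
    read_length: int = 0
    dist5: int = 0
    dist3: int = 0
    min_reads: int = 0

    @property
    def total(self) -> int:
        return (
            self.unknown_mirna
            + self.read_length
            + self.dist5
            + self.dist3
            + self.min_reads
        )


# ---------------------------------------------------------------------------
# catalog i/o


def read_catalog(path: str | Path) -> MiRNACatalog:
    """Load a canonical miRNA catalog from FASTA or two-column TSV.

    FASTA headers are split on whitespace; the first token is the miRNA id.
    An arm suffix (``-3p``/``-5p``) on the id sets the arm field.
    """
    path = Path(path)
    catalog = MiRNACatalog()
    text = path.read_text()
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(str(path), "fasta"):
            catalog.add(_make_canonical(rec.id, str(rec.seq)))
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise FormatError("catalog TSV needs two columns: id, sequence")
        # tolerate a header row
        first = df.iloc[0, 1]
        if set(first.upper()) - set("ACGUT"):
            df = df.iloc[1:]
        for _, row in df.iterrows():
            catalog.add(_make_canonical(row.iloc[0], row.iloc[1]))
    return catalog


def _make_canonical(mirna_id: str, seq: str) -> CanonicalMiRNA:
    arm = "unknown"
    low = mirna_id.lower()
    if low.endswith("-3p"):
        arm = "3p"
    elif low.endswith("-5p"):
        arm = "5p"
    spike = "spike" in low
    return CanonicalMiRNA(mirna_id, seq, arm=arm, spikein=spike)


def write_catalog(catalog: MiRNACatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in catalog.values():
            fh.write(f">{m.mirna_id}\n{m.sequence}\n")


# ---------------------------------------------------------------------------
# metadata i/o


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, age_days, batch, sex, ...)."""
    md = pd.read_csv(path, sep="\t")
    md.columns = [c.strip().lower() for c in md.columns]
    if "sample_id" not in md.columns:
        raise FormatError("metadata is missing required column 'sample_id'")
    return validate_metadata(md)


# ---------------------------------------------------------------------------
# isomiR table i/o


def read_isomir_table(
    path: str | Path,
    catalog: MiRNACatalog,
    thresholds: ValidationThresholds | None = None,
) -> tuple[IsomiRTable, DroppedReport]:
    """Read, validate and normalize a long-format isomiR TSV.

    Returns the validated table and a report of dropped records.  If the
    RATIO column is absent (or records were dropped), ratios are
    (re)computed as reads / total reads within each (miRNA, sample) group
    over retained records.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"LEN_TAIL": str})
    raw.columns = [str(c).strip().upper() for c in raw.columns]
    rename = {c: _COLUMN_ALIASES[c] for c in raw.columns if c in _COLUMN_ALIASES}
    df = raw.rename(columns=rename)

    required = ["mirna_id", "sample_id", "reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"isomiR table missing required column(s): {missing}")
    if "len_trim" not in df.columns:
        raise FormatError(
            "isomiR table needs a LEN_TRIM column (sequence-only inference "
            "is not supported in this dialect)"
        )

    df["reads"] = pd.to_numeric(df["reads"], errors="raise")
    if (df["reads"] < 0).any():
        raise FormatError("negative read counts in isomiR table")
    df["reads"] = df["reads"].round().astype(int)
    df["len_trim"] = pd.to_numeric(df["len_trim"], errors="raise").astype(int)
    if (df["len_trim"] < 0).any():
        raise FormatError("negative LEN_TRIM in isomiR table")
    if "tail_seq" not in df.columns:
        df["tail_seq"] = ""
    df["tail_seq"] = (
        df["tail_seq"].fillna("").astype(str).str.strip().str.upper()
        .str.replace("-", "", regex=False).str.replace("T", "U", regex=False)
    )
    if "len_5p" not in df.columns:
        df["len_5p"] = 0
    df["len_5p"] = pd.to_numeric(df["len_5p"], errors="raise").fillna(0).astype(int)

    table, report = _validate_records(df, catalog, thresholds or ValidationThresholds())
    return table, report


def _validate_records(
    df: pd.DataFrame, catalog: MiRNACatalog, thr: ValidationThresholds
) -> tuple[IsomiRTable, DroppedReport]:
    report = DroppedReport()

    known = df["mirna_id"].isin(catalog.keys())
    report.unknown_mirna = int((~known).sum())
    if report.unknown_mirna:
        unknown_ids = sorted(df.loc[~known, "mirna_id"].unique())[:5]
        warnings.warn(
            f"dropping {report.unknown_mirna} records with unknown mirna_id "
            f"(e.g., {unknown_ids})",
            stacklevel=3,
        )
    df = df[known].copy()

    canon_len = df["mirna_id"].map({k: len(v) for k, v in catalog.items()})
    if (df["len_trim"] >= canon_len).any():
        raise FormatError("LEN_TRIM >= canonical length for some records")
    tail_len = df["tail_seq"].str.len()
    end_pos = tail_len - df["len_trim"]
    read_len = canon_len - df["len_5p"] - df["len_trim"] + tail_len

    ok_len = (read_len >= thr.min_read_len) & (read_len <= thr.max_read_len)
    ok_d5 = df["len_5p"].abs() <= thr.max_dist5
    ok_d3 = end_pos.abs() <= thr.max_dist3
    ok_reads = df["reads"] >= thr.min_reads

    report.read_length = int((~ok_len).sum())
    report.dist5 = int((ok_len & ~ok_d5).sum())
    report.dist3 = int((ok_len & ok_d5 & ~ok_d3).sum())
    report.min_reads = int((ok_len & ok_d5 & ok_d3 & ~ok_reads).sum())

    keep = ok_len & ok_d5 & ok_d3 & ok_reads
    df = df[keep].copy()
    if report.total:
        logger.info("dropped %d isomiR records during validation", report.total)

    # ratios are normalized over retained records
    totals = df.groupby(["mirna_id", "sample_id"])["reads"].transform("sum")
    df["ratio"] = df["reads"] / totals

    records = df[RECORD_COLUMNS].reset_index(drop=True)
    table = IsomiRTable(records=records, catalog=catalog)
    table.check_ratio_sums()
    return table, report


def write_isomir_table(table: IsomiRTable, path: str | Path) -> None:
    """Write an isomiR table back to the TSV dialect read by
    :func:`read_isomir_table` (round-trips all retained fields)."""
    out = table.records.rename(
        columns={
            "mirna_id": "MIRNA",
            "sample_id": "SAMPLE",
            "len_trim": "LEN_TRIM",
            "tail_seq": "LEN_TAIL",
            "len_5p": "LEN_5P",
            "reads": "READS",
            "ratio": "RATIO",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def merge_sample_tables(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Concatenate per-sample isomiR TSVs into one long-format frame,
    injecting the SAMPLE column from the mapping key."""
    frames = []
    for sample_id, p in paths.items():
        df = pd.read_csv(p, sep="\t", dtype={"LEN_TAIL": str})
        df.columns = [str(c).strip().upper() for c in df.columns]
        df["SAMPLE"] = sample_id
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# abundance filtering


def filter_by_rpm(
    table: IsomiRTable, threshold: float = 10.0, inclusive: bool = True
) -> tuple[IsomiRTable, list[str]]:
    """Keep miRNAs detected at a mean of >= `threshold` reads per million
    miRNA reads across samples.

    The RPM denominator is the per-sample total of endogenous miRNA reads
    (spike-in features in the catalog are excluded from the denominator
    but are themselves subject to the same filter).
    """
    rec = table.records
    if rec.empty:
        warnings.warn("filter_by_rpm called on an empty table", stacklevel=2)
        return IsomiRTable(rec.copy(), table.catalog, list(table.samples)), []

    spike = {k for k, v in table.catalog.items() if v.spikein}
    endo = rec[~rec["mirna_id"].isin(spike)]
    denom = endo.groupby("sample_id")["reads"].sum()

    per = rec.groupby(["mirna_id", "sample_id"])["reads"].sum().unstack(fill_value=0)
    per = per.reindex(columns=table.samples, fill_value=0)
    rpm = per.div(denom.reindex(per.columns), axis=1) * 1e6
    mean_rpm = rpm.mean(axis=1)
    if inclusive:
        retained = mean_rpm[mean_rpm >= threshold].index.tolist()
    else:
        retained = mean_rpm[mean_rpm > threshold].index.tolist()
    retained = sorted(retained)
    logger.info(
        "RPM filter (mean %s %g): retained %d / %d miRNAs",
        ">=" if inclusive else ">", threshold, len(retained), per.shape[0],
    )
    sub = rec[rec["mirna_id"].isin(retained)].reset_index(drop=True)
    return IsomiRTable(sub, table.catalog, list(table.samples)), retained


# ---------------------------------------------------------------------------
# technical replicates


def average_replicate_scores(
    scores: EndScoreMatrix, metadata: pd.DataFrame
) -> tuple[EndScoreMatrix, pd.DataFrame]:
    """Collapse technical replicates to their per-miRNA mean end score.

    Samples sharing a non-empty ``replicate_group`` collapse into a single
    column (named after the group); metadata collapses to one row, which
    must be identical across replicates for every covariate.
    """
    md = validate_metadata(metadata)
    if "replicate_group" not in md.columns:
        return scores, md
    md = md.loc[[s for s in scores.sample_order if s in md.index]]

    group = md["replicate_group"].astype("string")
    has_group = group.notna() & (group != "")
    new_cols: dict[str, pd.Series] = {}
    new_meta_rows = []
    consumed: set[str] = set()
    for s in scores.sample_order:
        if s in consumed:
            continue
        if s in md.index and has_group.get(s, False):
            g = group[s]
            members = [m for m in scores.sample_order if group.get(m) == g]
            covs = md.loc[members].drop(columns=["replicate_group"])
            if covs["age_days"].nunique() > 1:
                raise ValueError(
                    f"replicate_group {g!r} spans different ages: "
                    f"{sorted(covs['age_days'].unique())}"
                )
            new_cols[g] = scores.scores[members].mean(axis=1)
            row = covs.iloc[0].copy()
            row.name = g
            new_meta_rows.append(row)
            consumed.update(members)
        else:
            new_cols[s] = scores.scores[s]
            if s in md.index:
                row = md.loc[s].drop(labels=["replicate_group"])
                new_meta_rows.append(row)
            consumed.add(s)
    collapsed = pd.DataFrame(new_cols)
    new_md = pd.DataFrame(new_meta_rows)
    new_md.index.name = "sample_id"
    return EndScoreMatrix(collapsed, mode=scores.mode), new_md


# ---------------------------------------------------------------------------
# isomiR-specific RT-qPCR primer rule


def design_isomir_primer(
    canonical: CanonicalMiRNA, n_trim: int, pad_a: bool = True
) -> str:
    """Forward-primer sequence for a 3'-trimmed isomiR.

    The primer is the DNA transcript (U->T) of the canonical sequence with
    its last ``n_trim`` nucleotides removed; with ``pad_a`` the removed
    positions are replaced by terminal ``A`` nucleotides matching the
    poly(A) tail added before reverse transcription, which excludes longer
    isomiRs from amplification.
    """
    if n_trim < 0:
        raise ValueError("n_trim must be >= 0")
    if n_trim >= len(canonical):
        raise ValueError(
            f"n_trim {n_trim} >= canonical length {len(canonical)}"
        )
    if n_trim > 2:
        warnings.warn(
            "primers for trims beyond 2 nt are untested territory", stacklevel=2
        )
    dna = canonical.sequence.replace("U", "T")
    core = dna[: len(dna) - n_trim] if n_trim else dna
    return core + "A" * n_trim if pad_a else core
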