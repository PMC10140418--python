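"""Core domain types shared across the package.

The unit of analysis is the isomiR observation: one (miRNA, sample) row
carrying the 3' trim length, the 3' tail sequence appended after trimming,
the read count, and the within-miRNA frequency (``ratio``).  The signed
3' end position of an isomiR relative to the canonical terminus is
``len(tail) - len_trim``: negative means the 3' end is shorter than the
canonical miRBase form, positive means it is extended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

RNA_ALPHABET = frozenset("ACGU")
ARMS = ("3p", "5p", "unknown")

#: canonical mature miRNA length bounds (nucleotides)
MIN_MIRNA_LEN = 17
MAX_MIRNA_LEN = 26

#: columns of the long-format isomiR records frame
RECORD_COLUMNS = [
    "mirna_id",
    "sample_id",
    "len_trim",
    "tail_seq",
    "len_5p",
    "reads",
    "ratio",
]

END_SCORE_MODES = ("total", "trim", "tail_A", "tail_C", "tail_G", "tail_U")
END_CLASSES = ("shortened", "extended", "ns")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass(frozen=True)
class CanonicalMiRNA:
    """A canonical (miRBase reference) mature miRNA sequence."""

    mirna_id: str
    sequence: str
    arm: str = "unknown"
    spikein: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"{self.mirna_id}: empty sequence")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.mirna_id}: non-RNA characters {sorted(bad)}")
        if not MIN_MIRNA_LEN <= len(seq) <= MAX_MIRNA_LEN:
            raise ValueError(
                f"{self.mirna_id}: length {len(seq)} outside "
                f"[{MIN_MIRNA_LEN}, {MAX_MIRNA_LEN}]"
            )
        if self.arm not in ARMS:
            raise ValueError(f"{self.mirna_id}: arm must be one of {ARMS}")

    def __len__(self) -> int:
        return len(self.sequence)


class MiRNACatalog(Mapping[str, CanonicalMiRNA]):
    """Mapping of miRNA id to its canonical sequence record."""

    def __init__(self, mirnas: Iterable[CanonicalMiRNA] = ()) -> None:
        self._mirnas: dict[str, CanonicalMiRNA] = {}
        for m in mirnas:
            self.add(m)

    def add(self, mirna: CanonicalMiRNA) -> None:
        if mirna.mirna_id in self._mirnas:
            raise ValueError(f"duplicate mirna_id {mirna.mirna_id!r} in catalog")
        self._mirnas[mirna.mirna_id] = mirna

    def __getitem__(self, key: str) -> CanonicalMiRNA:
        return self._mirnas[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._mirnas)

    def __len__(self) -> int:
        return len(self._mirnas)

    @property
    def ids(self) -> list[str]:
        return list(self._mirnas)

    def lengths(self) -> pd.Series:
        return pd.Series({k: len(v) for k, v in self._mirnas.items()}, dtype=int)


@dataclass
class IsomiRTable:
    """Validated long-format isomiR observations plus their catalog.

    ``records`` holds one row per isomiR x sample with the columns in
    :data:`RECORD_COLUMNS`.  Within each (mirna_id, sample_id) group the
    ``ratio`` column sums to 1.
    """

    records: pd.DataFrame
    catalog: MiRNACatalog
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records frame missing columns {missing}")
        if not self.samples:
            self.samples = sorted(self.records["sample_id"].unique().tolist())

    @property
    def mirna_ids(self) -> list[str]:
        return sorted(self.records["mirna_id"].unique().tolist())

    def end_positions(self) -> pd.Series:
        """Signed 3' end position (tail length minus trim length) per record."""
        return self.records["tail_seq"].str.len() - self.records["len_trim"]

    def check_ratio_sums(self, tol: float = 1e-6) -> None:
        sums = self.records.groupby(["mirna_id", "sample_id"])["ratio"].sum()
        bad = sums[(sums - 1.0).abs() > tol]
        if len(bad):
            raise ValueError(
                f"ratio does not sum to 1 within {len(bad)} (miRNA, sample) "
                f"groups; first: {bad.index[0]} -> {bad.iloc[0]:.8f}"
            )


def end_position(record) -> int:
    """3' end position of one isomiR record: ``len(tail_seq) - len_trim``."""
    return len(record["tail_seq"]) - int(record["len_trim"])


@dataclass
class EndScoreMatrix:
    """miRNA x sample matrix of 3' end scores (units: nucleotides).

    ``mode`` selects what the score weighs: the signed end position
    (``total``), the trim length (``trim``), or the per-nucleotide tail
    count (``tail_A`` .. ``tail_U``).
    """

    scores: pd.DataFrame  # index: mirna_id, columns: sample_id
    mode: str = "total"

    def __post_init__(self) -> None:
        if self.mode not in END_SCORE_MODES:
            raise ValueError(f"mode must be one of {END_SCORE_MODES}")

    @property
    def sample_order(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class ExpressionMatrix:
    """Feature x sample count/intensity matrix with per-feature classes.

    ``feature_class`` assigns each feature to one of
    {endogenous_miRNA, mRNA, other_ncRNA, spikein_small, spikein_large,
    protein}.  ``raw_totals`` (total raw counts per feature) survives
    normalization so low-count filtering can act on raw evidence.
    """

    counts: pd.DataFrame  # index: feature_id, columns: sample_id
    feature_class: pd.Series
    normalized: bool = False
    size_factors: pd.Series | None = None
    raw_totals: pd.Series | None = None

    FEATURE_CLASSES = (
        "endogenous_miRNA",
        "mRNA",
        "other_ncRNA",
        "spikein_small",
        "spikein_large",
        "protein",
    )

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("expression matrix contains negative values")
        self.feature_class = self.feature_class.reindex(self.counts.index)
        if self.feature_class.isna().any():
            bad = self.feature_class[self.feature_class.isna()].index[:5].tolist()
            raise ValueError(f"features without a class: {bad}")
        unknown = set(self.feature_class.unique()) - set(self.FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes {sorted(unknown)}")

    def subset_class(self, *classes: str) -> pd.DataFrame:
        mask = self.feature_class.isin(classes)
        return self.counts.loc[mask.values]


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check and canonicalize a sample metadata frame.

    Requires unique ``sample_id`` and positive ``age_days``; returns a copy
    indexed by sample_id.
    """
    md = metadata.copy()
    if "sample_id" in md.columns:
        md = md.set_index("sample_id")
    if md.index.duplicated().any():
        dups = md.index[md.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample_ids in metadata: {dups}")
    if "age_days" not in md.columns:
        raise ValueError("metadata must contain an 'age_days' column")
    ages = pd.to_numeric(md["age_days"], errors="raise")
    if (ages <= 0).any() or not np.isfinite(ages).all():
        raise ValueError("age_days must be positive and finite")
    md["age_days"] = ages.astype(float)
    return md
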