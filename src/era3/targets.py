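"""miRNA:target correlation analysis stratified by 3'-end class.

Predicted interactions from several target databases are filtered to
pairs supported by at least two tools, restricted to abundant miRNAs and
detected targets, and each surviving pair gets a Pearson correlation
across shared samples.  Correlations are then stratified by the miRNA's
3'-end class (shortened / extended / ns, from the age regression) and
the target's differential-expression direction or cluster, and the class
distributions of per-miRNA DE estimates and target counts are compared
with Kruskal-Wallis plus pairwise Wilcoxon rank-sum (Holm-adjusted)
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import END_CLASSES, ExpressionMatrix

CORRELATION_COLUMNS = [
    "mirna_id",
    "target_id",
    "r",
    "p",
    "n",
    "mirna_class",
    "target_direction",
    "target_cluster",
]


@dataclass
class InteractionSet:
    """Unique (miRNA, target) pairs with their supporting source tools."""

    pairs: pd.DataFrame  # columns: mirna_id, target_id, sources (frozenset),
    #                       support_count

    def __post_init__(self) -> None:
        df = self.pairs
        if df.duplicated(subset=["mirna_id", "target_id"]).any():
            raise ValueError("duplicate (mirna, target) pairs in interaction set")
        if not (df["support_count"] == df["sources"].map(len)).all():
            raise ValueError("support_count inconsistent with sources")

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "InteractionSet":
        """Build from long format (one row per mirna_id, target_id, source)."""
        grouped = (
            long.groupby(["mirna_id", "target_id"])["source"]
            .agg(lambda s: frozenset(s))
            .reset_index()
            .rename(columns={"source": "sources"})
        )
        grouped["support_count"] = grouped["sources"].map(len)
        return cls(grouped)


def read_interactions(path: str | Path) -> InteractionSet:
    """Read a long-format interaction TSV: mirna_id, target_id, source."""
    long = pd.read_csv(path, sep="\t")
    long.columns = [c.strip().lower() for c in long.columns]
    required = {"mirna_id", "target_id", "source"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"interaction table missing columns {sorted(missing)}")
    return InteractionSet.from_long(long)


def filter_interactions(
    raw: InteractionSet,
    min_support: int = 2,
    mirnas: list[str] | None = None,
    targets: list[str] | None = None,
) -> InteractionSet:
    """Keep pairs supported by >= ``min_support`` tools, optionally
    restricted to abundant miRNAs and detected targets."""
    df = raw.pairs
    df = df[df["support_count"] >= min_support]
    if mirnas is not None:
        df = df[df["mirna_id"].isin(set(mirnas))]
    if targets is not None:
        df = df[df["target_id"].isin(set(targets))]
    if df.empty:
        warnings.warn("no interactions survive filtering", stacklevel=2)
    return InteractionSet(df.reset_index(drop=True))


def correlate_pairs(
    interactions: InteractionSet,
    mirna_expr: ExpressionMatrix,
    target_expr: ExpressionMatrix,
    era_results: pd.DataFrame | None = None,
    de_results: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pearson r (two-sided p) per interaction pair over shared samples.

    Records are annotated with the miRNA's 3'-end class and the target's
    DE direction/cluster when those result frames are supplied.
    Zero-variance series yield r = NaN (kept in the frame, excluded from
    summaries).
    """
    shared = [s for s in mirna_expr.counts.columns if s in target_expr.counts.columns]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples for correlation")

    m_expr = mirna_expr.counts[shared]
    t_expr = target_expr.counts[shared]
    df = interactions.pairs
    df = df[
        df["mirna_id"].isin(m_expr.index) & df["target_id"].isin(t_expr.index)
    ].reset_index(drop=True)

    # standardize once, correlate via dot products
    def _standardize(mat: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        x = mat.to_numpy(float)
        x = x - x.mean(axis=1, keepdims=True)
        sd = np.sqrt((x**2).sum(axis=1))
        return x, sd

    mx, msd = _standardize(m_expr)
    tx, tsd = _standardize(t_expr)
    m_ix = pd.Index(m_expr.index).get_indexer(df["mirna_id"])
    t_ix = pd.Index(t_expr.index).get_indexer(df["target_id"])
    n = len(shared)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.einsum("ij,ij->i", mx[m_ix], tx[t_ix]) / (msd[m_ix] * tsd[t_ix])
    r = np.where((msd[m_ix] == 0) | (tsd[t_ix] == 0), np.nan, np.clip(r, -1, 1))
    n_na = int(np.isnan(r).sum())
    if n_na:
        warnings.warn(
            f"{n_na} pairs have zero-variance series; r set to NaN", stacklevel=2
        )
    # two-sided p via the exact t transform of Pearson r
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t_stat), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)

    out = pd.DataFrame(
        {
            "mirna_id": df["mirna_id"],
            "target_id": df["target_id"],
            "r": r,
            "p": p,
            "n": n,
        }
    )
    if era_results is not None:
        cls = era_results.set_index("mirna_id")["class"]
        out["mirna_class"] = out["mirna_id"].map(cls).fillna("ns")
    else:
        out["mirna_class"] = "ns"
    if de_results is not None:
        de_ix = de_results.set_index("feature_id")
        out["target_direction"] = out["target_id"].map(de_ix["direction"]).fillna("ns")
        out["target_cluster"] = out["target_id"].map(de_ix["cluster"])
    else:
        out["target_direction"] = "ns"
        out["target_cluster"] = pd.array([pd.NA] * len(out), dtype="Int64")
    return out


@dataclass
class StratifiedCorrelations:
    histogram: pd.DataFrame  # panel (target_direction), r_bin, mirna_class, count
    class_frequency: pd.DataFrame  # per panel: relative frequency of each class
    flagged_down_negative: list[str]  # target ids: DE down & r < lower cutoff
    flagged_up_positive: list[str]  # target ids: DE up & r > upper cutoff
    r_cutoffs: tuple[float, float]


def stratify_correlations(
    records: pd.DataFrame,
    r_cutoffs: tuple[float, float] = (-0.5, 0.5),
    bin_width: float = 0.1,
) -> StratifiedCorrelations:
    """Histogram correlations by target DE direction, colored by miRNA
    3'-end class, and export the extreme-correlation gene sets.

    The flagged sets — targets that decrease with age and correlate below
    the lower cutoff with a shortened miRNA, and targets that increase
    and correlate above the upper cutoff — are the inputs handed to
    external enrichment tools.
    """
    lower, upper = r_cutoffs
    if lower >= upper:
        raise ValueError("r_cutoffs must be (lower, upper) with lower < upper")
    rec = records.dropna(subset=["r"]).copy()
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 10)
    rec["r_bin"] = pd.cut(rec["r"], bins=edges, include_lowest=True)

    hist = (
        rec.groupby(["target_direction", "r_bin", "mirna_class"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    freq = (
        rec.groupby("target_direction")["mirna_class"]
        .value_counts(normalize=True)
        .rename("relative_frequency")
        .reset_index()
    )
    short = rec[rec["mirna_class"] == "shortened"]
    flagged_down = sorted(
        short.loc[
            (short["target_direction"] == "down") & (short["r"] < lower), "target_id"
        ].unique()
    )
    flagged_up = sorted(
        short.loc[
            (short["target_direction"] == "up") & (short["r"] > upper), "target_id"
        ].unique()
    )
    return StratifiedCorrelations(
        histogram=hist,
        class_frequency=freq,
        flagged_down_negative=flagged_down,
        flagged_up_positive=flagged_up,
        r_cutoffs=r_cutoffs,
    )


# ---------------------------------------------------------------------------
# class-level comparisons


def _kruskal_pairwise(values: pd.Series, classes: pd.Series) -> dict:
    """Kruskal-Wallis across classes plus Holm-adjusted pairwise
    Wilcoxon rank-sum tests; classes with <2 members are excluded."""
    groups = {}
    for cls in classes.unique():
        v = values[classes == cls].dropna()
        if len(v) >= 2:
            groups[cls] = v.to_numpy(float)
        else:
            warnings.warn(f"class {cls!r} has <2 members; excluded", stacklevel=3)
    if len(groups) < 2:
        raise ValueError("need >=2 classes with >=2 members")
    kw_stat, kw_p = stats.kruskal(*groups.values())
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append({"class_a": a, "class_b": b, "p_raw": res.pvalue})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["p_holm"] = multipletests(pairwise["p_raw"], method="holm")[1]
    return {
        "kruskal_stat": float(kw_stat),
        "kruskal_p": float(kw_p),
        "pairwise": pairwise,
        "group_sizes": {k: len(v) for k, v in groups.items()},
    }


def class_comparison_stats(
    era_results: pd.DataFrame,
    de_results: pd.DataFrame,
    interactions: InteractionSet,
    detected_targets: list[str] | None = None,
) -> dict[str, dict]:
    """Compare (a) the per-miRNA DE estimate and (b) the per-miRNA count
    of detected predicted targets across 3'-end classes."""
    era = era_results.set_index("mirna_id")
    classes = era["class"]

    de_est = de_results.set_index("feature_id")["estimate_age"]
    est = de_est.reindex(era.index)
    keep = est.notna()
    out: dict[str, dict] = {}
    out["de_estimate"] = _kruskal_pairwise(est[keep], classes[keep])

    pairs = interactions.pairs
    if detected_targets is not None:
        pairs = pairs[pairs["target_id"].isin(set(detected_targets))]
    counts = (
        pairs.groupby("mirna_id")["target_id"].nunique().reindex(era.index).fillna(0)
    )
    out["target_count"] = _kruskal_pairwise(counts, classes)
    return out
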