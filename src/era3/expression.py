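"""Spike-in-anchored abundance trends, normalization, age-trend DE, and
expression-pattern clustering.

The endogenous-to-spike-in ratio regression asks whether *total* miRNA
output changes with age: per sample, total endogenous miRNA reads are
divided by total small-spike-in reads (spike-ins enter every sample at
constant expectation, so the ratio cancels sequencing depth), and the
ratio is regressed on age plus nuisance covariates.

Differential expression with age uses a Gaussian nested-model F test on
log2(normalized count + 0.5): the full model (covariates + age) is
compared against the reduced model (covariates only), a deliberate
simplification of a negative-binomial likelihood-ratio test that keeps
the same output contract (estimate, FDR, direction) so an external
NB-based run can be substituted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .era import EraModelSpec, build_design, ols_fit
from .model import ExpressionMatrix, validate_metadata

logger = logging.getLogger(__name__)

DE_COLUMNS = ["feature_id", "estimate_age", "p", "fdr", "direction", "cluster"]

#: human lifespan bins: (upper bound in years, exclusive), label
AGE_BINS_YEARS = [
    (1, "infant"),
    (13, "child"),
    (19, "adolescent"),
    (30, "young adult"),
    (65, "adult"),
    (np.inf, "elderly"),
]
DAYS_PER_YEAR = 365.0


# ---------------------------------------------------------------------------
# matrix i/o


def read_expression_matrix(
    counts_path, classes_path=None, default_class: str = "mRNA"
) -> ExpressionMatrix:
    """Read a features x samples TSV plus an optional feature-class sidecar
    TSV (feature_id, feature_class)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if classes_path is not None:
        cls = pd.read_csv(classes_path, sep="\t", index_col=0).iloc[:, 0]
    else:
        cls = pd.Series(default_class, index=counts.index)
    return ExpressionMatrix(counts=counts, feature_class=cls)


def write_expression_matrix(matrix: ExpressionMatrix, counts_path, classes_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t")
    matrix.feature_class.rename("feature_class").to_csv(classes_path, sep="\t")


# ---------------------------------------------------------------------------
# spike-in anchored trend


@dataclass
class SpikeinTrend:
    ratios: pd.Series  # per-sample endogenous / spike-in ratio
    estimate_age: float
    p_age: float
    adj_r2: float
    coefficients: pd.Series


def spikein_ratio_trend(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    spec: EraModelSpec | None = None,
) -> SpikeinTrend:
    """Regress the per-sample endogenous-miRNA / small-spike-in read ratio
    on age + covariates.  Recovers global gains or losses in total miRNA
    output that per-feature normalization would cancel."""
    spec = spec or EraModelSpec()
    endo = matrix.subset_class("endogenous_miRNA")
    spike = matrix.subset_class("spikein_small")
    if endo.empty or spike.empty:
        raise ValueError("need >=1 endogenous_miRNA and >=1 spikein_small feature")
    spike_tot = spike.sum(axis=0)
    zero = spike_tot[spike_tot == 0]
    if len(zero):
        raise ValueError(f"zero spike-in total in sample(s): {list(zero.index)}")
    ratios = endo.sum(axis=0) / spike_tot

    md = validate_metadata(metadata)
    samples = list(ratios.index)
    X, names, age_ix = build_design(md, spec, samples)
    fit = ols_fit(X, ratios.to_numpy(float)[:, None])
    n, p = X.shape
    tss = float(((ratios - ratios.mean()) ** 2).sum())
    rss = float(fit["rss"][0])
    adj_r2 = 1.0 - (rss / (n - p)) / (tss / (n - 1)) if tss > 0 else np.nan
    return SpikeinTrend(
        ratios=ratios,
        estimate_age=float(fit["beta"][age_ix, 0]),
        p_age=float(fit["p"][age_ix, 0]),
        adj_r2=adj_r2,
        coefficients=pd.Series(fit["beta"][:, 0], index=names),
    )


# ---------------------------------------------------------------------------
# normalization


def normalize_counts(
    matrix: ExpressionMatrix, method: str = "median_of_ratios"
) -> ExpressionMatrix:
    """Normalize a count matrix.

    ``median_of_ratios``: per-sample size factor = median over reference
    features (those with all-positive counts, hence a positive geometric
    mean) of count / geometric mean, computed on the combined
    endogenous + spike-in matrix; counts are divided by the factor.
    ``rpm``: per-million scaling, each feature scaled by the per-sample
    total of its own feature class.
    """
    counts = matrix.counts
    if method == "median_of_ratios":
        if counts.shape[1] < 2:
            raise ValueError("median_of_ratios needs >=2 samples")
        log_counts = np.log(counts.where(counts > 0))
        log_geomean = log_counts.mean(axis=1)
        ref = np.isfinite(log_geomean) & counts.gt(0).all(axis=1)
        if not ref.any():
            raise ValueError(
                "no reference features (every feature contains a zero); "
                "consider method='rpm'"
            )
        log_ratios = log_counts.loc[ref].sub(log_geomean[ref], axis=0)
        size_factors = np.exp(log_ratios.median(axis=0))
        normalized = counts.div(size_factors, axis=1)
    elif method == "rpm":
        normalized = counts.copy().astype(float)
        for cls in matrix.feature_class.unique():
            mask = (matrix.feature_class == cls).values
            tot = counts.loc[mask].sum(axis=0)
            tot = tot.replace(0, np.nan)
            normalized.loc[mask] = counts.loc[mask].div(tot, axis=1) * 1e6
        normalized = normalized.fillna(0.0)
        size_factors = None
    else:
        raise ValueError("method must be 'median_of_ratios' or 'rpm'")
    return ExpressionMatrix(
        counts=normalized,
        feature_class=matrix.feature_class,
        normalized=True,
        size_factors=size_factors,
        raw_totals=counts.sum(axis=1),
    )


# ---------------------------------------------------------------------------
# age-trend differential expression


def de_trend(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    spec: EraModelSpec | None = None,
    min_total: int = 10,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature age-trend test: full vs covariates-only model on
    log2(normalized + pseudocount), nested-model F test, BH FDR.

    Features with fewer than ``min_total`` total *raw* counts are removed
    before testing.  ``direction`` is the sign of the age coefficient at
    FDR < alpha, else ``ns``.
    """
    spec = spec or EraModelSpec()
    if not matrix.normalized:
        warnings.warn("de_trend called on an unnormalized matrix", stacklevel=2)
    totals = (
        matrix.raw_totals
        if matrix.raw_totals is not None
        else matrix.counts.sum(axis=1)
    )
    keep = totals >= min_total
    counts = matrix.counts.loc[keep.values]
    if counts.empty:
        return pd.DataFrame(columns=DE_COLUMNS)
    logger.info("de_trend: %d / %d features pass the raw-count filter",
                counts.shape[0], matrix.counts.shape[0])

    md = validate_metadata(metadata)
    samples = list(counts.columns)
    X_full, _, age_ix = build_design(md, spec, samples)
    X_red = np.delete(X_full, age_ix, axis=1)

    Y = np.log2(counts.T.to_numpy(float) + pseudocount)
    fit_full = ols_fit(X_full, Y)
    beta_full, _, _, _ = np.linalg.lstsq(X_red, Y, rcond=None)
    resid_red = Y - X_red @ beta_full
    rss_red = np.einsum("ij,ij->j", resid_red, resid_red)
    rss_full = fit_full["rss"]
    df_num = 1  # one age term
    df_den = fit_full["dof"]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    F = np.clip(np.nan_to_num(F, nan=0.0, posinf=np.inf), 0.0, None)
    p = stats.f.sf(F, df_num, df_den)
    p = np.where(np.isfinite(F), p, 0.0)
    zero_var = Y.std(axis=0, ddof=0) == 0
    est = fit_full["beta"][age_ix].copy()
    est[zero_var] = 0.0
    p[zero_var] = 1.0

    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    direction = np.where(
        (fdr < spec.alpha) & (est > 0),
        "up",
        np.where((fdr < spec.alpha) & (est < 0), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "feature_id": counts.index,
            "estimate_age": est,
            "p": p,
            "fdr": fdr,
            "direction": direction,
            "cluster": pd.array([pd.NA] * len(counts), dtype="Int64"),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression-pattern clustering


def cluster_patterns(
    de: pd.DataFrame,
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    k: int | str = "auto",
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster significant features by their z-scored per-age-group mean
    log profiles (distance = 1 - Pearson r, average linkage).

    ``k='auto'`` picks the cut (2..8) maximizing the mean silhouette on
    the correlation distance.  Returns (labels, per-cluster mean
    z-profiles); on <2 significant features returns empty results with a
    warning.  Age is treated as categorical here.
    """
    sig = de.loc[de["fdr"] < alpha, "feature_id"]
    sig = [f for f in sig if f in matrix.counts.index]
    if len(sig) < 2:
        warnings.warn("fewer than 2 significant features; nothing to cluster",
                      stacklevel=2)
        return pd.Series(dtype="Int64"), pd.DataFrame()

    md = validate_metadata(metadata)
    log_expr = np.log2(matrix.counts.loc[sig] + pseudocount)
    ages = md.loc[log_expr.columns, "age_days"]
    group_means = log_expr.T.groupby(ages.values).mean().T  # features x age groups
    group_means = group_means[sorted(group_means.columns)]

    mu = group_means.mean(axis=1)
    sd = group_means.std(axis=1, ddof=0).replace(0, 1.0)
    z = group_means.sub(mu, axis=0).div(sd, axis=0)

    dist = pdist(z.values, metric="correlation")
    dist = np.clip(np.nan_to_num(dist, nan=1.0), 0.0, None)
    Z = linkage(dist, method="average")

    if k == "auto":
        best_k, best_score = 2, -np.inf
        square = squareform(dist)
        for kk in range(2, min(8, len(sig) - 1) + 1):
            labels = fcluster(Z, kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(square, labels, metric="precomputed")
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    labels = fcluster(Z, int(k), criterion="maxclust")
    label_series = pd.Series(labels, index=z.index, name="cluster", dtype="Int64")
    profiles = z.groupby(label_series).mean()
    profiles.index.name = "cluster"
    return label_series, profiles


# ---------------------------------------------------------------------------
# helpers


def bin_human_ages(metadata: pd.DataFrame) -> pd.Series:
    """Map age_days to the six human lifespan groups (infant < 1 y,
    child 1-12, adolescent 13-18, young adult 19-29, adult 30-64,
    elderly 65+); boundaries inclusive on the lower edge."""
    md = validate_metadata(metadata)
    years = md["age_days"] / DAYS_PER_YEAR
    labels = []
    for y in years:
        for upper, label in AGE_BINS_YEARS:
            if y < upper:
                labels.append(label)
                break
    return pd.Series(labels, index=md.index, name="age_group")


def de_by_abundance(
    de: pd.DataFrame, matrix: ExpressionMatrix, n_bins: int = 5
) -> pd.DataFrame:
    """Fraction of up/down/ns calls per mean-abundance quantile bin."""
    shared = de.set_index("feature_id").join(
        matrix.counts.mean(axis=1).rename("mean_abundance"), how="inner"
    )
    shared["abundance_bin"] = pd.qcut(
        shared["mean_abundance"].rank(method="first"), n_bins, labels=False
    ) + 1
    freq = (
        shared.groupby("abundance_bin")["direction"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    for col in ("up", "down", "ns"):
        if col not in freq.columns:
            freq[col] = 0.0
    return freq[["up", "down", "ns"]]
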