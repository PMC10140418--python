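"""3' End Regression Analysis (3'ERA).

For each miRNA and sample, the 3' end score is the frequency-weighted sum
over its isomiRs of a per-isomiR quantity: the signed end position
(``total`` mode), the trim length (``trim``), or the count of a given
nucleotide in the 3' tail (``tail_A`` .. ``tail_U``).  Each miRNA's score
is then regressed on age plus nuisance covariates by ordinary least
squares; the age coefficient, its two-sided p-value, and the
Benjamini-Hochberg FDR across miRNAs classify every miRNA as
``shortened`` (negative estimate, FDR < alpha), ``extended`` (positive
estimate, FDR < alpha), or ``ns``.

Because the end position equals the tail length minus the trim length,
and OLS is linear in the response, the total-score age coefficient
decomposes exactly as

    beta_total = beta_tail_A + beta_tail_C + beta_tail_G + beta_tail_U - beta_trim

per miRNA whenever all modes share the same design and sample set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .model import END_SCORE_MODES, EndScoreMatrix, IsomiRTable, validate_metadata

logger = logging.getLogger(__name__)

DECOMPOSITION_MODES = ("trim", "tail_A", "tail_C", "tail_G", "tail_U")

RESULT_COLUMNS = [
    "mirna_id",
    "estimate_age",
    "p_age",
    "fdr",
    "n_samples",
    "class",
    "mode",
]


@dataclass
class EraModelSpec:
    """Regression model for 3'ERA: age term plus nuisance covariates.

    ``age_term`` is ``linear`` (age in days) or ``log`` (natural log of
    age in days, for wide age ranges).  ``covariates`` name metadata
    columns; non-numeric ones get treatment coding with the first level
    (by sort order) as reference.
    """

    age_term: str = "linear"
    covariates: list[str] = field(default_factory=list)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.age_term not in ("linear", "log"):
            raise ValueError("age_term must be 'linear' or 'log'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# end scores


def compute_end_scores(table: IsomiRTable, mode: str = "total") -> EndScoreMatrix:
    """Per-miRNA, per-sample frequency-weighted 3' end score.

    ``total``: sum_i ratio_i * (len(tail_i) - len_trim_i);
    ``trim``:  sum_i ratio_i * len_trim_i;
    ``tail_N``: sum_i ratio_i * (occurrences of N in tail_i).

    miRNAs absent from a sample yield missing (NaN) cells; downstream
    regression drops such miRNAs unless told otherwise.
    """
    if mode not in END_SCORE_MODES:
        raise ValueError(f"mode must be one of {END_SCORE_MODES}")
    rec = table.records
    if mode == "total":
        value = rec["tail_seq"].str.len() - rec["len_trim"]
    elif mode == "trim":
        value = rec["len_trim"].astype(float)
    else:
        nt = mode.split("_")[1]
        value = rec["tail_seq"].str.count(nt).astype(float)
    weighted = rec["ratio"] * value
    scores = (
        weighted.groupby([rec["mirna_id"], rec["sample_id"]])
        .sum()
        .unstack()
        .reindex(columns=table.samples)
    )
    # distinguish "miRNA absent from sample" (NaN) from score 0
    present = (
        rec.groupby(["mirna_id", "sample_id"])["reads"].sum().unstack()
        .reindex(columns=table.samples)
    )
    scores = scores.where(present.notna())
    scores.index.name = "mirna_id"
    scores.columns.name = "sample_id"
    return EndScoreMatrix(scores, mode=mode)


# ---------------------------------------------------------------------------
# PCA / outlier screen


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x components
    variance_explained: np.ndarray
    outlier: pd.Series  # bool per sample, advisory only
    distances: pd.Series


def pca_end_scores(
    matrix: EndScoreMatrix,
    n_components: int = 2,
    k_mad: float = 5.0,
    scale: bool = False,
) -> PcaResult:
    """PCA of samples in end-score space with an advisory outlier flag.

    Scores are centered per miRNA and, by default, not scaled (all scores
    share nucleotide units).  A sample is flagged when its distance from
    the coordinate-wise median of the first two components exceeds the
    median distance by more than ``k_mad`` median absolute deviations.
    Flags are advisory; nothing is removed automatically.
    """
    X = matrix.scores.dropna(axis=0).T  # samples x miRNAs
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA needs >=3 samples and >=2 miRNAs without missing cells")
    values = X.values.astype(float)
    centered = values - values.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("no variance: end-score matrix is constant")
    if scale:
        sd = values.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        centered = centered / sd
    n_components = min(max(n_components, 2), X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(centered)
    coord_df = pd.DataFrame(
        coords,
        index=X.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    first2 = coord_df.iloc[:, : min(2, coord_df.shape[1])]
    center = first2.median(axis=0)
    dist = np.sqrt(((first2 - center) ** 2).sum(axis=1))
    med = float(dist.median())
    mad = float((dist - med).abs().median())
    if mad > 0:
        flags = dist - med > k_mad * mad
    else:  # all-but-identical cloud: flag anything strictly off-center
        flags = dist > med
    return PcaResult(
        coordinates=coord_df,
        variance_explained=pca.explained_variance_ratio_,
        outlier=flags,
        distances=dist,
    )


# ---------------------------------------------------------------------------
# design matrices and vectorized OLS


def build_design(
    metadata: pd.DataFrame, spec: EraModelSpec, samples: list[str]
) -> tuple[np.ndarray, list[str], int]:
    """Design matrix [intercept, age, covariates...] for the given samples.

    Returns (X, column names, index of the age column).  Categorical
    covariates are treatment-coded with the first sorted level as the
    reference.  Raises on rank deficiency, naming the aliased columns.
    """
    md = validate_metadata(metadata).loc[samples]
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(md))}
    age = md["age_days"].to_numpy(float)
    if spec.age_term == "log":
        cols["log(age_days)"] = np.log(age)
    else:
        cols["age_days"] = age
    for cov in spec.covariates:
        if cov not in md.columns:
            raise ValueError(f"covariate {cov!r} not found in metadata")
        col = md[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols[cov] = col.to_numpy(float)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:  # treatment coding, first level = reference
                cols[f"{cov}[{lev}]"] = (col.astype(str) == lev).to_numpy(float)
    X = np.column_stack(list(cols.values()))
    names = list(cols)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(
            f"fewer samples ({n}) than parameters + 1 ({p + 1}); "
            "the model cannot be fit"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        aliased = _aliased_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")
    return X, names, 1  # age term is always the second column


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.where(diag < tol)[0]]


def ols_fit(X: np.ndarray, Y: np.ndarray) -> dict[str, np.ndarray]:
    """OLS of each column of Y on X; returns coefficients, SEs, t, p, dof.

    Y is (n_samples, n_responses); the fit is shared-design multi-response
    least squares, so thousands of miRNAs fit in one call.
    """
    n, p = X.shape
    dof = n - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    var_diag = np.diag(xtx_inv)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(var_diag, sigma2))
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return {
        "beta": beta,
        "se": se,
        "t": tvals,
        "p": pvals,
        "dof": dof,
        "rss": rss,
        "resid": resid,
    }


# ---------------------------------------------------------------------------
# per-miRNA age regression


def regress_end_scores(
    matrix: EndScoreMatrix,
    metadata: pd.DataFrame,
    spec: EraModelSpec | None = None,
) -> pd.DataFrame:
    """Per-miRNA OLS of end score on age + covariates with BH FDR.

    Returns one row per tested miRNA with the age coefficient
    (nucleotides per age unit), its two-sided p-value, the BH-adjusted
    FDR across all miRNAs tested in this call, and the 3'-end class.
    miRNAs with missing cells are dropped (logged).  Zero-variance scores
    get estimate 0 and p = 1 by convention.
    """
    spec = spec or EraModelSpec()
    md = validate_metadata(metadata)
    missing_samples = [s for s in matrix.sample_order if s not in md.index]
    if missing_samples:
        raise ValueError(f"samples without metadata: {missing_samples[:5]}")

    scores = matrix.scores
    complete = scores.dropna(axis=0)
    n_dropped = scores.shape[0] - complete.shape[0]
    if n_dropped:
        logger.info(
            "dropping %d miRNAs with missing cells from %s-mode regression",
            n_dropped, matrix.mode,
        )
    if complete.empty:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    samples = list(complete.columns)
    X, names, age_ix = build_design(md, spec, samples)
    Y = complete.T.to_numpy(float)  # samples x miRNAs
    fit = ols_fit(X, Y)

    est = fit["beta"][age_ix].copy()
    p = fit["p"][age_ix].copy()
    zero_var = Y.std(axis=0, ddof=0) == 0
    est[zero_var] = 0.0
    p[zero_var] = 1.0
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)

    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    cls = np.where(
        (fdr < spec.alpha) & (est < 0),
        "shortened",
        np.where((fdr < spec.alpha) & (est > 0), "extended", "ns"),
    )
    return pd.DataFrame(
        {
            "mirna_id": complete.index,
            "estimate_age": est,
            "p_age": p,
            "fdr": fdr,
            "n_samples": len(samples),
            "class": cls,
            "mode": matrix.mode,
        }
    ).reset_index(drop=True)


def decompose_shortening(
    table: IsomiRTable,
    metadata: pd.DataFrame,
    spec: EraModelSpec | None = None,
    exclude_a_tail: bool = False,
    include_total: bool = True,
) -> dict[str, pd.DataFrame]:
    """Repeat the age regression per 3'-modification type.

    Runs ``trim`` and the four ``tail_N`` modes (plus ``total`` by
    default).  With ``exclude_a_tail`` (poly(A)-based library preps such
    as Combo-Seq, where pre-existing terminal A is indistinguishable from
    the added tail) the ``tail_A`` results are still computed but carry
    ``interpretable = False``.
    """
    spec = spec or EraModelSpec()
    modes = (("total",) if include_total else ()) + DECOMPOSITION_MODES
    results: dict[str, pd.DataFrame] = {}
    for mode in modes:
        res = regress_end_scores(compute_end_scores(table, mode), metadata, spec)
        res["interpretable"] = not (exclude_a_tail and mode == "tail_A")
        results[mode] = res
    return results


def decomposition_residual(results: dict[str, pd.DataFrame]) -> pd.Series:
    """Per-miRNA |beta_total - (sum tail betas - beta_trim)|.

    Zero (to numerical precision) whenever all modes share the same
    design and no cells are missing.
    """
    needed = ("total",) + DECOMPOSITION_MODES
    missing = [m for m in needed if m not in results]
    if missing:
        raise ValueError(f"decomposition requires modes {missing}")
    est = {
        m: results[m].set_index("mirna_id")["estimate_age"] for m in needed
    }
    common = est["total"].index
    for m in needed[1:]:
        common = common.intersection(est[m].index)
    tails = sum(est[f"tail_{n}"].loc[common] for n in "ACGU")
    return (est["total"].loc[common] - (tails - est["trim"].loc[common])).abs()
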