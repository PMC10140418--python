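"""Synthetic isomiR / expression data generator with ground truth.

The generator emulates the structure of an aging small-RNA-seq study:

* per-miRNA isomiR 3'-end-position distributions over a small support
  around the canonical terminus, drawn from a Dirichlet;
* for a designated fraction of miRNAs the distribution tilts toward
  shorter ends linearly with age — either by moving mass into trimmed
  isomiRs (empty tails) or by a decline in U tailing;
* negative-binomial read counts with log-normal library-size variation,
  split across isomiRs multinomially;
* spike-in features with constant expectation, endogenous features with
  log-linear age trends, and miRNA:target pairs with programmable
  correlation structure.

Every generated entity has exactly one truth record.  The true 3'-end
slope of a miRNA is defined as the OLS slope of its *analytic* expected
end position over the design ages, so saturation of the tilt near the
support boundary is part of the truth rather than a recovery bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    CanonicalMiRNA,
    ExpressionMatrix,
    IsomiRTable,
    MiRNACatalog,
    RECORD_COLUMNS,
)

TOOLS = ("TargetScan", "miRDB", "miRNet")

# baseline end-position supports and priors per mechanism
_SUPPORTS = {
    "none": (np.arange(-3, 3), np.array([0.04, 0.08, 0.18, 0.50, 0.13, 0.07])),
    "trim": (np.arange(-3, 1), np.array([0.05, 0.10, 0.25, 0.60])),
    "tail_U": (np.arange(0, 3), np.array([0.55, 0.28, 0.17])),
}


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic aging experiment.

    Defaults mirror a four-age mouse design (postnatal days 22, 40, 60,
    120; 8 samples per age) with 30% of miRNAs undergoing true 3'
    shortening at 0.01-0.02 nt/day, half via trimming and half via U-tail
    decline.
    """

    seed: int
    n_mirnas: int = 60
    n_samples: int = 32
    ages: tuple[float, ...] = (22.0, 40.0, 60.0, 120.0)
    frac_shortened: float = 0.3
    slope_range: tuple[float, float] = (-0.02, -0.01)  # nt/day, negative
    frac_trim_mechanism: float = 0.5  # of shortened; remainder = U-tail decline
    reads_per_mirna: float = 2000.0  # mean miRNA read count per sample
    mirna_abundance_sigma: float = 0.3  # log-normal spread across miRNAs
    lib_size_sigma: float = 0.2  # log-normal library-size variation
    dispersion: float | None = 0.1  # NB dispersion; None/0 = deterministic
    sample_concentration: float | None = 150.0  # Dirichlet overdispersion
    min_emit_reads: int = 10  # records below this are not emitted
    erase_a_tails: bool = False  # poly(A) prep: terminal A tails unobservable
    # expression layer
    n_targets: int = 200
    frac_targets_up: float = 0.25
    frac_targets_down: float = 0.25
    target_trend_range: tuple[float, float] = (0.01, 0.03)  # |log2/day|
    target_base_mean: float = 500.0
    spikein_small_n: int = 12
    spikein_large_n: int = 8
    spikein_mean: float = 5000.0
    endogenous_gain_per_day: float = 0.0  # multiplicative linear gain
    shortened_up_bias: float = 0.02  # extra log2/day for shortened miRNAs
    expr_noise_sigma: float = 0.1  # log-normal residual noise on means
    # interaction layer
    n_interactions: int = 400
    link_strength: float = 0.8
    link_scope: str = "shortened_de"  # shortened_de | all | none

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        for name in ("frac_shortened", "frac_trim_mechanism", "frac_targets_up",
                     "frac_targets_down", "link_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_targets_up + self.frac_targets_down > 1.0:
            raise ValueError("target trend fractions exceed 1")
        if any(a <= 0 for a in self.ages):
            raise ValueError("ages must be positive")
        lo, hi = self.slope_range
        if lo > hi or hi > 0:
            raise ValueError("slope_range must be negative (shortening)")
        if self.link_scope not in ("shortened_de", "all", "none"):
            raise ValueError("link_scope must be shortened_de | all | none")
        age_span = max(self.ages) - min(self.ages)
        for mech in ("trim", "tail_U"):
            support, _ = _SUPPORTS[mech]
            span = support.max() - support.min()
            if abs(lo) * age_span > span + 0.25:
                raise ValueError(
                    f"slope {lo} nt/day over {age_span} days exceeds the "
                    f"{mech} end-position support span ({span} nt)"
                )

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            data["seed"] = seed
        for key in ("ages", "slope_range", "target_trend_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class SimulationTruth:
    """Ground truth for every generated entity."""

    mirnas: pd.DataFrame  # mirna_id, mechanism, shortened, true_slope, expr_slope_log2
    targets: pd.DataFrame | None = None  # target_id, trend, slope_log2, linked_mirna
    pairs: pd.DataFrame | None = None  # mirna_id, target_id, linked, sign, strength
    expected_ratio_slope: float | None = None  # endo/spike-in ratio per day


# ---------------------------------------------------------------------------
# helpers


def _make_metadata(config: SimulationConfig) -> pd.DataFrame:
    ages = list(config.ages)
    rows = []
    for i in range(config.n_samples):
        rows.append(
            {
                "sample_id": f"S{i + 1:03d}",
                "age_days": float(ages[i % len(ages)]),
                "batch": f"B{(i // len(ages)) % 2 + 1}",
                "sex": "F" if i % 2 else "M",
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _random_catalog(config: SimulationConfig, rng: np.random.Generator) -> MiRNACatalog:
    catalog = MiRNACatalog()
    for i in range(config.n_mirnas):
        length = int(rng.integers(20, 24))
        seq = "".join(rng.choice(list("ACGU"), size=length))
        arm = "3p" if rng.random() < 0.5 else "5p"
        catalog.add(CanonicalMiRNA(f"syn-mir-{i + 1:04d}-{arm}", seq, arm=arm))
    return catalog


def _nb_draw(
    rng: np.random.Generator, mean: float, dispersion: float | None
) -> float:
    """One negative-binomial count; the deterministic regime
    (dispersion None/0) returns the expectation itself."""
    if not dispersion:
        return float(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return float(rng.negative_binomial(r, p))


def _weights_at_age(
    base: np.ndarray, support: np.ndarray, tilt_per_day: float, age: float,
    age_ref: float,
) -> np.ndarray:
    """Exponential-family tilt of the end-position distribution.

    ``tilt_per_day`` is calibrated so the expected end position moves at
    approximately the requested nt/day near the reference age; the exact
    expectation is always computed from the returned weights.
    """
    theta = tilt_per_day * (age - age_ref)
    w = base * np.exp(theta * support)
    return w / w.sum()


def _tail_for_position(e: int, mechanism: str, tail_nt: str) -> tuple[int, str]:
    """(len_trim, tail_seq) realizing end position ``e``."""
    if e < 0:
        return -e, ""
    if e == 0:
        return 0, ""
    nt = "U" if mechanism == "tail_U" else tail_nt
    return 0, nt * e


# ---------------------------------------------------------------------------
# isomiR table simulation


def simulate_isomir_table(
    config: SimulationConfig,
) -> tuple[IsomiRTable, pd.DataFrame, SimulationTruth]:
    """Generate a validated isomiR table, sample metadata, and truth.

    Same config (and seed) always yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    metadata = _make_metadata(config)
    catalog = _random_catalog(config, rng)
    mirna_ids = catalog.ids
    ages = metadata["age_days"].to_numpy()
    age_ref = float(ages.mean())

    n_short = int(round(config.frac_shortened * config.n_mirnas))
    n_trim_mech = int(round(config.frac_trim_mechanism * n_short))
    mechanisms = (
        ["trim"] * n_trim_mech
        + ["tail_U"] * (n_short - n_trim_mech)
        + ["none"] * (config.n_mirnas - n_short)
    )
    rng.shuffle(mechanisms)

    base_means = config.reads_per_mirna * rng.lognormal(
        0.0, config.mirna_abundance_sigma, size=config.n_mirnas
    )
    lib_factors = rng.lognormal(0.0, config.lib_size_sigma, size=config.n_samples)

    records: list[dict] = []
    truth_rows = []
    for mi, (mid, mech) in enumerate(zip(mirna_ids, mechanisms)):
        support, prior = _SUPPORTS[mech]
        base = rng.dirichlet(prior * 30.0)
        base = np.clip(base, 1e-6, None)
        base = base / base.sum()
        if mech == "none":
            requested = 0.0
            tilt = 0.0
        else:
            requested = float(rng.uniform(*config.slope_range))
            var0 = float(np.sum(base * support**2) - np.sum(base * support) ** 2)
            tilt = requested / max(var0, 1e-3)
        tail_nt = str(rng.choice(["A", "U", "C", "G"], p=[0.35, 0.35, 0.15, 0.15]))

        # analytic expectations define the truth slope
        expected = np.array(
            [
                np.sum(_weights_at_age(base, support, tilt, a, age_ref) * support)
                for a in ages
            ]
        )
        true_slope = (
            float(np.polyfit(ages, expected, 1)[0]) if mech != "none" else 0.0
        )
        truth_rows.append(
            {
                "mirna_id": mid,
                "mechanism": mech,
                "shortened": mech != "none",
                "true_slope": true_slope,
                "requested_slope": requested,
            }
        )

        for si, (sample, age) in enumerate(zip(metadata.index, ages)):
            w = _weights_at_age(base, support, tilt, age, age_ref)
            if config.sample_concentration:
                w = rng.dirichlet(np.clip(w, 1e-8, None) * config.sample_concentration)
            mean_total = base_means[mi] * lib_factors[si]
            total = int(np.rint(_nb_draw(rng, mean_total, config.dispersion)))
            if total <= 0:
                continue
            if config.dispersion or config.sample_concentration:
                counts = rng.multinomial(total, w / w.sum())
            else:
                counts = np.rint(total * w).astype(int)
            for e, c in zip(support, counts):
                if c < config.min_emit_reads:
                    continue
                len_trim, tail = _tail_for_position(int(e), mech, tail_nt)
                if config.erase_a_tails and tail and set(tail) == {"A"}:
                    tail = ""  # poly(A) prep absorbs terminal A tails
                records.append(
                    {
                        "mirna_id": mid,
                        "sample_id": sample,
                        "len_trim": len_trim,
                        "tail_seq": tail,
                        "len_5p": 0,
                        "reads": int(c),
                    }
                )

    rec = pd.DataFrame(records)
    # A-tail erasure can merge rows that became identical; re-aggregate
    rec = (
        rec.groupby(["mirna_id", "sample_id", "len_trim", "tail_seq", "len_5p"],
                    as_index=False)["reads"].sum()
    )
    totals = rec.groupby(["mirna_id", "sample_id"])["reads"].transform("sum")
    rec["ratio"] = rec["reads"] / totals
    rec = rec[RECORD_COLUMNS].sort_values(
        ["mirna_id", "sample_id", "len_trim", "tail_seq"]
    ).reset_index(drop=True)

    table = IsomiRTable(records=rec, catalog=catalog,
                        samples=list(metadata.index))
    table.check_ratio_sums()
    truth = SimulationTruth(mirnas=pd.DataFrame(truth_rows))
    return table, metadata, truth


# ---------------------------------------------------------------------------
# expression + interaction simulation


def simulate_expression(
    config: SimulationConfig,
    truth: SimulationTruth,
    metadata: pd.DataFrame,
) -> tuple[ExpressionMatrix, "InteractionSet", SimulationTruth]:
    """Generate a combined miRNA + mRNA + spike-in count matrix and an
    interaction set, wiring the configured correlation structure into
    linked pairs.  Extends ``truth`` in place with target and pair
    records and returns it.
    """
    from .targets import InteractionSet  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed + 104729)  # decouple from table noise
    ages = metadata["age_days"].to_numpy(float)
    n_s = len(ages)
    age0 = ages.min()
    lib = rng.lognormal(0.0, config.lib_size_sigma, size=n_s)

    mirna_ids = truth.mirnas["mirna_id"].tolist()
    shortened = set(truth.mirnas.loc[truth.mirnas["shortened"], "mirna_id"])

    # --- miRNA counts
    expr_slopes = rng.normal(0.0, 0.002, size=len(mirna_ids))
    expr_slopes += np.array(
        [config.shortened_up_bias if m in shortened else 0.0 for m in mirna_ids]
    )
    gain = 1.0 + config.endogenous_gain_per_day * (ages - age0)
    mirna_counts = {}
    mirna_base = config.reads_per_mirna * rng.lognormal(
        0.0, config.mirna_abundance_sigma, size=len(mirna_ids)
    )
    noise_sd = config.expr_noise_sigma
    for i, mid in enumerate(mirna_ids):
        mean = (
            mirna_base[i]
            * lib
            * gain
            * np.exp2(expr_slopes[i] * (ages - age0))
        )
        if noise_sd:
            mean = mean * rng.lognormal(0.0, noise_sd, size=n_s)
        mirna_counts[mid] = np.array(
            [_nb_draw(rng, m, config.dispersion) for m in mean], float
        )
    truth.mirnas = truth.mirnas.assign(expr_slope_log2=expr_slopes)

    # --- target trend assignment
    n_up = int(round(config.frac_targets_up * config.n_targets))
    n_down = int(round(config.frac_targets_down * config.n_targets))
    trends = ["up"] * n_up + ["down"] * n_down + [
        "flat"
    ] * (config.n_targets - n_up - n_down)
    rng.shuffle(trends)
    target_ids = [f"gene-{i + 1:04d}" for i in range(config.n_targets)]
    t_slopes = {}
    for tid, tr in zip(target_ids, trends):
        mag = float(rng.uniform(*config.target_trend_range))
        t_slopes[tid] = {"up": mag, "down": -mag, "flat": 0.0}[tr]

    # --- interactions and linked pairs
    n_pairs = min(config.n_interactions, len(mirna_ids) * len(target_ids))
    pair_idx = rng.choice(
        len(mirna_ids) * len(target_ids), size=n_pairs, replace=False
    )
    pair_rows = []
    for ix in np.sort(pair_idx):
        m = mirna_ids[ix // len(target_ids)]
        t = target_ids[ix % len(target_ids)]
        n_src = int(rng.choice([1, 2, 3], p=[0.35, 0.45, 0.20]))
        sources = frozenset(rng.choice(TOOLS, size=n_src, replace=False).tolist())
        pair_rows.append(
            {"mirna_id": m, "target_id": t, "sources": sources,
             "support_count": len(sources)}
        )
    pairs = pd.DataFrame(pair_rows)

    linked_partner: dict[str, tuple[str, int]] = {}  # target -> (mirna, sign)
    if config.link_scope != "none" and config.link_strength > 0:
        for _, row in pairs.iterrows():
            m, t = row["mirna_id"], row["target_id"]
            tr = trends[target_ids.index(t)]
            if t in linked_partner:
                continue
            if config.link_scope == "shortened_de":
                eligible = (m in shortened) and tr != "flat"
            else:
                eligible = True
            if eligible:
                sign = 1 if t_slopes[t] >= 0 else -1
                linked_partner[t] = (m, sign)

    # --- target counts
    target_counts = {}
    rho = config.link_strength
    for tid in target_ids:
        trend_prof = np.exp2(t_slopes[tid] * (ages - age0))
        own = trend_prof * (
            rng.lognormal(0.0, noise_sd, size=n_s) if noise_sd else 1.0
        )
        if tid in linked_partner:
            m, sign = linked_partner[tid]
            m_rel = mirna_counts[m] / max(mirna_counts[m].mean(), 1e-9)
            affine = m_rel if sign > 0 else np.clip(2.0 - m_rel, 0.0, None)
            profile = rho * affine + (1.0 - rho) * own
        else:
            profile = own
        mean = config.target_base_mean * lib * profile
        target_counts[tid] = np.array(
            [_nb_draw(rng, mv, config.dispersion) for mv in mean], float
        )

    # --- spike-ins: constant expectation, library scaling only
    spike_counts = {}
    for i in range(config.spikein_small_n):
        mean = config.spikein_mean * lib
        spike_counts[f"spike-small-{i + 1:02d}"] = np.array(
            [_nb_draw(rng, mv, config.dispersion) for mv in mean], float
        )
    for i in range(config.spikein_large_n):
        mean = 2.0 * config.spikein_mean * lib
        spike_counts[f"spike-large-{i + 1:02d}"] = np.array(
            [_nb_draw(rng, mv, config.dispersion) for mv in mean], float
        )

    counts = pd.DataFrame(
        {**mirna_counts, **target_counts, **spike_counts}, index=metadata.index
    ).T
    classes = pd.Series(
        {
            **{m: "endogenous_miRNA" for m in mirna_ids},
            **{t: "mRNA" for t in target_ids},
            **{
                s: ("spikein_small" if "small" in s else "spikein_large")
                for s in spike_counts
            },
        }
    )
    matrix = ExpressionMatrix(counts=counts, feature_class=classes)

    # analytic expected endo/spike ratio slope (truth for the trend test)
    exp_endo = np.zeros(n_s)
    for i, mid in enumerate(mirna_ids):
        exp_endo += mirna_base[i] * gain * np.exp2(expr_slopes[i] * (ages - age0))
    exp_spike = config.spikein_small_n * config.spikein_mean * np.ones(n_s)
    exp_ratio = exp_endo / exp_spike
    ratio_slope = float(np.polyfit(ages, exp_ratio, 1)[0])

    truth.targets = pd.DataFrame(
        {
            "target_id": target_ids,
            "trend": trends,
            "slope_log2": [t_slopes[t] for t in target_ids],
            "linked_mirna": [
                linked_partner.get(t, (None,))[0] for t in target_ids
            ],
        }
    )
    truth.pairs = pairs.assign(
        linked=[row["target_id"] in linked_partner
                and linked_partner[row["target_id"]][0] == row["mirna_id"]
                for _, row in pairs.iterrows()],
        sign=[linked_partner.get(row["target_id"], (None, 0))[1]
              if row["target_id"] in linked_partner
              and linked_partner[row["target_id"]][0] == row["mirna_id"] else 0
              for _, row in pairs.iterrows()],
        strength=config.link_strength,
    )
    truth.expected_ratio_slope = ratio_slope
    return matrix, InteractionSet(pairs), truth


# ---------------------------------------------------------------------------
# recovery metrics


def evaluate_recovery(
    truth: SimulationTruth,
    era_results: pd.DataFrame | None = None,
    de_results: pd.DataFrame | None = None,
    correlations: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Score inference output against the generator's ground truth."""
    metrics: dict[str, float] = {}
    if era_results is not None:
        truth_m = truth.mirnas.set_index("mirna_id")
        unknown = set(era_results["mirna_id"]) - set(truth_m.index)
        if unknown:
            raise ValueError(f"era results contain unknown miRNAs: {sorted(unknown)[:5]}")
        res = era_results.set_index("mirna_id")
        joined = res.join(truth_m, how="inner")
        true_short = joined["shortened"].astype(bool)
        called_short = joined["class"] == "shortened"
        called_any = joined["class"] != "ns"
        tp = int((called_short & true_short).sum())
        metrics["sensitivity"] = tp / max(int(true_short.sum()), 1)
        metrics["specificity"] = int((~called_any & ~true_short).sum()) / max(
            int((~true_short).sum()), 1
        )
        fp = int((called_any & ~true_short).sum())
        metrics["empirical_fdr"] = fp / max(int(called_any.sum()), 1)
        metrics["n_called"] = float(called_any.sum())
        sub = joined[true_short]
        if len(sub):
            err = sub["estimate_age"] - sub["true_slope"]
            metrics["slope_bias"] = float(err.mean())
            metrics["slope_rmse"] = float(np.sqrt((err**2).mean()))
            metrics["mean_abs_true_slope"] = float(sub["true_slope"].abs().mean())
    if de_results is not None and truth.targets is not None:
        truth_t = truth.targets.set_index("target_id")
        de = de_results.set_index("feature_id")
        common = truth_t.index.intersection(de.index)
        trended = truth_t.loc[common, "trend"].isin(["up", "down"])
        sub = common[trended]
        if len(sub):
            match = de.loc[sub, "direction"] == truth_t.loc[sub, "trend"]
            metrics["de_direction_accuracy"] = float(match.mean())
    if correlations is not None and truth.pairs is not None:
        linked = truth.pairs[truth.pairs["linked"]]
        if len(linked):
            key = list(zip(linked["mirna_id"], linked["target_id"]))
            corr = correlations.set_index(["mirna_id", "target_id"])
            present = [k for k in key if k in corr.index]
            if present:
                r = corr.loc[present, "r"].dropna()
                signs = linked.set_index(["mirna_id", "target_id"]).loc[
                    r.index, "sign"
                ]
                metrics["correlation_sign_accuracy"] = float(
                    (np.sign(r) == np.sign(signs)).mean()
                )
    if not metrics:
        raise ValueError("no inference results supplied")
    return metrics
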