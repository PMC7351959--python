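"""Sequencing-depth sufficiency evaluation for source attribution.

The experiment: run attribution once on the full-depth table (the
reference), then rarefy the table to a descending ladder of depths, re-run
attribution on each rarefied replicate, and compare each run to the
reference with four statistics — mean squared difference of the proportion
cells, Spearman correlation of the flattened cells, the hit ratio (percent
of sinks whose top-ranked source, Unknown included, matches the
reference's), and the per-sink absolute difference in Unknown
classification rate.  Replicate values per depth are then screened with
Shapiro-Wilk and Levene and compared with Kruskal-Wallis plus a Dunn
post-hoc test under Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_table import FeatureTable, FeatureTableError, rarefy, sample_substream
from .gibbs import UNKNOWN, AttributionResult, GibbsConfig, track_all_sinks
from .metadata import SampleMetadata

log = logging.getLogger(__name__)

__all__ = [
    "DepthEvalConfig",
    "DepthEvalResult",
    "run_depth_evaluation",
    "mean_squared_difference",
    "spearman_vs_reference",
    "hit_ratio",
    "unknown_rate_difference",
    "compare_depths_stats",
    "dunn_test",
]


@dataclass(frozen=True)
class DepthEvalConfig:
    """Rarefaction ladder and replication schedule.

    The default ladder descends 7712 / 5000 / 1000 / 500 / 200 reads per
    sample with 3 replicates per depth except the smallest, which gets 10
    (higher variance is expected there).  ``hit_rule`` is ``"top1"`` or
    ``("topk", k)``.
    """

    depths: tuple[int, ...] = (7712, 5000, 1000, 500, 200)
    replicates_default: int = 3
    replicates_smallest: int = 10
    hit_rule: object = "top1"
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.depths) != sorted(self.depths, reverse=True):
            raise ValueError("depths must be sorted descending")
        if self.replicates_default < 1 or self.replicates_smallest < 1:
            raise ValueError("replicates must be >= 1")

    def replicates_for(self, depth: int) -> int:
        return (
            self.replicates_smallest
            if depth == min(self.depths)
            else self.replicates_default
        )


@dataclass(frozen=True)
class DepthEvalResult:
    """Per-(depth, replicate) comparison statistics plus the reference run."""

    reference: AttributionResult
    records: pd.DataFrame  # depth, replicate, msd, spearman_rho, hit_ratio,
    #                        unknown_diff_mean, n_sinks
    proportions: Mapping[tuple[int, int], pd.DataFrame] = field(repr=False)

    def metric_groups(self, metric: str) -> dict[int, np.ndarray]:
        col = {
            "msd": "msd",
            "hit_ratio": "hit_ratio",
            "unknown_diff": "unknown_diff_mean",
            "spearman": "spearman_rho",
        }[metric]
        return {
            int(d): g[col].to_numpy()
            for d, g in self.records.groupby("depth", sort=False)
        }

    def to_long(self) -> pd.DataFrame:
        """Long-format (depth, replicate, metric, value) table."""
        rows = []
        for _, r in self.records.iterrows():
            for metric in ("msd", "spearman_rho", "hit_ratio", "unknown_diff_mean"):
                rows.append(
                    (int(r["depth"]), int(r["replicate"]), metric, r[metric])
                )
        return pd.DataFrame(rows, columns=["depth", "replicate", "metric", "value"])


# ---------------------------------------------------------------------------
# Pairwise comparison statistics
# ---------------------------------------------------------------------------


def _align(est: pd.DataFrame, ref: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if list(est.index) != list(ref.index) or list(est.columns) != list(ref.columns):
        if set(est.index) != set(ref.index) or set(est.columns) != set(ref.columns):
            raise ValueError("proportion matrices are not aligned")
        est = est.loc[ref.index, ref.columns]
    return est, ref


def mean_squared_difference(
    est: pd.DataFrame, ref: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Cellwise (est - ref)^2 and its mean over all cells."""
    est, ref = _align(est, ref)
    sq = (est - ref) ** 2
    return float(sq.to_numpy().mean()), sq


def spearman_vs_reference(est: pd.DataFrame, ref: pd.DataFrame) -> float:
    """Spearman rank correlation of the flattened proportion cells."""
    est, ref = _align(est, ref)
    a, b = est.to_numpy().ravel(), ref.to_numpy().ravel()
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant proportion vector: Spearman undefined")
        return float("nan")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def _top_labels(row: pd.Series, k: int = 1) -> list[str]:
    # sort by descending value, ties broken toward the smallest label
    ordered = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))
    return [lab for lab, _ in ordered[:k]]


def hit_ratio(est: pd.DataFrame, ref: pd.DataFrame, rule: object = "top1") -> float:
    """Percent of sinks whose top source matches the reference's top source.

    The Unknown environment is eligible like any other; ties break toward
    the lexicographically smallest environment label.  With
    ``rule=("topk", k)`` a hit is scored when the reference's top label
    appears among the estimate's top k labels.
    """
    est, ref = _align(est, ref)
    if est.shape[0] == 0:
        raise ValueError("hit_ratio needs at least one sink")
    if rule == "top1":
        k = 1
    elif isinstance(rule, tuple) and len(rule) == 2 and rule[0] == "topk":
        k = int(rule[1])
    else:
        raise ValueError(f"unknown hit rule {rule!r}")
    hits = 0
    for sid in ref.index:
        ref_top = _top_labels(ref.loc[sid], 1)[0]
        if ref_top in _top_labels(est.loc[sid], k):
            hits += 1
    return 100.0 * hits / est.shape[0]


def unknown_rate_difference(
    est: pd.DataFrame, ref: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Per-sink |est - ref| of the Unknown proportion, in percent, plus mean."""
    est, ref = _align(est, ref)
    if UNKNOWN not in est.columns or UNKNOWN not in ref.columns:
        raise ValueError(f"missing {UNKNOWN!r} column")
    diffs = (est[UNKNOWN] - ref[UNKNOWN]).abs() * 100.0
    return diffs, float(diffs.mean())


# ---------------------------------------------------------------------------
# The experiment driver
# ---------------------------------------------------------------------------


def run_depth_evaluation(
    table: FeatureTable,
    metadata: SampleMetadata,
    gibbs: GibbsConfig,
    config: DepthEvalConfig,
) -> DepthEvalResult:
    """Full-depth reference plus rarefaction-replicate attribution runs.

    Every (depth, replicate) run rarefies the whole table on a fresh random
    substream and re-attributes with a Gibbs seed derived from the same
    substream, so runs are independent but the whole experiment is
    reproducible from one seed pair.
    """
    reference = track_all_sinks(table, metadata, gibbs)
    ref_props = reference.proportions
    records = []
    proportions: dict[tuple[int, int], pd.DataFrame] = {}
    for depth in config.depths:
        n_rep = config.replicates_for(depth)
        for rep in range(n_rep):
            stream = sample_substream(config.seed, "depth_eval", depth, rep)
            rare_seed = int(stream.integers(0, 2**31 - 1))
            try:
                rarefied = rarefy(table, depth, seed=rare_seed)
            except FeatureTableError:
                warnings.warn(f"depth {depth} drops all samples; skipped")
                break
            kept_sinks = [
                s for s in rarefied.sample_ids if s in set(metadata.sink_ids)
            ]
            if not kept_sinks:
                warnings.warn(f"depth {depth} drops all sinks; skipped")
                break
            # one shared GibbsConfig for reference and rarefied runs: with
            # unchanged counts (depth = full library size) the comparison is
            # then exact, and replicates still differ through rarefaction
            run = track_all_sinks(rarefied, metadata, gibbs)
            est = run.proportions.reindex(
                index=kept_sinks, columns=ref_props.columns, fill_value=0.0
            )
            ref_sub = ref_props.loc[kept_sinks]
            msd, _ = mean_squared_difference(est, ref_sub)
            rho = spearman_vs_reference(est, ref_sub)
            hr = hit_ratio(est, ref_sub, config.hit_rule)
            _, udiff = unknown_rate_difference(est, ref_sub)
            unknown_rate = float(est[UNKNOWN].mean() * 100.0)
            records.append(
                (depth, rep, msd, rho, hr, udiff, unknown_rate, len(kept_sinks))
            )
            proportions[(depth, rep)] = est
            log.info(
                "depth %d rep %d: msd=%.4g rho=%.3f hit=%.1f%% unknown_diff=%.2f",
                depth, rep, msd, rho, hr, udiff,
            )
    rec = pd.DataFrame(
        records,
        columns=[
            "depth", "replicate", "msd", "spearman_rho", "hit_ratio",
            "unknown_diff_mean", "unknown_rate", "n_sinks",
        ],
    )
    return DepthEvalResult(reference, rec, proportions)


# ---------------------------------------------------------------------------
# Statistical testing across depth groups
# ---------------------------------------------------------------------------


def dunn_test(groups: dict[int, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z test with tie correction and BH adjustment.

    For groups i, j with mean ranks Ri, Rj over the pooled ranking of N
    values, z = (Ri - Rj) / sqrt((N(N+1)/12 - C)(1/ni + 1/nj)) where
    C = sum(t^3 - t)/(12(N-1)) over tie groups.  Two-sided normal p-values,
    Benjamini-Hochberg adjusted over all pairs.
    """
    labels = list(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    N = len(values)
    ranks = stats.rankdata(values)
    mean_ranks = {}
    start = 0
    for g in labels:
        mean_ranks[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    C = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    var_base = N * (N + 1) / 12.0 - C
    rows = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            gi, gj = labels[a], labels[b]
            se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se if se > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append((gi, gj, z, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    ok = df["p"].notna()
    adj = np.full(len(df), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["p_adj"] = adj
    return df


def compare_depths_stats(
    result: DepthEvalResult, metric: str = "msd"
) -> dict[str, object]:
    """Normality screen, Levene, Kruskal-Wallis and Dunn/BH across depths.

    Returns a report dict; entries that cannot be computed (too few
    replicates, constant groups) are reported as NaN with a note rather
    than silently omitted.
    """
    groups = result.metric_groups(metric)
    if len(groups) < 2:
        raise ValueError("need at least two depth groups")
    notes: list[str] = []
    shapiro = {}
    for d, vals in groups.items():
        if len(vals) < 3:
            shapiro[d] = (np.nan, np.nan)
            notes.append(f"depth {d}: <3 replicates, Shapiro-Wilk skipped")
        elif np.ptp(vals) == 0:
            shapiro[d] = (np.nan, np.nan)
            notes.append(f"depth {d}: constant values, Shapiro-Wilk undefined")
        else:
            w, p = stats.shapiro(vals)
            shapiro[d] = (float(w), float(p))
    arrays = list(groups.values())
    if all(len(v) >= 2 for v in arrays) and np.ptp(np.concatenate(arrays)) > 0:
        lev_stat, lev_p = stats.levene(*arrays)
    else:
        lev_stat, lev_p = np.nan, np.nan
        notes.append("Levene test undefined (constants or <2 per group)")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        kw_h, kw_p = 0.0, 1.0
        notes.append("all values identical: Kruskal-Wallis trivially null")
        dunn = None
    else:
        kw_h, kw_p = stats.kruskal(*arrays)
        dunn = dunn_test(groups)
    return {
        "metric": metric,
        "shapiro": shapiro,
        "levene": (float(lev_stat), float(lev_p))
        if np.isfinite(lev_stat)
        else (np.nan, np.nan),
        "kruskal_h": float(kw_h),
        "kruskal_p": float(kw_p),
        "dunn": dunn,
        "notes": notes,
    }
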