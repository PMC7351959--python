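"""Alpha/beta diversity and bench-count (qPCR / plate count) statistics.

Alpha indices are computed on a table rarefied to the minimum library size
so that observed-taxon counts are comparable across samples.  Shannon uses
the natural logarithm; Simpson is reported as 1 - sum(p^2).  Bray-Curtis
distances follow BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i) on raw counts.
Group comparisons gate on Shapiro-Wilk normality (alpha = 0.05) to choose a
paired t-test or Wilcoxon signed-rank, with Benjamini-Hochberg adjustment
over the family of comparisons.  Bacterial cell equivalents (BCE) are
extrapolated from qPCR 16S gene copies with an average of four copies per
cell.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .feature_table import FeatureTable, rarefy

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "grouped_comparison",
    "bce_from_copies",
    "correlate_counts",
]


def alpha_diversity(
    table: FeatureTable, rarefy_to_min: bool = True, seed: int = 0
) -> pd.DataFrame:
    """Observed taxa, Shannon (natural log) and Simpson (1 - sum p^2) per sample."""
    if table.n_samples < 1:
        raise ValueError("need at least one sample")
    sums = table.sample_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-sum sample: {zero.index[0]!r}")
    if rarefy_to_min:
        table = rarefy(table, int(sums.min()), seed=seed)
    rows = {}
    for sid in table.sample_ids:
        col = table.data[sid].to_numpy().astype(float)
        p = col[col > 0] / col.sum()
        rows[sid] = {
            "observed_taxa": int((col > 0).sum()),
            "shannon": float(-(p * np.log(p)).sum()),
            "simpson": float(1.0 - (p**2).sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(table: FeatureTable) -> pd.DataFrame:
    """Symmetric Bray-Curtis distance matrix over samples (zero diagonal)."""
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    X = table.counts.T.astype(float)
    empty = X.sum(axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = squareform(pdist(X, metric="braycurtis"))
    if empty.any():
        warnings.warn("all-zero samples: their pairwise distances are undefined")
        idx = np.where(empty)[0]
        for i in idx:
            for j in idx:
                if i != j:
                    D[i, j] = np.nan
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=table.sample_ids, columns=table.sample_ids)


def grouped_comparison(
    values: pd.Series,
    groups: pd.Series,
    paired: bool = True,
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise group comparisons with a normality gate and BH adjustment.

    ``values`` holds one measurement per sample, ``groups`` the group label
    per sample (aligned index).  By default consecutive groups in order of
    first appearance are compared (the natural layout for positions along a
    processing line); pass ``pairs`` for an explicit family.  Each
    comparison runs Shapiro-Wilk on both groups: if both look normal a
    (paired) t-test is used, otherwise the Wilcoxon test; groups under 3
    values fall back to Wilcoxon with a warning.  Paired comparisons
    require matched ordering of the two groups' values.
    """
    groups = groups.reindex(values.index)
    order = list(dict.fromkeys(groups.dropna()))
    if pairs is None:
        pairs = list(zip(order[:-1], order[1:]))
    rows = []
    for ga, gb in pairs:
        a = values[groups == ga].to_numpy(dtype=float)
        b = values[groups == gb].to_numpy(dtype=float)
        note = ""
        if paired and len(a) != len(b):
            raise ValueError(f"paired comparison {ga!r} vs {gb!r}: unequal sizes")
        if paired and np.array_equal(a, b):
            rows.append((ga, gb, "wilcoxon", np.nan, np.nan,
                         "identical paired values: no difference"))
            warnings.warn(
                f"{ga!r} vs {gb!r}: identical paired values, test degenerate"
            )
            continue
        normal = True
        for g, v in ((ga, a), (gb, b)):
            if len(v) < 3:
                normal = False
                note = "group <3: normality untestable, Wilcoxon used"
                warnings.warn(f"group {g!r} has <3 values; falling back to Wilcoxon")
            elif np.ptp(v) == 0:
                normal = False
            else:
                _, p_norm = stats.shapiro(v)
                if p_norm < alpha:
                    normal = False
        if normal:
            test = "paired t-test" if paired else "t-test"
            stat, p = (
                stats.ttest_rel(a, b) if paired else stats.ttest_ind(a, b)
            )[:2]
        else:
            test = "wilcoxon" if paired else "mann-whitney"
            if paired:
                stat, p = stats.wilcoxon(a, b)
            else:
                stat, p = stats.mannwhitneyu(a, b)
        rows.append((ga, gb, test, float(stat), float(p), note))
    df = pd.DataFrame(
        rows, columns=["group_a", "group_b", "test", "stat", "p", "note"]
    )
    ok = df["p"].notna()
    adj = np.full(len(df), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["p_adj"] = adj
    return df


def bce_from_copies(gene_copies: float, copies_per_cell: float = 4.0) -> float:
    """Bacterial cell equivalents from total 16S gene copies.

    Divides by the assumed mean rRNA operon copy number per cell (4 by
    default, the rrnDB-derived average used for meat-associated
    communities).
    """
    if copies_per_cell <= 0:
        raise ValueError("copies_per_cell must be > 0")
    if gene_copies < 0:
        raise ValueError("gene_copies must be >= 0")
    return gene_copies / copies_per_cell


def correlate_counts(
    panel: pd.DataFrame,
    x: str = "bce",
    y: str = "amc",
    position_col: str = "position",
) -> pd.DataFrame:
    """Spearman correlation of two count columns within each sampling position.

    The panel carries one row per sample with a position label and count
    columns (BCE plus plate counts).  Positions with fewer than 3 complete
    pairs are reported as NaN with a warning.
    """
    rows = {}
    for pos, sub in panel.groupby(position_col, sort=False):
        pairs = sub[[x, y]].dropna()
        if len(pairs) < 3:
            warnings.warn(f"position {pos!r}: <3 pairs, correlation skipped")
            rows[pos] = {"rho": np.nan, "p": np.nan, "n": len(pairs)}
            continue
        rho, p = stats.spearmanr(pairs[x], pairs[y])
        rows[pos] = {"rho": float(rho), "p": float(p), "n": len(pairs)}
    return pd.DataFrame.from_dict(rows, orient="index")
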