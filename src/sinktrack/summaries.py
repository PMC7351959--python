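"""Aggregations of attribution results: flow tables and genus-source matrices.

Two summaries underlie the usual presentation of source-tracking output for
a processing line: (1) a flow table giving, per processing-line position,
the average percentage of sink communities contributed by each source
environment (the numbers behind a Sankey diagram), and (2) a genus x source
matrix giving the relative contribution of each source to the reads of
spoilage- or safety-relevant genera (the numbers behind a heatmap), with a
shared-source hierarchical clustering of the genus columns.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .gibbs import UNKNOWN, AttributionResult
from .metadata import SampleMetadata, Taxonomy

__all__ = [
    "aggregate_by_position",
    "genus_source_contributions",
    "shared_source_clustering",
]


def aggregate_by_position(
    result: AttributionResult, metadata: SampleMetadata
) -> pd.DataFrame:
    """Mean source contribution (percent) per processing-line position.

    Returns a DataFrame with rows = source environments (+ Unknown),
    columns = sink positions; each column sums to 100.
    """
    if not result.sink_ids:
        raise ValueError("empty attribution result")
    positions = {}
    for sid in result.sink_ids:
        positions[sid] = metadata.position_of(sid)  # raises if missing
    pos_series = pd.Series(positions)
    out = {}
    for pos in dict.fromkeys(pos_series.values):  # preserve first-seen order
        members = pos_series.index[pos_series == pos]
        out[pos] = result.proportions.loc[members].mean(axis=0) * 100.0
    return pd.DataFrame(out)


def genus_source_contributions(
    result: AttributionResult,
    taxonomy: Taxonomy,
    relevant_genera: list[str],
    normalize: str = "genus",
) -> pd.DataFrame:
    """Relative contribution of each source environment per genus.

    Mean assigned read counts are summed over sinks per (genus, source);
    genera outside ``relevant_genera`` are pooled into "Other".  With the
    default ``normalize="genus"`` each genus column sums to 1; passing
    ``normalize="source"`` normalizes rows instead.  Genus columns with zero
    assigned reads everywhere are dropped with a warning rather than
    returned as NaN.
    """
    if not result.taxon_assignments:
        raise ValueError("attribution result carries no taxon assignments")
    if not relevant_genera:
        warnings.warn("empty genus list: all genera pooled into 'Other'")
    keep = set(relevant_genera)
    envs = result.environments
    acc: dict[str, np.ndarray] = {}
    for sid, assign in result.taxon_assignments.items():
        gmap = taxonomy.genus_map(list(assign.index))
        labels = gmap.where(gmap.isin(keep), "Other")
        grouped = assign.groupby(labels.values).sum()
        for genus, row in grouped.iterrows():
            acc.setdefault(str(genus), np.zeros(len(envs)))
            acc[str(genus)] += row.reindex(envs).fillna(0).to_numpy()
    cols = [g for g in relevant_genera if g in acc]
    if "Other" in acc:
        cols.append("Other")
    mat = pd.DataFrame({g: acc[g] for g in cols}, index=envs)
    empty = mat.columns[mat.sum(axis=0) == 0]
    if len(empty):
        warnings.warn(f"genera with zero assigned reads dropped: {list(empty)}")
        mat = mat.drop(columns=empty)
    if normalize == "genus":
        mat = mat / mat.sum(axis=0)
    elif normalize == "source":
        mat = mat.div(mat.sum(axis=1), axis=0)
    else:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    return mat


def shared_source_clustering(matrix: pd.DataFrame) -> list[str]:
    """Order genera by shared-source similarity (average-linkage, Euclidean).

    Returns the leaf order of a hierarchical clustering of genus columns on
    their source-contribution vectors; deterministic for a given matrix.
    """
    genera = list(matrix.columns)
    if len(genera) < 2:
        return genera
    X = matrix.to_numpy().T  # genera x sources
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="average")
    order = hierarchy.leaves_list(Z)
    return [genera[i] for i in order]
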