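"""Bayesian source attribution by collapsed Gibbs sampling.

Each sink (meat) community is modelled as a mixture over V known source
environments plus one latent "Unknown" environment.  Known-source taxon
distributions are smoothed empirical profiles fixed from the source count
data; the Unknown source's taxon distribution is learned from the sink's
own reads during sampling.  A symmetric Dirichlet(beta) prior sits on the
sink's environment mixture over all V+1 environments.

The collapsed conditional for a sink read j carrying taxon t is

    P(z_j = v | z_-j) ∝ (m_tv + a1)/(sum_t m_tv + T a1) * (n_v^(-j) + beta)/(n - 1 + (V+1) beta)

for a known source v (m = source counts, T = taxa in the registry), and for
the Unknown source the first factor is replaced by
(u_t^(-j) + a2)/(u^(-j) + T a2) built from the reads currently assigned to
Unknown.  Posterior mixing proportions are the mean environment assignment
fractions over retained draws across independent restarts.

An exact enumeration oracle (:func:`enumerate_posterior_oracle`) sums the
same joint over every assignment vector and is used to validate the sampler
on tiny instances.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from math import lgamma
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._kernel import gibbs_sink_kernel
from .feature_table import FeatureTable, sample_substream
from .metadata import SampleMetadata

log = logging.getLogger(__name__)

UNKNOWN = "Unknown"

__all__ = [
    "GibbsConfig",
    "AttributionResult",
    "conditional_assignment_distribution",
    "source_profiles",
    "collapse_sources_by_env",
    "fit_sink",
    "track_all_sinks",
    "enumerate_posterior_oracle",
    "UNKNOWN",
]


@dataclass(frozen=True)
class GibbsConfig:
    """Sampler controls.

    alpha1 : pseudocount smoothing the known-source taxon profiles.
    alpha2 : pseudocount for the Unknown source's taxon distribution;
        larger values let Unknown absorb unexplained taxa more readily.
    beta : symmetric prior count on the sink's environment mixture,
        shared by all V+1 environments including Unknown.
    restarts, burnin_passes, draws_per_restart, delay_passes : chain
        schedule; retained draws = restarts * draws_per_restart.
    resample_source_profiles : draw a fresh Dirichlet(m_v + alpha1)
        realization of each source profile per restart instead of using the
        fixed smoothed profile (off by default so the sampler matches the
        enumeration oracle exactly).
    """

    alpha1: float = 0.001
    alpha2: float = 0.1
    beta: float = 10.0
    restarts: int = 10
    burnin_passes: int = 100
    draws_per_restart: int = 10
    delay_passes: int = 10
    seed: int = 0
    resample_source_profiles: bool = False

    def __post_init__(self) -> None:
        if self.alpha1 <= 0 or self.alpha2 <= 0 or self.beta <= 0:
            raise ValueError("alpha1, alpha2 and beta must be > 0")
        if self.restarts < 1 or self.draws_per_restart < 1:
            raise ValueError("restarts and draws_per_restart must be >= 1")
        if self.burnin_passes < 0 or self.delay_passes < 1:
            raise ValueError("burnin >= 0 and delay >= 1 required")


@dataclass(frozen=True)
class AttributionResult:
    """Posterior mixing proportions plus per-taxon assignment tallies.

    proportions : DataFrame sinks x (source envs + Unknown), posterior mean.
    proportions_sd : same shape, standard deviation over retained draws.
    taxon_assignments : per sink, DataFrame taxa x (source envs + Unknown)
        of mean assigned read counts; cells sum to the sink's depth.
    """

    proportions: pd.DataFrame
    proportions_sd: pd.DataFrame
    taxon_assignments: Mapping[str, pd.DataFrame] = field(repr=False)

    @property
    def environments(self) -> list[str]:
        return list(self.proportions.columns)

    @property
    def sink_ids(self) -> list[str]:
        return list(self.proportions.index)

    def write(self, prefix: str, write_assignments: bool = False) -> None:
        self.proportions.to_csv(f"{prefix}.tsv", sep="\t")
        self.proportions_sd.to_csv(f"{prefix}_sd.tsv", sep="\t")
        if write_assignments:
            for sid, df in self.taxon_assignments.items():
                df.to_csv(f"{prefix}_assignments_{sid}.tsv", sep="\t")


def source_profiles(source_counts: np.ndarray, alpha1: float) -> np.ndarray:
    """Smoothed per-source taxon probabilities: (m_tv + a1)/(sum + T a1).

    ``source_counts`` is (V, T): rows are environments, columns taxa.
    """
    m = np.asarray(source_counts, dtype=float)
    T = m.shape[1]
    return (m + alpha1) / (m.sum(axis=1, keepdims=True) + T * alpha1)


def conditional_assignment_distribution(
    taxon: int,
    counts_excluding_current: np.ndarray,
    source_profiles_matrix: np.ndarray,
    unknown_counts_excluding_current: np.ndarray,
    config: GibbsConfig,
    n: int,
    T: int,
) -> np.ndarray:
    """Full-conditional assignment distribution for one sink read.

    Parameters mirror the sampler state with the current read removed:
    ``counts_excluding_current`` is the (V+1,) per-environment assignment
    count vector (Unknown last) and ``unknown_counts_excluding_current`` the
    (T,) per-taxon counts currently on Unknown.  Returns a strictly positive
    probability vector over (sources..., Unknown).
    """
    phi = np.asarray(source_profiles_matrix, dtype=float)
    envc = np.asarray(counts_excluding_current, dtype=float)
    unk = np.asarray(unknown_counts_excluding_current, dtype=float)
    V = phi.shape[0]
    if envc.shape[0] != V + 1 or unk.shape[0] != T or phi.shape[1] != T:
        raise ValueError("dimension mismatch between counts, profiles and T")
    if envc.min() < 0 or unk.min() < 0:
        raise ValueError("counts must be non-negative")
    denom = n - 1 + (V + 1) * config.beta
    p = np.empty(V + 1)
    p[:V] = phi[:, taxon] * (envc[:V] + config.beta) / denom
    p[V] = (
        (unk[taxon] + config.alpha2)
        / (unk.sum() + T * config.alpha2)
        * (envc[V] + config.beta)
        / denom
    )
    return p / p.sum()


def collapse_sources_by_env(
    table: FeatureTable, metadata: SampleMetadata
) -> FeatureTable:
    """Sum source-sample columns into one column per source environment.

    Environment order follows first appearance among the table's source
    samples, so permuting unrelated samples never reorders result columns.
    """
    src = [s for s in table.sample_ids if s in set(metadata.source_ids)]
    if not src:
        raise ValueError("no source samples designated in table")
    env_order: list[str] = []
    cols: dict[str, np.ndarray] = {}
    for sid in src:
        env = metadata.env_of(sid)
        if env not in cols:
            env_order.append(env)
            cols[env] = np.zeros(table.n_taxa, dtype=np.int64)
        cols[env] += table.data[sid].to_numpy()
    return FeatureTable(
        pd.DataFrame({e: cols[e] for e in env_order}, index=table.taxon_ids)
    )


def _restart_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def fit_sink(
    sources: FeatureTable,
    sink_counts: pd.Series | np.ndarray,
    config: GibbsConfig,
    sink_id: str = "sink",
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Attribute one sink to the source environments of ``sources``.

    ``sources`` must have one column per source environment (see
    :func:`collapse_sources_by_env`) and a taxon registry aligned with
    ``sink_counts``.  Reads are expanded taxon-id-sorted, initialized
    uniformly at random over V+1 environments, then sampled with
    ``config.restarts`` independent chains.

    Returns
    -------
    (mean proportions, sd proportions, mean taxon-assignment counts), the
    Series indexed by environment (Unknown last), the DataFrame by taxa.
    """
    if sources.n_samples == 0:
        raise ValueError("empty source set")
    if isinstance(sink_counts, pd.Series):
        sink_counts = sink_counts.reindex(sources.taxon_ids).fillna(0)
        sink_vec = sink_counts.to_numpy()
    else:
        sink_vec = np.asarray(sink_counts)
    if sink_vec.shape[0] != sources.n_taxa:
        raise ValueError("sink counts not aligned with source taxa")
    sink_vec = sink_vec.astype(np.int64)
    n = int(sink_vec.sum())
    if n < 1:
        raise ValueError(f"sink {sink_id!r} has zero analyzed reads")
    envs = sources.sample_ids
    V, T = len(envs), sources.n_taxa
    m = sources.counts.T.astype(float)  # (V, T)
    phi_fixed = source_profiles(m, config.alpha1)

    # expand reads in taxon-id-sorted order
    order = np.argsort(np.asarray(sources.taxon_ids, dtype=object))
    read_taxon = np.repeat(order, sink_vec[order]).astype(np.int64)

    rng = sample_substream(config.seed, "fit_sink", sink_id)
    D = config.restarts * config.draws_per_restart
    all_props = np.empty((D, V + 1))
    assign_total = np.zeros((T, V + 1))
    for r in range(config.restarts):
        if config.resample_source_profiles:
            phi = np.vstack(
                [rng.dirichlet(m[v] + config.alpha1) for v in range(V)]
            )
            phi = np.maximum(phi, 1e-300)
        else:
            phi = phi_fixed
        kseed = _restart_seed(rng)
        props, assign = gibbs_sink_kernel(
            read_taxon,
            np.ascontiguousarray(phi),
            float(config.alpha2),
            float(config.beta),
            int(config.burnin_passes),
            int(config.draws_per_restart),
            int(config.delay_passes),
            kseed,
        )
        all_props[
            r * config.draws_per_restart : (r + 1) * config.draws_per_restart
        ] = props
        assign_total += assign
    labels = [*envs, UNKNOWN]
    mean = pd.Series(all_props.mean(axis=0), index=labels, name=sink_id)
    sd = pd.Series(all_props.std(axis=0, ddof=0), index=labels, name=sink_id)
    assignments = pd.DataFrame(
        assign_total / D, index=sources.taxon_ids, columns=labels
    )
    return mean, sd, assignments


def track_all_sinks(
    table: FeatureTable,
    metadata: SampleMetadata,
    config: GibbsConfig,
) -> AttributionResult:
    """Run :func:`fit_sink` for every designated sink sample independently.

    Per-sink random substreams are derived from the sink id, so results are
    identical whatever the execution order and whatever other sinks exist.
    """
    sources = collapse_sources_by_env(table, metadata)
    sinks = [s for s in table.sample_ids if s in set(metadata.sink_ids)]
    if not sinks:
        warnings.warn("no sink samples present in table; empty result")
        empty = pd.DataFrame(columns=[*sources.sample_ids, UNKNOWN])
        return AttributionResult(empty, empty.copy(), {})
    rows, sds, assigns = [], [], {}
    for sid in sinks:
        try:
            mean, sd, assign = fit_sink(
                sources, table.data[sid], config, sink_id=sid
            )
        except ValueError as exc:
            raise ValueError(f"sink {sid!r}: {exc}") from exc
        rows.append(mean)
        sds.append(sd)
        assigns[sid] = assign
    return AttributionResult(
        pd.DataFrame(rows), pd.DataFrame(sds), assigns
    )


# ---------------------------------------------------------------------------
# Exact enumeration oracle
# ---------------------------------------------------------------------------


def enumerate_posterior_oracle(
    sources: FeatureTable,
    sink_counts: pd.Series | np.ndarray,
    config: GibbsConfig,
    max_states: int = 2_000_000,
) -> pd.Series:
    """Exact posterior-mean proportions by summing over all assignments.

    The joint over an assignment vector z (marginalizing the environment
    mixture and the Unknown taxon distribution) is

        P(z) ∝ prod_{j: z_j known} phi[z_j, t_j]
               * prod_t Gamma(u_t + a2)/Gamma(a2) / Gamma(u + T a2)
               * prod_v Gamma(n_v + beta)

    with u_t the Unknown per-taxon counts and n_v the environment counts.
    Feasible only for tiny instances: (V+1)^n must not exceed ``max_states``.
    """
    if isinstance(sink_counts, pd.Series):
        sink_counts = sink_counts.reindex(sources.taxon_ids).fillna(0)
        sink_vec = sink_counts.to_numpy().astype(int)
    else:
        sink_vec = np.asarray(sink_counts, dtype=int)
    n = int(sink_vec.sum())
    V, T = sources.n_samples, sources.n_taxa
    E = V + 1
    n_states = E**n
    if n_states > max_states:
        raise ValueError(
            f"(V+1)^n = {n_states} exceeds enumeration bound {max_states}"
        )
    order = np.argsort(np.asarray(sources.taxon_ids, dtype=object))
    read_taxon = np.repeat(order, sink_vec[order])
    phi = source_profiles(sources.counts.T.astype(float), config.alpha1)
    log_phi = np.log(phi)
    a2, beta = config.alpha2, config.beta
    logw = np.empty(n_states)
    env_counts = np.empty((n_states, E), dtype=int)
    for idx, z in enumerate(itertools.product(range(E), repeat=n)):
        nv = np.zeros(E, dtype=int)
        ut = np.zeros(T, dtype=int)
        lw = 0.0
        for j, v in enumerate(z):
            nv[v] += 1
            t = read_taxon[j]
            if v < V:
                lw += log_phi[v, t]
            else:
                ut[t] += 1
        u = ut.sum()
        lw += sum(lgamma(c + a2) - lgamma(a2) for c in ut if c)
        lw += lgamma(T * a2) - lgamma(u + T * a2)
        lw += sum(lgamma(c + beta) - lgamma(beta) for c in nv)
        logw[idx] = lw
        env_counts[idx] = nv
    w = np.exp(logw - logw.max())
    w /= w.sum()
    props = (w[:, None] * env_counts).sum(axis=0) / n
    return pd.Series(props, index=[*sources.sample_ids, UNKNOWN])
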