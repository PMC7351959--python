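"""Numba-jitted collapsed Gibbs sweep for sink-read source assignment.

The kernel is deliberately minimal: all model preparation (profile
smoothing, read expansion, seeding, restart orchestration) happens in
:mod:`sinktrack.gibbs`; here we only loop.  The conditional sampled for
read j carrying taxon t is

    P(z_j = v | rest) ~ phi[v, t] * (n_v^(-j) + beta)              known v
    P(z_j = U | rest) ~ (u_t^(-j) + a2) / (u^(-j) + T a2)
                        * (n_U^(-j) + beta)                        unknown

where phi holds the smoothed known-source taxon probabilities, n_v the
per-environment assignment counts and u_t the unknown source's per-taxon
counts.  The shared denominator (n - 1 + (V+1) beta) cancels.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def gibbs_sink_kernel(
    read_taxon: np.ndarray,  # (n,) int64 taxon index per read
    phi: np.ndarray,  # (V, T) float64 smoothed source profiles
    alpha2: float,
    beta: float,
    burnin: int,
    draws: int,
    delay: int,
    seed: int,
):
    """One restart: burn in, then retain ``draws`` draws ``delay`` sweeps apart.

    Returns (prop_draws (draws, V+1), assign_sum (T, V+1)) where assign_sum
    accumulates per-(taxon, environment) assignment counts over the retained
    draws.
    """
    np.random.seed(seed)
    n = read_taxon.shape[0]
    V = phi.shape[0]
    T = phi.shape[1]
    E = V + 1
    z = np.empty(n, dtype=np.int64)
    envcounts = np.zeros(E, dtype=np.float64)
    unk = np.zeros(T, dtype=np.float64)
    unk_total = 0.0
    prop_draws = np.zeros((draws, E), dtype=np.float64)
    assign_sum = np.zeros((T, E), dtype=np.float64)
    for j in range(n):
        v = np.random.randint(0, E)
        z[j] = v
        envcounts[v] += 1.0
        if v == V:
            unk[read_taxon[j]] += 1.0
            unk_total += 1.0
    p = np.empty(E, dtype=np.float64)
    total_sweeps = burnin + draws * delay
    d = 0
    for sweep in range(total_sweeps):
        for j in range(n):
            t = read_taxon[j]
            v0 = z[j]
            envcounts[v0] -= 1.0
            if v0 == V:
                unk[t] -= 1.0
                unk_total -= 1.0
            s = 0.0
            for v in range(V):
                pv = phi[v, t] * (envcounts[v] + beta)
                p[v] = pv
                s += pv
            pu = (
                (unk[t] + alpha2)
                / (unk_total + T * alpha2)
                * (envcounts[V] + beta)
            )
            p[V] = pu
            s += pu
            r = np.random.random() * s
            acc = 0.0
            vnew = E - 1
            for v in range(E):
                acc += p[v]
                if r < acc:
                    vnew = v
                    break
            z[j] = vnew
            envcounts[vnew] += 1.0
            if vnew == V:
                unk[t] += 1.0
                unk_total += 1.0
        if sweep >= burnin and (sweep - burnin + 1) % delay == 0 and d < draws:
            for v in range(E):
                prop_draws[d, v] = envcounts[v] / n
            for j in range(n):
                assign_sum[read_taxon[j], z[j]] += 1.0
            d += 1
    return prop_draws, assign_sum
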