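# sinktrack

Bayesian microbial source tracking for food-facility hygiene surveillance.

When pork carcasses move down a slaughter line, the bacteria found on the
meat at the end were transferred somewhere along the way — from gloves,
knives, polishing whips, railings, the animals' own skin. Given 16S rRNA
amplicon (ASV) count tables from environmental swabs (**sources**) and meat
samples (**sinks**), `sinktrack` estimates, for each sink, what fraction of
its community came from each sampled source environment and how much cannot
be explained by any of them. It also quantifies how robust those estimates
are to sequencing depth, and ships a synthetic facility generator with
known ground truth so every stage can be validated end to end.

## The model

Each sink community with reads $x_1,\dots,x_n$ (read $j$ carries taxon
$t_j$) is modelled as a mixture over $V$ known source environments plus one
latent *Unknown* environment. Known-source taxon distributions are smoothed
empirical profiles $\phi_{v}$ fixed from the source counts $m_{tv}$; the
Unknown source's distribution is learned from the sink itself. With a
symmetric Dirichlet($\beta$) prior on the environment mixture, the
collapsed Gibbs conditional for read $j$ is

$$P(z_j = v \mid z_{-j}) \propto \frac{m_{t_j v} + \alpha_1}{\sum_t m_{tv} + T\alpha_1}\cdot\frac{n_v^{(-j)} + \beta}{n - 1 + (V{+}1)\beta}$$

for a known source $v$, while for the Unknown source the first factor is
replaced by $(u_{t_j}^{(-j)} + \alpha_2)\,/\,(u^{(-j)} + T\alpha_2)$, built
from the reads currently assigned to Unknown. Posterior mixing proportions
are averaged over retained draws across independent restarts (defaults:
$\alpha_1 = 0.001$, $\alpha_2 = 0.1$, $\beta = 10$, 10 restarts, 100
burn-in sweeps). An exact enumeration oracle over all $(V{+}1)^n$
assignment vectors validates the sampler on small instances.

Around the sampler sits the full analysis chain: classic OTU-table /
BIOM-JSON I/O, the low-yield filter (samples < 200 reads, taxa < 5 reads),
prevalence-based decontamination against negative controls (threshold 0.5),
seeded rarefaction, flow-table and genus x source summaries, alpha/beta
diversity, BCE conversion for qPCR counts, and the depth-robustness
experiment: rarefy to a ladder of depths (7712 / 5000 / 1000 / 500 / 200 by
default, 3 replicates each, 10 at the smallest), re-attribute, and compare
to the full-depth reference via mean squared differences, Spearman
correlation, hit ratio, and unknown-rate shifts, with Kruskal–Wallis +
Dunn/Benjamini–Hochberg testing across depths.

## Worked example

```python
import sinktrack as st
from sinktrack.synthetic import FacilityDesign, generate_dataset

design = FacilityDesign(sinks_per_position=2,
                        source_depth_range=(8000, 12000),
                        sink_depth_range=(5000, 5000),
                        n_controls=0, contaminant_spike_fraction=0.0)
table, metadata, taxonomy, truth = generate_dataset(design, seed=11)
result = st.track_all_sinks(table, metadata, st.GibbsConfig(seed=11))
```

For the first sink this prints (see `examples/02_source_tracking.py`):

```
mixing proportions for sink Meat_Sticking_01 (rows are source environments):
                       estimated   true
Skin Sticking              0.171  0.178
Polishing Water            0.160  0.171
Gloves Classification      0.319  0.330
Unknown                    0.310  0.321

mean absolute proportion error over all 12 sinks: 0.0063
```

Each row is the fraction of that meat sample's community attributed to one
source environment; `Unknown` is the mass no sampled source explains. The
generator recorded the true weights, so the 0.0063 mean absolute error
measures genuine recovery, not self-agreement. The other scripts in
`examples/` demonstrate filtering/decontamination, the depth-robustness
ladder, and the diversity/bench-count statistics, one capability each.

A thin CLI wraps the same calls:

```bash
sinktrack simulate --out sim --seed 2
sinktrack run-all --table sim/table.tsv --metadata sim/metadata.tsv \
    --taxonomy sim/taxonomy.tsv --out run --seed 2
sinktrack depth-eval --table sim/table.tsv --metadata sim/metadata.tsv \
    --out depth.tsv --seed 2
```

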