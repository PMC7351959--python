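"""Synthetic meat-processing-facility datasets with known ground truth.

The generator emulates the structure of a facility surveillance study:
~15 environmental source positions sampled along a slaughter line, meat
(sink) samples taken at 6 ordered processing positions, per-sample
sequencing depths spanning a wide range, sink communities composed as
mixtures of a few source communities plus an "unknown" community whose
taxa are partly absent from every source, and negative-control samples
dominated by contaminant taxa that can also bleed into true samples at low
weight.  The exact source profiles, sink mixing weights and contaminant
set are recorded as :class:`SyntheticTruth`, so every downstream estimate
can be scored against a known answer.

Source profiles are symmetric-Dirichlet draws (small concentration gives
the sparse, location-specific profiles typical of facility surfaces);
sample counts are multinomial at log-uniformly drawn depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, sample_substream
from .gibbs import UNKNOWN
from .metadata import SampleMetadata, Taxonomy

__all__ = ["FacilityDesign", "SyntheticTruth", "generate_sources",
           "generate_sinks", "generate_negative_controls", "generate_dataset"]

SOURCE_ENV_NAMES = [
    "Anal Swab", "Skin Sticking", "Singeing Oven", "Polishing Whips",
    "Polishing Nozzles", "Polishing Water", "Gloves Evisceration",
    "Knives Evisceration", "Aprons Evisceration", "Railing Classification",
    "Gloves Classification", "Wall Cooling", "Lock", "Splitting Saw",
    "Scalding Tank",
]

SINK_POSITIONS = [
    "Sticking", "Singeing", "Polishing", "Evisceration", "Classification",
    "Truck",
]


@dataclass(frozen=True)
class FacilityDesign:
    """Shape and noise parameters of the simulated facility.

    Defaults mirror a mid-size surveillance campaign: 15 source
    environments with 5 replicate swabs each, 12 tracked carcasses sampled
    at 6 line positions, 300 taxa, sparse Dirichlet(0.1) source profiles,
    an unknown mixture weight between 0.1 and 0.4, and library sizes
    log-uniform between 200 and 30,000 reads.
    """

    n_sources: int = 15
    samples_per_source: int = 5
    n_sink_positions: int = 6
    sinks_per_position: int = 12
    n_taxa: int = 300
    concentration: float = 0.1
    unknown_weight_range: tuple[float, float] = (0.1, 0.4)
    depth_range: tuple[int, int] = (200, 30000)
    source_depth_range: tuple[int, int] | None = None
    sink_depth_range: tuple[int, int] | None = None
    sources_per_sink: int = 3
    n_controls: int = 3
    control_depth: int = 1000
    n_contaminants: int = 8
    contaminant_spike_fraction: float = 0.25
    contaminant_spike_weight: float = 0.02
    control_background_weight: float = 0.0
    unknown_exclusive_fraction: float = 0.10
    unknown_exclusive_mass: float = 0.5
    n_genera: int = 40

    def __post_init__(self) -> None:
        for name in ("n_sources", "samples_per_source", "n_sink_positions",
                     "sinks_per_position", "n_taxa", "n_genera"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for rng_name in ("unknown_weight_range", "depth_range"):
            lo, hi = getattr(self, rng_name)
            if lo > hi:
                raise ValueError(f"{rng_name} must be well-ordered")
        if not 0 <= self.unknown_exclusive_fraction < 1:
            raise ValueError("unknown_exclusive_fraction must be in [0, 1)")
        if self.sources_per_sink > self.n_sources:
            raise ValueError("sources_per_sink exceeds n_sources")

    @property
    def taxon_ids(self) -> list[str]:
        return [f"ASV_{i:04d}" for i in range(1, self.n_taxa + 1)]

    @property
    def source_envs(self) -> list[str]:
        base = list(SOURCE_ENV_NAMES)
        while len(base) < self.n_sources:
            base.append(f"Extra Source {len(base) + 1}")
        return base[: self.n_sources]

    @property
    def sink_positions(self) -> list[str]:
        base = list(SINK_POSITIONS)
        while len(base) < self.n_sink_positions:
            base.append(f"Position {len(base) + 1}")
        return base[: self.n_sink_positions]


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generator (sufficient for every check)."""

    source_profiles: pd.DataFrame  # envs x taxa, rows sum to 1
    unknown_profile: pd.Series  # taxa, sums to 1
    sink_mixtures: pd.DataFrame = field(
        default_factory=pd.DataFrame
    )  # sinks x (envs + Unknown)
    contaminant_taxa: list[str] = field(default_factory=list)
    depth_map: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not np.allclose(self.source_profiles.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("source profiles must sum to 1")
        if abs(self.unknown_profile.sum() - 1.0) > 1e-9:
            raise ValueError("unknown profile must sum to 1")
        if len(self.sink_mixtures) and not np.allclose(
            self.sink_mixtures.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("sink mixtures must sum to 1")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.source_profiles.to_csv(outdir / "truth_profiles.tsv", sep="\t")
        self.sink_mixtures.to_csv(outdir / "truth_mixtures.tsv", sep="\t")
        pd.Series(self.depth_map, name="depth").to_csv(
            outdir / "truth_depths.tsv", sep="\t"
        )
        with open(outdir / "truth_contaminants.tsv", "w") as fh:
            fh.write("\n".join(self.contaminant_taxa) + "\n")


def _draw_depth(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return int(lo)
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def _taxon_partition(design: FacilityDesign) -> tuple[list[str], list[str], list[str]]:
    """(contaminant taxa, unknown-exclusive taxa, shared taxa) — disjoint."""
    ids = design.taxon_ids
    n_cont = min(design.n_contaminants, design.n_taxa // 4)
    n_excl = int(round(design.unknown_exclusive_fraction * design.n_taxa))
    cont = ids[:n_cont]
    excl = ids[n_cont : n_cont + n_excl]
    shared = ids[n_cont + n_excl :]
    return cont, excl, shared


def generate_sources(
    design: FacilityDesign, seed: int
) -> tuple[FeatureTable, SyntheticTruth, SampleMetadata]:
    """Draw source profiles and replicate source-sample counts.

    Each source environment's taxon profile is a symmetric
    Dirichlet(concentration) draw over the shared taxon pool (contaminant
    and unknown-exclusive taxa stay at zero); each replicate swab is a
    multinomial draw at a log-uniform depth.  The unknown community's
    profile is drawn at the same time: a configurable share of its mass
    sits on taxa no source carries, the rest overlaps the shared pool.
    """
    rng = sample_substream(seed, "sources")
    ids = design.taxon_ids
    cont, excl, shared = _taxon_partition(design)
    shared_idx = [ids.index(t) for t in shared]
    excl_idx = [ids.index(t) for t in excl]
    envs = design.source_envs
    lo, hi = design.source_depth_range or design.depth_range

    profiles = np.zeros((design.n_sources, design.n_taxa))
    for v in range(design.n_sources):
        draw = rng.dirichlet(np.full(len(shared_idx), design.concentration))
        profiles[v, shared_idx] = draw
    prof_df = pd.DataFrame(profiles, index=envs, columns=ids)

    # unknown community: part exclusive support, part overlapping
    unknown = np.zeros(design.n_taxa)
    if excl_idx and design.unknown_exclusive_mass > 0:
        unknown[excl_idx] = design.unknown_exclusive_mass * rng.dirichlet(
            np.full(len(excl_idx), 1.0)
        )
        overlap_mass = 1.0 - design.unknown_exclusive_mass
    else:
        overlap_mass = 1.0
    if overlap_mass > 0:
        overlap = rng.dirichlet(np.full(len(shared_idx), design.concentration))
        unknown[shared_idx] += overlap_mass * overlap
    unknown /= unknown.sum()
    unknown_s = pd.Series(unknown, index=ids, name="unknown_profile")

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    depth_map: dict[str, int] = {}
    for v, env in enumerate(envs):
        for r in range(design.samples_per_source):
            sid = f"Src{v + 1:02d}R{r + 1}"
            depth = _draw_depth(rng, lo, hi)
            cols[sid] = rng.multinomial(depth, profiles[v])
            depth_map[sid] = depth
            meta_rows.append((sid, "source", env, pd.NA, "surface"))
    table = FeatureTable(pd.DataFrame(cols, index=ids))
    meta = SampleMetadata(
        pd.DataFrame(
            [r[1:] for r in meta_rows],
            index=[r[0] for r in meta_rows],
            columns=["role", "env", "position", "sample_type"],
        )
    )
    truth = SyntheticTruth(
        source_profiles=prof_df,
        unknown_profile=unknown_s,
        contaminant_taxa=list(cont),
        depth_map=depth_map,
        seed=seed,
    )
    truth.validate()
    return table, truth, meta


def generate_sinks(
    design: FacilityDesign,
    truth: SyntheticTruth,
    seed: int,
    mixtures: pd.DataFrame | None = None,
) -> tuple[FeatureTable, SampleMetadata]:
    """Draw sink (meat) samples as source mixtures plus the unknown community.

    Per sink, ``sources_per_sink`` contributing environments are chosen at
    random; their weights are Dirichlet(1) scaled to 1 minus an unknown
    weight drawn uniformly from ``unknown_weight_range``.  Pass
    ``mixtures`` (sinks x (envs + Unknown), rows summing to 1) to fix the
    weights instead; they are recorded verbatim in the truth.
    """
    rng = sample_substream(seed, "sinks")
    envs = list(truth.source_profiles.index)
    ids = list(truth.source_profiles.columns)
    lo, hi = design.sink_depth_range or design.depth_range
    positions = design.sink_positions

    sink_ids: list[str] = []
    weight_rows: list[np.ndarray] = []
    if mixtures is not None:
        bad = np.abs(mixtures.sum(axis=1) - 1.0) > 1e-9
        if bad.any():
            raise ValueError(
                f"mixture weights must sum to 1 (bad: {list(mixtures.index[bad])})"
            )
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    profmat = truth.source_profiles.to_numpy()
    unknown = truth.unknown_profile.to_numpy()
    k = 0
    for pos in positions:
        for i in range(design.sinks_per_position):
            sid = f"Meat_{pos.replace(' ', '')}_{i + 1:02d}"
            if mixtures is not None:
                w_full = (
                    mixtures.loc[sid]
                    if sid in mixtures.index
                    else mixtures.iloc[k % len(mixtures)]
                )
                w = w_full.reindex([*envs, UNKNOWN]).fillna(0.0).to_numpy()
            else:
                w_u = rng.uniform(*design.unknown_weight_range)
                chosen = rng.choice(
                    design.n_sources, size=design.sources_per_sink, replace=False
                )
                w = np.zeros(len(envs) + 1)
                w[chosen] = (1.0 - w_u) * rng.dirichlet(
                    np.ones(design.sources_per_sink)
                )
                w[-1] = w_u
            composition = w[:-1] @ profmat + w[-1] * unknown
            depth = _draw_depth(rng, lo, hi)
            cols[sid] = rng.multinomial(depth, composition / composition.sum())
            truth.depth_map[sid] = depth
            sink_ids.append(sid)
            weight_rows.append(w)
            meta_rows.append((sid, "sink", f"Meat {pos}", pos, "meat"))
            k += 1
    truth.sink_mixtures = pd.DataFrame(
        weight_rows, index=sink_ids, columns=[*envs, UNKNOWN]
    )
    truth.validate()
    table = FeatureTable(pd.DataFrame(cols, index=ids))
    meta = SampleMetadata(
        pd.DataFrame(
            [r[1:] for r in meta_rows],
            index=[r[0] for r in meta_rows],
            columns=["role", "env", "position", "sample_type"],
        )
    )
    return table, meta


def generate_negative_controls(
    design: FacilityDesign,
    truth: SyntheticTruth,
    table: FeatureTable,
    seed: int,
) -> tuple[FeatureTable, SampleMetadata | None]:
    """Append negative-control samples and spike contaminants into true samples.

    Controls draw their reads predominantly from the contaminant community
    (an even Dirichlet(5) profile over the contaminant taxa, mimicking
    reagent contaminants that recur across blanks); setting
    ``control_background_weight`` > 0 additionally mixes in the average
    source community to model sample-to-blank cross-talk.  A configurable
    fraction of true samples receives a low-weight contaminant spike so the
    prevalence filter has genuine work; with
    ``contaminant_spike_fraction = 0`` contaminants appear only in controls.
    """
    if design.n_controls == 0:
        truth.contaminant_taxa = []
        return table, None
    if design.control_depth < 1:
        raise ValueError("control_depth must be >= 1")
    rng = sample_substream(seed, "controls")
    ids = table.taxon_ids
    cont_idx = [ids.index(t) for t in truth.contaminant_taxa]
    if not cont_idx:
        raise ValueError("design requests controls but no contaminant taxa exist")
    cont_profile = np.zeros(len(ids))
    cont_profile[cont_idx] = rng.dirichlet(np.full(len(cont_idx), 5.0))
    background = truth.source_profiles.to_numpy().mean(axis=0)

    data = table.data.copy()
    # spike a fraction of true samples
    if design.contaminant_spike_fraction > 0 and design.contaminant_spike_weight > 0:
        n_spike = int(round(design.contaminant_spike_fraction * table.n_samples))
        spiked = rng.choice(table.n_samples, size=n_spike, replace=False)
        for j in spiked:
            sid = table.sample_ids[j]
            depth = int(data[sid].sum())
            extra = max(
                1, int(round(depth * design.contaminant_spike_weight
                             / (1 - design.contaminant_spike_weight)))
            )
            data[sid] = data[sid].to_numpy() + rng.multinomial(extra, cont_profile)
    meta_rows = []
    w_b = design.control_background_weight
    for i in range(design.n_controls):
        sid = f"NegCtrl{i + 1}"
        comp = (1.0 - w_b) * cont_profile + w_b * background
        data[sid] = rng.multinomial(design.control_depth, comp / comp.sum())
        truth.depth_map[sid] = design.control_depth
        meta_rows.append((sid, "negative_control", "Negative Control", pd.NA,
                          "control"))
    meta = SampleMetadata(
        pd.DataFrame(
            [r[1:] for r in meta_rows],
            index=[r[0] for r in meta_rows],
            columns=["role", "env", "position", "sample_type"],
        )
    )
    return FeatureTable(data), meta


def _genus_partition(design: FacilityDesign, seed: int) -> pd.Series:
    """Taxa -> synthetic genus labels with geometric-ish genus sizes."""
    rng = sample_substream(seed, "genera")
    ids = design.taxon_ids
    p = min(0.95, design.n_genera / design.n_taxa)
    sizes = []
    total = 0
    g = 0
    while total < design.n_taxa:
        size = int(rng.geometric(p))
        if g >= design.n_genera - 1:
            size = design.n_taxa - total
        size = min(size, design.n_taxa - total)
        sizes.append(size)
        total += size
        g += 1
    labels = {}
    start = 0
    perm = rng.permutation(design.n_taxa)
    for gi, size in enumerate(sizes):
        for t in perm[start : start + size]:
            labels[ids[t]] = f"Genus_{gi + 1:03d}"
        start += size
    return pd.Series(labels).reindex(ids)


def make_taxonomy(design: FacilityDesign, seed: int) -> Taxonomy:
    genus = _genus_partition(design, seed)
    lineages = {}
    for tid, g in genus.items():
        num = int(str(g).split("_")[1])
        lineages[tid] = (
            f"Bacteria;Phylum_{(num - 1) % 5 + 1};Class_{(num - 1) % 9 + 1};"
            f"Order_{(num - 1) % 13 + 1};Family_{(num - 1) % 17 + 1};{g};{tid}"
        )
    return Taxonomy(pd.Series(lineages))


def generate_dataset(
    design: FacilityDesign, seed: int,
    mixtures: pd.DataFrame | None = None,
) -> tuple[FeatureTable, SampleMetadata, Taxonomy, SyntheticTruth]:
    """One-call composition: sources + sinks + controls + taxonomy + truth."""
    src_table, truth, src_meta = generate_sources(design, seed)
    sink_table, sink_meta = generate_sinks(design, truth, seed, mixtures=mixtures)
    combined = FeatureTable(
        pd.concat([src_table.data, sink_table.data], axis=1)
    )
    meta_frames = [src_meta.data, sink_meta.data]
    combined, ctl_meta = generate_negative_controls(design, truth, combined, seed)
    if ctl_meta is not None:
        meta_frames.append(ctl_meta.data)
    metadata = SampleMetadata(pd.concat(meta_frames, axis=0))
    taxonomy = make_taxonomy(design, seed)
    truth.validate()
    return combined, metadata, taxonomy, truth
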