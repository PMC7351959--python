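"""ASV/feature count tables: data model, readers/writers, filtering and rarefaction.

The count table (taxa x samples) is the currency of the whole pipeline: every
downstream stage (decontamination, source attribution, diversity, the depth
robustness experiment) consumes and produces :class:`FeatureTable` objects.
Counts are always non-negative integers; a column sum is the library size of
that sample and is recomputed on demand, never cached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "read_feature_table",
    "write_feature_table",
    "filter_low_yield",
    "prevalence_contaminant_filter",
    "rarefy",
    "sample_substream",
]


class FeatureTableError(ValueError):
    """Raised for malformed tables or filters that empty them."""


@dataclass(frozen=True)
class FeatureTable:
    """Non-negative integer count matrix with taxon (row) and sample (column) ids.

    Parameters
    ----------
    data : pandas.DataFrame
        Integer counts, index = taxon ids, columns = sample ids.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FeatureTableError(f"duplicate taxon id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise FeatureTableError(f"duplicate sample id: {dup!r}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise FeatureTableError("counts must be finite integers")
            object.__setattr__(self, "data", df.astype(np.int64))
            arr = self.data.to_numpy()
        if arr.size and arr.min() < 0:
            r, c = np.unravel_index(np.argmin(arr), arr.shape)
            raise FeatureTableError(
                f"negative count at taxon {df.index[r]!r}, sample {df.columns[c]!r}"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        """Library size per sample (column sums), recomputed each call."""
        return self.data.sum(axis=0)

    def taxon_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise FeatureTableError(f"unknown sample ids: {missing}")
        return FeatureTable(self.data.loc[:, list(sample_ids)].copy())

    def select_taxa(self, taxon_ids: Sequence[str]) -> "FeatureTable":
        missing = [t for t in taxon_ids if t not in self.data.index]
        if missing:
            raise FeatureTableError(f"unknown taxon ids: {missing}")
        return FeatureTable(self.data.loc[list(taxon_ids)].copy())

    def drop_taxa(self, taxon_ids: Iterable[str]) -> "FeatureTable":
        drop = set(taxon_ids)
        keep = [t for t in self.data.index if t not in drop]
        return FeatureTable(self.data.loc[keep].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.data.equals(other.data)


def from_arrays(
    counts: np.ndarray, taxon_ids: Sequence[str], sample_ids: Sequence[str]
) -> FeatureTable:
    """Build a table from a matrix plus id registries (validated)."""
    counts = np.asarray(counts)
    if counts.shape != (len(taxon_ids), len(sample_ids)):
        raise FeatureTableError(
            f"shape {counts.shape} does not match {len(taxon_ids)} taxa x "
            f"{len(sample_ids)} samples"
        )
    return FeatureTable(
        pd.DataFrame(counts, index=list(taxon_ids), columns=list(sample_ids))
    )


# ---------------------------------------------------------------------------
# I/O: classic OTU-table TSV and minimal dense BIOM-JSON
# ---------------------------------------------------------------------------

_CLASSIC_HEADER = "#OTU ID"


def read_feature_table(
    path: str | Path, dialect: str = "classic_tsv"
) -> tuple[FeatureTable, pd.Series | None]:
    """Read a count table.

    ``classic_tsv`` is the tab-separated OTU-table dialect: first header cell
    ``#OTU ID``, taxa as rows.  A trailing column named ``taxonomy`` is split
    off and returned as a Series (taxon id -> lineage string) instead of being
    kept in the matrix.  ``biom_json`` is the minimal dense BIOM 1.0 JSON
    variant.

    Returns
    -------
    (FeatureTable, taxonomy or None)
    """
    path = Path(path)
    if dialect == "classic_tsv":
        return _read_classic_tsv(path)
    if dialect == "biom_json":
        return _read_biom_json(path), None
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_classic_tsv(path: Path) -> tuple[FeatureTable, pd.Series | None]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    # tolerate a leading "# Constructed from biom file" comment line
    while lines and not lines[0].startswith(_CLASSIC_HEADER):
        if lines[0].startswith("#"):
            lines.pop(0)
        else:
            raise FeatureTableError(
                f"{path}: expected header starting with {_CLASSIC_HEADER!r}"
            )
    if not lines:
        raise FeatureTableError(f"{path}: no header line")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    has_tax = bool(sample_ids) and sample_ids[-1].lower() == "taxonomy"
    if has_tax:
        sample_ids = sample_ids[:-1]
    rows: list[list[int]] = []
    taxa: list[str] = []
    lineages: dict[str, str] = {}
    for ln in lines[1:]:
        cells = ln.split("\t")
        tid = cells[0]
        body = cells[1:]
        if has_tax:
            lineages[tid] = body[-1]
            body = body[:-1]
        if len(body) != len(sample_ids):
            raise FeatureTableError(
                f"{path}: row {tid!r} has {len(body)} cells, expected {len(sample_ids)}"
            )
        vals = []
        for sid, cell in zip(sample_ids, body):
            try:
                v = float(cell)
            except ValueError:
                raise FeatureTableError(
                    f"{path}: non-numeric count at taxon {tid!r}, sample {sid!r}: {cell!r}"
                ) from None
            if v < 0 or v != int(v):
                raise FeatureTableError(
                    f"{path}: invalid count at taxon {tid!r}, sample {sid!r}: {cell!r}"
                )
            vals.append(int(v))
        taxa.append(tid)
        rows.append(vals)
    if not taxa:
        raise FeatureTableError(f"{path}: no taxa")
    table = from_arrays(np.asarray(rows, dtype=np.int64), taxa, sample_ids)
    return table, (pd.Series(lineages, name="taxonomy") if has_tax else None)


def _read_biom_json(path: Path) -> FeatureTable:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise FeatureTableError(f"{path}: only dense BIOM-JSON supported")
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    if not taxa:
        raise FeatureTableError(f"{path}: no taxa")
    data = np.asarray(doc["data"])
    return from_arrays(data, taxa, samples)


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    dialect: str = "classic_tsv",
    taxonomy: pd.Series | None = None,
) -> None:
    """Write a table in the same dialects :func:`read_feature_table` accepts."""
    path = Path(path)
    if dialect == "classic_tsv":
        with open(path, "w") as fh:
            cols = list(table.sample_ids)
            header = [_CLASSIC_HEADER, *cols]
            if taxonomy is not None:
                header.append("taxonomy")
            fh.write("\t".join(header) + "\n")
            for tid, row in table.data.iterrows():
                cells = [str(tid), *(str(int(v)) for v in row)]
                if taxonomy is not None:
                    cells.append(str(taxonomy.get(tid, "")))
                fh.write("\t".join(cells) + "\n")
    elif dialect == "biom_json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "sinktrack",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_low_yield(
    table: FeatureTable,
    min_sample_reads: int = 200,
    min_taxon_reads: int = 5,
) -> FeatureTable:
    """Drop shallow samples, then rare taxa.

    Samples with library size below ``min_sample_reads`` are removed first;
    taxa whose total count over the *remaining* samples is below
    ``min_taxon_reads`` are removed second.  One pass, no iteration to a
    fixpoint, so the operation is idempotent.
    """
    if min_sample_reads < 0 or min_taxon_reads < 0:
        raise ValueError("thresholds must be >= 0")
    sums = table.sample_sums()
    keep_samples = sums[sums >= min_sample_reads].index
    if len(keep_samples) == 0:
        raise FeatureTableError("no samples survive filtering")
    sub = table.data.loc[:, keep_samples]
    tax_sums = sub.sum(axis=1)
    keep_taxa = tax_sums[tax_sums >= min_taxon_reads].index
    n_s = table.n_samples - len(keep_samples)
    n_t = table.n_taxa - len(keep_taxa)
    if n_s or n_t:
        log.info("filter_low_yield removed %d samples and %d taxa", n_s, n_t)
    return FeatureTable(sub.loc[keep_taxa].copy())


def prevalence_contaminant_filter(
    table: FeatureTable,
    is_control: pd.Series | Sequence[bool],
    threshold: float = 0.5,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Prevalence-based contaminant identification against negative controls.

    For each taxon a 2x2 presence/absence table (present/absent x
    control/true sample) is scored with a one-sided Fisher exact test for the
    alternative "more prevalent in controls".  Taxa with score below
    ``threshold`` *and* control prevalence strictly above true-sample
    prevalence are flagged and removed.  The direction gate means an abundant
    genuine taxon can never be flagged just for being ubiquitous.

    Parameters
    ----------
    is_control : boolean per sample (aligned to ``table.sample_ids``), True
        marks a negative-control sample.

    Returns
    -------
    (filtered table, DataFrame of flagged taxa with columns
    ``score``, ``prev_control``, ``prev_sample``)
    """
    mask = np.asarray(
        is_control.reindex(table.sample_ids)
        if isinstance(is_control, pd.Series)
        else is_control,
        dtype=bool,
    )
    if mask.shape[0] != table.n_samples:
        raise FeatureTableError("is_control must align with table samples")
    n_ctl = int(mask.sum())
    n_true = int((~mask).sum())
    if n_ctl == 0:
        raise FeatureTableError(
            "no negative controls present; skip the decontamination step"
        )
    if n_true == 0:
        raise FeatureTableError("no non-control samples present")
    present = table.counts > 0
    k_ctl = present[:, mask].sum(axis=1)
    k_true = present[:, ~mask].sum(axis=1)
    records = []
    for i, tid in enumerate(table.taxon_ids):
        a, b = int(k_ctl[i]), int(k_true[i])
        prev_c = a / n_ctl
        prev_s = b / n_true
        if prev_c <= prev_s:
            continue
        # one-sided exact test: P(control presences >= a) under hypergeometric
        _, p = stats.fisher_exact(
            [[a, n_ctl - a], [b, n_true - b]], alternative="greater"
        )
        if p < threshold:
            records.append((tid, float(p), prev_c, prev_s))
    flagged = pd.DataFrame(
        records, columns=["taxon_id", "score", "prev_control", "prev_sample"]
    ).set_index("taxon_id")
    if len(flagged):
        log.info("prevalence filter flagged %d contaminant taxa", len(flagged))
    return table.drop_taxa(flagged.index), flagged


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def sample_substream(master_seed: int, *context: object) -> np.random.Generator:
    """Derive an independent, reproducible random stream for one unit of work.

    Context items (sample id, depth, replicate index, ...) are hashed with
    blake2b so adding or reordering *other* samples never perturbs this
    stream's draws.
    """
    h = hashlib.blake2b(digest_size=8)
    for item in context:
        h.update(repr(item).encode())
        h.update(b"\x00")
    key = int.from_bytes(h.digest()[:4], "big")
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([int(master_seed), key]))
    )


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Uniform without-replacement subsampling to exactly ``depth`` reads.

    Samples whose library size is below ``depth`` are dropped (logged).
    Each surviving sample's subsample is drawn from its own substream, so
    results per sample are invariant to the presence of other samples.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    sums = table.sample_sums()
    keep = [s for s in table.sample_ids if sums[s] >= depth]
    dropped = table.n_samples - len(keep)
    if not keep:
        raise FeatureTableError(f"rarefying to {depth} drops all samples")
    if dropped:
        log.info("rarefy(depth=%d) dropped %d shallow samples", depth, dropped)
    out = {}
    for sid in keep:
        col = table.data[sid].to_numpy()
        if col.sum() == depth:
            out[sid] = col
        else:
            rng = sample_substream(seed, "rarefy", sid, depth)
            out[sid] = rng.multivariate_hypergeometric(col, depth)
    return FeatureTable(pd.DataFrame(out, index=table.taxon_ids))
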