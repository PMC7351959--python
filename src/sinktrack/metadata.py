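"""Sample metadata (source/sink/control roles) and taxonomy tables.

Metadata follows the QIIME-style mapping file convention: a tab-separated
file whose header starts with ``#SampleID`` and which carries at least an
``Env`` and a ``SourceSink`` column (``source`` or ``sink``); negative
controls are marked in an optional ``ControlType`` column.  ``Position``
orders sink samples along the processing line and ``SampleType`` records
meat / surface / control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = ["SampleMetadata", "Taxonomy", "read_metadata", "read_taxonomy"]

ROLES = ("source", "sink", "negative_control")


class MetadataError(ValueError):
    pass


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample role / environment / position / type bookkeeping.

    ``data`` is indexed by sample id with columns ``role`` (source, sink or
    negative_control), ``env`` (free-text environment label, e.g.
    "Gloves Evisceration"), ``position`` (ordered processing-line station)
    and ``sample_type`` (meat, surface or control).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise MetadataError(f"duplicate sample id: {dup!r}")
        for col in ("role", "env"):
            if col not in df.columns:
                raise MetadataError(f"metadata missing column {col!r}")
        bad = set(df["role"]) - set(ROLES)
        if bad:
            raise MetadataError(f"unknown roles: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def ids_with_role(self, role: str) -> list[str]:
        return list(self.data.index[self.data["role"] == role])

    @property
    def source_ids(self) -> list[str]:
        return self.ids_with_role("source")

    @property
    def sink_ids(self) -> list[str]:
        return self.ids_with_role("sink")

    @property
    def control_ids(self) -> list[str]:
        return self.ids_with_role("negative_control")

    def env_of(self, sample_id: str) -> str:
        return str(self.data.at[sample_id, "env"])

    def position_of(self, sample_id: str) -> str:
        if "position" not in self.data.columns or pd.isna(
            self.data.at[sample_id, "position"]
        ):
            raise MetadataError(f"sample {sample_id!r} has no position")
        return str(self.data.at[sample_id, "position"])

    def is_control_mask(self, sample_ids: Sequence[str]) -> pd.Series:
        roles = self.data["role"].reindex(sample_ids)
        if roles.isna().any():
            missing = [s for s, r in roles.items() if pd.isna(r)]
            raise MetadataError(f"samples missing from metadata: {missing}")
        return roles == "negative_control"

    def validate_for_attribution(self, sample_ids: Sequence[str]) -> None:
        """Check that attribution over these samples is well-posed."""
        seen = self.data.index.intersection(sample_ids)
        missing = set(sample_ids) - set(seen)
        if missing:
            raise MetadataError(f"samples missing from metadata: {sorted(missing)}")
        roles = self.data.loc[list(sample_ids), "role"]
        if (roles == "source").sum() == 0:
            raise MetadataError("no source samples designated")
        if (roles == "sink").sum() == 0:
            raise MetadataError("no sink samples designated")


@dataclass(frozen=True)
class Taxonomy:
    """Taxon id -> ranked lineage mapping with a genus accessor.

    Lineages are semicolon-separated ranked labels (domain ... species).
    Genus may be a placeholder such as ``Family_X`` for candidate genera
    without a name assignment; missing ranks come back as ``unclassified``.
    """

    lineages: pd.Series = field(repr=False)  # taxon id -> "d;p;c;o;f;g;s"
    genus_rank: int = 5  # 0-based position of genus in the lineage

    def genus(self, taxon_id: str) -> str:
        lin = self.lineages.get(taxon_id)
        if lin is None or not str(lin).strip():
            return "unclassified"
        parts = [p.strip() for p in str(lin).split(";")]
        if len(parts) <= self.genus_rank or not parts[self.genus_rank]:
            return "unclassified"
        return parts[self.genus_rank]

    def genus_map(self, taxon_ids: Sequence[str]) -> pd.Series:
        return pd.Series({t: self.genus(t) for t in taxon_ids}, name="genus")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#TaxonID\tlineage\n")
            for tid, lin in self.lineages.items():
                fh.write(f"{tid}\t{lin}\n")


def read_taxonomy(path: str | Path, genus_rank: int = 5) -> Taxonomy:
    """Read a 2-column TSV (taxon id, semicolon-ranked lineage)."""
    rows: dict[str, str] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            cells = ln.split("\t")
            if len(cells) < 2:
                raise MetadataError(f"{path}: malformed taxonomy line {ln!r}")
            rows[cells[0]] = cells[1]
    return Taxonomy(pd.Series(rows, name="taxonomy"), genus_rank=genus_rank)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a QIIME-style mapping TSV into :class:`SampleMetadata`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    first = df.columns[0]
    if not first.lstrip("#").strip().lower().startswith("sampleid"):
        raise MetadataError(f"{path}: first column must be #SampleID, got {first!r}")
    df = df.rename(columns={first: "sample_id"}).set_index("sample_id")
    colmap = {c.lower(): c for c in df.columns}
    for req in ("env", "sourcesink"):
        if req not in colmap:
            raise MetadataError(f"{path}: missing required column {req!r}")
    out = pd.DataFrame(index=df.index)
    out["env"] = df[colmap["env"]]
    ss = df[colmap["sourcesink"]].str.strip().str.lower()
    role = ss.map({"source": "source", "sink": "sink"})
    if "controltype" in colmap:
        is_ctl = df[colmap["controltype"]].fillna("").str.strip() != ""
        role = role.mask(is_ctl, "negative_control")
    if role.isna().any():
        bad = list(role.index[role.isna()])
        raise MetadataError(f"{path}: samples with invalid SourceSink: {bad}")
    out["role"] = role
    out["position"] = df[colmap["position"]] if "position" in colmap else pd.NA
    out["sample_type"] = (
        df[colmap["sampletype"]] if "sampletype" in colmap else pd.NA
    )
    return SampleMetadata(out)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.data
    with open(path, "w") as fh:
        fh.write("#SampleID\tEnv\tSourceSink\tControlType\tPosition\tSampleType\n")
        for sid, row in df.iterrows():
            role = row["role"]
            ss = "source" if role == "negative_control" else role
            ctl = "negative" if role == "negative_control" else ""
            pos = "" if pd.isna(row.get("position")) else row["position"]
            st = "" if pd.isna(row.get("sample_type")) else row["sample_type"]
            fh.write(f"{sid}\t{row['env']}\t{ss}\t{ctl}\t{pos}\t{st}\n")
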