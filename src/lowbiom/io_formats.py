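"""Tabular I/O and taxonomic aggregation for amplicon feature tables.

The central object is a :class:`FeatureTable`: non-negative integer counts of
amplicon sequence variants (ASVs, or any discrete features) per sample, stored
features-as-rows. On disk everything is plain TSV: a QIIME-style feature table
(``#FeatureID`` header), a sample metadata sheet, and a two-column taxonomy
file mapping feature IDs to semicolon-delimited lineages.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SampleClass",
    "SampleMetadata",
    "TaxonomyMap",
    "RANKS",
    "FormatError",
    "Orientation",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "aggregate_by_rank",
]

#: Ordered taxonomic ranks accepted in lineages (SILVA/QIIME convention).
RANKS: tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_PREFIXES = ("d__", "k__", "p__", "c__", "o__", "f__", "g__", "s__")


class FormatError(ValueError):
    """A file or in-memory table violates the expected format."""


class Orientation(str, enum.Enum):
    """On-disk layout of a feature table."""

    FEATURES_AS_ROWS = "features_as_rows"
    SAMPLES_AS_ROWS = "samples_as_rows"


class SampleClass(str, enum.Enum):
    SPECIMEN = "specimen"
    FIELD_CONTROL = "field_control"


@dataclass(frozen=True)
class SampleMetadata:
    """One sample's study annotations.

    ``pair_id`` links a cow-calf couple across sample types (e.g. the meconium
    and the amniotic fluid sample of the same pregnancy); ``None`` for
    unpaired samples and field controls.
    """

    sample_id: str
    sample_class: SampleClass
    sample_type: str
    pair_id: str | None = None


class FeatureTable:
    """Integer count matrix of features x samples.

    Parameters
    ----------
    counts:
        2-D array-like of non-negative integers, features as rows.
    feature_ids, sample_ids:
        Unique string identifiers for rows and columns.
    """

    def __init__(
        self,
        counts: np.ndarray | Iterable[Iterable[int]],
        feature_ids: Iterable[str],
        sample_ids: Iterable[str],
    ) -> None:
        counts = np.asarray(counts)
        feature_ids = [str(f) for f in feature_ids]
        sample_ids = [str(s) for s in sample_ids]
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if counts.shape != (len(feature_ids), len(sample_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(feature_ids)} features x {len(sample_ids)} samples"
            )
        if len(set(feature_ids)) != len(feature_ids):
            raise FormatError("duplicate feature identifiers")
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError("duplicate sample identifiers")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.all(np.isfinite(counts)) or np.any(counts != rounded):
                raise FormatError("counts must be integral")
            counts = rounded.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise FormatError("counts must be non-negative")
        self._df = pd.DataFrame(
            counts.astype(np.int64, copy=False),
            index=pd.Index(feature_ids, name="#FeatureID"),
            columns=pd.Index(sample_ids),
        )

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an int64 array (features x samples); a copy."""
        return self._df.to_numpy(copy=True)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def to_dataframe(self) -> pd.DataFrame:
        return self._df.copy()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(df.to_numpy(), df.index, df.columns)

    def depth(self, sample_id: str | None = None):
        """Read depth (column sum) for one sample, or a Series for all."""
        sums = self._df.sum(axis=0)
        if sample_id is None:
            return sums
        if sample_id not in self._df.columns:
            raise KeyError(sample_id)
        return int(sums[sample_id])

    def filter_samples(self, keep: Iterable[str]) -> "FeatureTable":
        keep = [s for s in keep]
        missing = set(keep) - set(self._df.columns)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)}")
        return FeatureTable.from_dataframe(self._df[keep])

    def filter_features(self, keep: Iterable[str]) -> "FeatureTable":
        keep = [f for f in keep]
        missing = set(keep) - set(self._df.index)
        if missing:
            raise KeyError(f"unknown features: {sorted(missing)}")
        return FeatureTable.from_dataframe(self._df.loc[keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        nf, ns = self.shape
        return f"<FeatureTable {nf} features x {ns} samples>"


@dataclass
class TaxonomyMap:
    """Feature -> ranked lineage. Missing features are unclassified."""

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        """Lineage padded/truncated to ``len(RANKS)`` entries, '' = unknown."""
        raw = self.lineages.get(feature_id, ())
        padded = tuple(raw[: len(RANKS)]) + ("",) * (len(RANKS) - len(raw))
        return padded


def _strip_rank_prefix(name: str) -> str:
    name = name.strip()
    for pfx in _RANK_PREFIXES:
        if name.lower().startswith(pfx):
            return name[len(pfx):].strip()
    return name


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Parse a semicolon-delimited lineage, stripping 'g__'-style prefixes.

    A lineage is truncated at its first empty entry: classification below an
    unclassified rank is not meaningful for prefix aggregation.
    """
    parts = [_strip_rank_prefix(p) for p in lineage.split(";")]
    clean: list[str] = []
    for p in parts:
        if not p or p.lower() in {"unclassified", "unknown", "na", "uncultured"}:
            break
        clean.append(p)
    return tuple(clean[: len(RANKS)])


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------


def read_feature_table(
    path: str | Path,
    orientation: Orientation | str = Orientation.FEATURES_AS_ROWS,
) -> FeatureTable:
    """Read a TSV count table.

    The first column holds feature IDs (or sample IDs when
    ``orientation="samples_as_rows"``); remaining columns are integer counts.
    """
    orientation = Orientation(orientation)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    col_names = header[1:]
    if len(set(col_names)) != len(col_names):
        raise FormatError(f"{path}: duplicate column identifiers")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str,
                     comment=None, skip_blank_lines=True)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate row identifiers")
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate column identifiers")
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    if np.any(~np.isfinite(values)):
        raise FormatError(f"{path}: missing or non-finite cell")
    if np.any(values != np.rint(values)):
        raise FormatError(f"{path}: non-integer count")
    if values.size and values.min() < 0:
        raise FormatError(f"{path}: negative count")
    counts = values.astype(np.int64)
    if orientation is Orientation.SAMPLES_AS_ROWS:
        return FeatureTable(counts.T, df.columns, df.index)
    return FeatureTable(counts, df.index, df.columns)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="#FeatureID")


# ---------------------------------------------------------------------------
# Metadata I/O
# ---------------------------------------------------------------------------

_REQUIRED_METADATA_COLS = ("sample_id", "sample_class", "sample_type")


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    """Read the sample sheet; returns a mapping keyed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_METADATA_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    records: dict[str, SampleMetadata] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"].strip()
        if not sid:
            raise FormatError(f"{path}: empty sample_id")
        if sid in records:
            raise FormatError(f"{path}: duplicate sample_id {sid!r}")
        try:
            klass = SampleClass(row["sample_class"].strip())
        except ValueError as exc:
            raise FormatError(
                f"{path}: unknown sample_class {row['sample_class']!r} "
                f"for sample {sid!r} (expected 'specimen' or 'field_control')"
            ) from exc
        pair = row.get("pair_id", "")
        pair = pair.strip() if isinstance(pair, str) else ""
        records[sid] = SampleMetadata(
            sample_id=sid,
            sample_class=klass,
            sample_type=row["sample_type"].strip(),
            pair_id=pair or None,
        )
    _check_pairing(records.values())
    return records


def _check_pairing(records: Iterable[SampleMetadata]) -> None:
    seen: set[tuple[str, str]] = set()
    for rec in records:
        if rec.pair_id is None or rec.sample_class is not SampleClass.SPECIMEN:
            continue
        key = (rec.pair_id, rec.sample_type)
        if key in seen:
            raise FormatError(
                f"pair {rec.pair_id!r} has more than one "
                f"{rec.sample_type!r} specimen"
            )
        seen.add(key)


def write_metadata(records: Mapping[str, SampleMetadata], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "sample_class": r.sample_class.value,
            "sample_type": r.sample_type,
            "pair_id": r.pair_id or "",
        }
        for r in records.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy I/O
# ---------------------------------------------------------------------------


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV of feature_id and semicolon-delimited lineage."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected feature_id<TAB>lineage")
    fid_col, lin_col = df.columns[0], df.columns[1]
    lineages: dict[str, tuple[str, ...]] = {}
    for _, row in df.iterrows():
        fid = row[fid_col].strip()
        if fid in lineages:
            raise FormatError(f"{path}: duplicate feature_id {fid!r}")
        lineages[fid] = parse_lineage(row[lin_col])
    return TaxonomyMap(lineages)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    rows = [
        {"feature_id": fid, "lineage": ";".join(lin)}
        for fid, lin in taxonomy.lineages.items()
    ]
    pd.DataFrame(rows, columns=["feature_id", "lineage"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Taxonomic aggregation
# ---------------------------------------------------------------------------


def _group_key(lineage: tuple[str, ...], rank_idx: int) -> tuple[str, ...]:
    """Aggregation key for a feature at the requested rank.

    Classified-at-rank features share the lineage prefix down to the rank.
    Features whose classification stops above the rank are pooled under
    their deepest classified parent with an "unclassified <parent>" leaf;
    fully unclassified features pool into a single "unclassified" group.
    """
    effective = lineage[: rank_idx + 1]
    # truncate at first empty entry
    prefix: list[str] = []
    for name in effective:
        if not name:
            break
        prefix.append(name)
    if len(prefix) == rank_idx + 1:
        return tuple(prefix)
    parent = prefix[-1] if prefix else ""
    label = f"unclassified {parent}" if parent else "unclassified"
    return tuple(prefix) + (label,)


def aggregate_by_rank(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    rank: str,
    return_taxonomy: bool = False,
):
    """Sum features into taxa at the given rank.

    Per-sample totals are conserved exactly: every feature lands in exactly
    one group. The aggregated feature IDs are lineage strings joined with
    ';' down to the rank (ending in "unclassified <parent>" for pooled
    groups), which keeps IDs unambiguous when distinct parents share a name.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    rank_idx = RANKS.index(rank)
    keys = [_group_key(taxonomy.lineage(fid), rank_idx) for fid in table.feature_ids]
    order: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    for key in keys:
        if key not in seen:
            seen.add(key)
            order.append(key)
    key_pos = {key: i for i, key in enumerate(order)}
    counts = table.counts
    agg = np.zeros((len(order), counts.shape[1]), dtype=np.int64)
    for row, key in enumerate(keys):
        agg[key_pos[key]] += counts[row]
    new_ids = [";".join(key) for key in order]
    out = FeatureTable(agg, new_ids, table.sample_ids)
    if not return_taxonomy:
        return out
    new_tax = TaxonomyMap(
        {
            ";".join(key): tuple(
                name for name in key if not name.startswith("unclassified")
            )
            for key in order
        }
    )
    return out, new_tax
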