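"""Field-control-based contaminant filtering for low-biomass amplicon data.

In a low-biomass study, genuine microbial DNA is comparable in amount to the
reagent and environmental DNA that enters every sample. Empty sampling
instruments processed alongside the specimens ("field controls") capture that
background. A feature is called a contaminant and removed when it looks the
same in specimens as in controls on two axes simultaneously:

* prevalence: the fraction of specimens carrying the feature is at most
  ``prevalence_ratio`` (default 2) times its fraction among field controls;
* abundance: its mean relative abundance across specimens is at most
  ``abundance_ratio`` (default 10) times its mean relative abundance across
  field controls.

Filtering is performed separately per sample type (each type's controls
inform only that type), and a specimen whose remaining depth falls below
``min_sample_reads`` (default 500, strict) after feature removal is dropped.

A feature absent from every field control can never be removed: its control
prevalence and abundance are zero, so the ``<=`` comparisons fail for any
feature actually present in a specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import FeatureTable, SampleClass, SampleMetadata

__all__ = [
    "DecontamParams",
    "FeatureContamStats",
    "DecontamReport",
    "compute_contam_stats",
    "apply_decontamination",
    "remove_singletons",
]


class DecontamError(ValueError):
    """The filter is undefined for the given inputs."""


@dataclass(frozen=True)
class DecontamParams:
    """Filter thresholds.

    combine="and" (default) removes a feature only when both criteria hold;
    "or" is a more aggressive variant kept for sensitivity analysis.
    """

    prevalence_ratio: float = 2.0
    abundance_ratio: float = 10.0
    min_sample_reads: int = 500
    presence_threshold: int = 1
    combine: str = "and"

    def __post_init__(self) -> None:
        if self.prevalence_ratio <= 0 or self.abundance_ratio <= 0:
            raise ValueError("ratios must be positive")
        if self.min_sample_reads < 0:
            raise ValueError("min_sample_reads must be >= 0")
        if self.presence_threshold < 1:
            raise ValueError("presence_threshold must be >= 1")
        if self.combine not in ("and", "or"):
            raise ValueError("combine must be 'and' or 'or'")


@dataclass(frozen=True)
class FeatureContamStats:
    feature_id: str
    prev_specimen: float
    prev_control: float
    mean_relabund_specimen: float
    mean_relabund_control: float
    prevalence_criterion: bool
    abundance_criterion: bool
    removed: bool


@dataclass
class DecontamReport:
    """Audit trail of one sample type's filtering pass."""

    sample_type: str
    params: DecontamParams
    feature_stats: list[FeatureContamStats]
    removed_feature_ids: list[str]
    retained_table: FeatureTable
    filtered_full_table: FeatureTable  # all specimens, before the depth cut
    dropped_sample_ids: list[str]
    reads_before: dict[str, int] = field(default_factory=dict)
    reads_after: dict[str, int] = field(default_factory=dict)


def _split_groups(
    table: FeatureTable,
    metadata: dict[str, SampleMetadata],
    sample_type: str,
) -> tuple[list[str], list[str]]:
    specimens, controls = [], []
    for sid in table.sample_ids:
        rec = metadata.get(sid)
        if rec is None or rec.sample_type != sample_type:
            continue
        if rec.sample_class is SampleClass.SPECIMEN:
            specimens.append(sid)
        else:
            controls.append(sid)
    return specimens, controls


def _group_stats(counts: np.ndarray, presence_threshold: int):
    """Prevalence and mean relative abundance per feature over a group.

    Relative abundance is count over sample depth, taken as 0 for an empty
    sample; the mean runs over *all* samples of the group, zeros included.
    """
    n = counts.shape[1]
    prevalence = (counts >= presence_threshold).sum(axis=1) / n
    depths = counts.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        relabund = np.where(depths > 0, counts / depths, 0.0)
    return prevalence, relabund.mean(axis=1)


def compute_contam_stats(
    table: FeatureTable,
    metadata: dict[str, SampleMetadata],
    sample_type: str,
    params: DecontamParams = DecontamParams(),
) -> list[FeatureContamStats]:
    """Evaluate the two contaminant criteria for every feature of one type."""
    specimens, controls = _split_groups(table, metadata, sample_type)
    if not controls:
        raise DecontamError(
            f"no field controls of sample_type {sample_type!r}: filter undefined"
        )
    if not specimens:
        raise DecontamError(f"no specimens of sample_type {sample_type!r}")
    counts = table.counts
    cols = {sid: j for j, sid in enumerate(table.sample_ids)}
    spec_counts = counts[:, [cols[s] for s in specimens]]
    ctrl_counts = counts[:, [cols[s] for s in controls]]
    prev_s, mra_s = _group_stats(spec_counts, params.presence_threshold)
    prev_c, mra_c = _group_stats(ctrl_counts, params.presence_threshold)

    stats: list[FeatureContamStats] = []
    for i, fid in enumerate(table.feature_ids):
        crit_prev = bool(prev_s[i] <= params.prevalence_ratio * prev_c[i])
        crit_abund = bool(mra_s[i] <= params.abundance_ratio * mra_c[i])
        if params.combine == "and":
            removed = crit_prev and crit_abund
        else:
            removed = crit_prev or crit_abund
        stats.append(
            FeatureContamStats(
                feature_id=fid,
                prev_specimen=float(prev_s[i]),
                prev_control=float(prev_c[i]),
                mean_relabund_specimen=float(mra_s[i]),
                mean_relabund_control=float(mra_c[i]),
                prevalence_criterion=crit_prev,
                abundance_criterion=crit_abund,
                removed=removed,
            )
        )
    return stats


def apply_decontamination(
    table: FeatureTable,
    metadata: dict[str, SampleMetadata],
    params: DecontamParams = DecontamParams(),
    sample_types: list[str] | None = None,
) -> dict[str, DecontamReport]:
    """Run the filter independently for each sample type.

    Statistics are computed once on the input table (single pass); the
    removal set is then applied to that type's specimens, and specimens
    left with fewer than ``min_sample_reads`` reads are dropped. Field
    controls are never carried into the retained table.
    """
    if sample_types is None:
        sample_types = sorted(
            {
                metadata[s].sample_type
                for s in table.sample_ids
                if s in metadata and metadata[s].sample_class is SampleClass.SPECIMEN
            }
        )
    reports: dict[str, DecontamReport] = {}
    for stype in sample_types:
        stats = compute_contam_stats(table, metadata, stype, params)
        removed = [st.feature_id for st in stats if st.removed]
        removed_set = set(removed)
        kept_features = [f for f in table.feature_ids if f not in removed_set]
        specimens, _ = _split_groups(table, metadata, stype)
        spec_table = table.filter_samples(specimens)
        reads_before = {s: int(spec_table.depth(s)) for s in specimens}
        filtered = spec_table.filter_features(kept_features)
        reads_after = {s: int(filtered.depth(s)) for s in specimens}
        dropped = [s for s in specimens if reads_after[s] < params.min_sample_reads]
        retained = filtered.filter_samples(
            [s for s in specimens if s not in set(dropped)]
        )
        reports[stype] = DecontamReport(
            sample_type=stype,
            params=params,
            feature_stats=stats,
            removed_feature_ids=removed,
            retained_table=retained,
            filtered_full_table=filtered,
            dropped_sample_ids=dropped,
            reads_before=reads_before,
            reads_after=reads_after,
        )
    return reports


def remove_singletons(table: FeatureTable) -> FeatureTable:
    """Drop features whose total count over all samples is 1.

    Denoising pipelines usually do this upstream; provided for convenience
    when ingesting tables that have not been singleton-filtered.
    """
    totals = table.counts.sum(axis=1)
    keep = [f for f, t in zip(table.feature_ids, totals) if t != 1]
    return table.filter_features(keep)
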