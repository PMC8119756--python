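"""End-to-end orchestration: decontaminate, quantify, and compare.

The pipeline mirrors the analysis order of a low-biomass paired study:
field-control decontamination per sample type, qPCR specimen-vs-control
comparison, genus aggregation, Shannon diversity, Bray-Curtis distances,
PCoA, PERMANOVA and dispersion homogeneity between sample types, and paired
Spearman correlations across the shared high-count features. All outputs are
plain TSV/JSON; a manifest records input hashes, parameters, seed and
library versions so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, qpcr
from .decontam import DecontamParams, DecontamReport, apply_decontamination
from .io_formats import (
    FeatureTable,
    SampleClass,
    SampleMetadata,
    aggregate_by_rank,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    write_feature_table,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "merge_tables"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    table_path: str
    metadata_path: str
    taxonomy_path: str
    out_dir: str
    qpcr_path: str | None = None
    decontam: DecontamParams = field(default_factory=DecontamParams)
    rank: str = "genus"
    n_permutations: int = 9999
    seed: int = 0
    unit_scale: float = 1.0
    min_shared_total: int = 100

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def merge_tables(tables: list[FeatureTable]) -> FeatureTable:
    """Union of feature spaces across tables; absent features count 0."""
    frames = [t.to_dataframe() for t in tables]
    all_features: list[str] = []
    seen: set[str] = set()
    for f in frames:
        for fid in f.index:
            if fid not in seen:
                seen.add(fid)
                all_features.append(fid)
    merged = pd.concat(
        [f.reindex(all_features, fill_value=0) for f in frames], axis=1
    )
    if merged.columns.has_duplicates:
        raise ValueError("duplicate sample ids across merged tables")
    return FeatureTable.from_dataframe(merged.astype(np.int64))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stats_frame(report: DecontamReport) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(s) for s in report.feature_stats]
    ).set_index("feature_id")


def _reads_frame(report: DecontamReport) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s,
            "reads_before": report.reads_before[s],
            "reads_after": report.reads_after[s],
            "dropped": s in set(report.dropped_sample_ids),
        }
        for s in report.reads_before
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def _pairs_between(
    metadata: dict[str, SampleMetadata],
    table_a: FeatureTable,
    table_b: FeatureTable,
    type_a: str,
    type_b: str,
) -> dict[str, tuple[str, str]]:
    by_pair: dict[str, dict[str, str]] = {}
    for sid, rec in metadata.items():
        if rec.pair_id and rec.sample_class is SampleClass.SPECIMEN:
            by_pair.setdefault(rec.pair_id, {})[rec.sample_type] = sid
    in_a, in_b = set(table_a.sample_ids), set(table_b.sample_ids)
    pairs = {}
    for pid, members in sorted(by_pair.items()):
        sa, sb = members.get(type_a), members.get(type_b)
        if sa in in_a and sb in in_b:
            pairs[pid] = (sa, sb)
    return pairs


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the result summary dictionary.

    Any stage failure raises :class:`PipelineError` naming the stage; files
    written so far are kept and a ``FAILED`` marker file records the error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "inputs": {},
        "stages": [],
        "outputs": [],
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    results: dict = {}
    stage = "load"
    try:
        for key, path in (
            ("table", config.table_path),
            ("metadata", config.metadata_path),
            ("taxonomy", config.taxonomy_path),
            ("qpcr", config.qpcr_path),
        ):
            if path is not None:
                manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
        table = read_feature_table(config.table_path)
        metadata = read_metadata(config.metadata_path)
        taxonomy = read_taxonomy(config.taxonomy_path)
        missing = [s for s in table.sample_ids if s not in metadata]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        manifest["stages"].append(stage)

        stage = "decontam"
        reports = apply_decontamination(table, metadata, config.decontam)
        results["decontam"] = {}
        for stype, rep in reports.items():
            _write(out / f"decontam_{stype}_stats.tsv", _stats_frame(rep), manifest)
            _write(out / f"decontam_{stype}_reads.tsv", _reads_frame(rep), manifest)
            tpath = out / f"retained_{stype}.tsv"
            write_feature_table(rep.retained_table, tpath)
            manifest["outputs"].append(str(tpath))
            results["decontam"][stype] = {
                "n_features_removed": len(rep.removed_feature_ids),
                "n_features_retained": rep.retained_table.shape[0],
                "n_samples_dropped": len(rep.dropped_sample_ids),
                "dropped_sample_ids": rep.dropped_sample_ids,
                "mean_reads_before": float(np.mean(list(rep.reads_before.values()))),
                "mean_reads_after": float(np.mean(list(rep.reads_after.values()))),
            }
        manifest["stages"].append(stage)

        stage = "qpcr"
        if config.qpcr_path is not None:
            qdf = qpcr.read_qpcr_csv(config.qpcr_path)
            copies = qpcr.quantify(qdf, unit_scale=config.unit_scale)
            results["qpcr"] = {"copies": copies, "comparisons": {}}
            types = sorted({m.sample_type for m in metadata.values()})
            for stype in types:
                spec = [
                    v
                    for s, v in copies.items()
                    if s in metadata
                    and metadata[s].sample_type == stype
                    and metadata[s].sample_class is SampleClass.SPECIMEN
                ]
                ctrl = [
                    v
                    for s, v in copies.items()
                    if s in metadata
                    and metadata[s].sample_type == stype
                    and metadata[s].sample_class is SampleClass.FIELD_CONTROL
                ]
                if spec and ctrl:
                    cmp_res = qpcr.mann_whitney_u(spec, ctrl)
                    results["qpcr"]["comparisons"][stype] = {
                        "u_statistic": cmp_res.u_statistic,
                        "n_specimens": cmp_res.n1,
                        "n_controls": cmp_res.n2,
                        "p_two_tailed": cmp_res.p_two_tailed,
                        "method": cmp_res.method.value,
                        "mean_specimen": float(np.mean(spec)),
                        "mean_control": float(np.mean(ctrl)),
                    }
            pd.Series(copies, name="copies").rename_axis("sample_id").to_frame().to_csv(
                out / "qpcr_copies.tsv", sep="\t"
            )
            manifest["outputs"].append(str(out / "qpcr_copies.tsv"))
        manifest["stages"].append(stage)

        stage = "community"
        retained = merge_tables([rep.retained_table for rep in reports.values()])
        if retained.shape[1] < 3:
            raise ValueError("fewer than three specimens survived decontamination")
        nonempty = [s for s in retained.sample_ids if retained.depth(s) > 0]
        retained = retained.filter_samples(nonempty)
        genus_table = aggregate_by_rank(retained, taxonomy, config.rank)
        write_feature_table(genus_table, out / f"retained_{config.rank}.tsv")
        manifest["outputs"].append(str(out / f"retained_{config.rank}.tsv"))

        shannon_div = community.shannon_per_sample(genus_table)
        shannon_div.rename("shannon").rename_axis("sample_id").to_frame().to_csv(
            out / "shannon.tsv", sep="\t"
        )
        manifest["outputs"].append(str(out / "shannon.tsv"))
        labels = {s: metadata[s].sample_type for s in retained.sample_ids}
        results["shannon"] = {
            stype: float(
                np.mean([shannon_div[s] for s in retained.sample_ids if labels[s] == stype])
            )
            for stype in sorted(set(labels.values()))
        }
        types_present = sorted(set(labels.values()))
        if len(types_present) == 2:
            a, b = types_present
            sh_cmp = qpcr.mann_whitney_u(
                [shannon_div[s] for s in retained.sample_ids if labels[s] == a],
                [shannon_div[s] for s in retained.sample_ids if labels[s] == b],
            )
            results["shannon_comparison"] = {
                "groups": [a, b],
                "p_two_tailed": sh_cmp.p_two_tailed,
            }

        results["beta"] = {}
        for level, tab in (("asv", retained), (config.rank, genus_table)):
            dm = community.bray_curtis(tab)
            dm.to_dataframe().to_csv(out / f"braycurtis_{level}.tsv", sep="\t")
            manifest["outputs"].append(str(out / f"braycurtis_{level}.tsv"))
            ordn = community.pcoa(dm)
            coords = pd.DataFrame(
                ordn.coordinates[:, : min(3, ordn.coordinates.shape[1])],
                index=ordn.sample_ids,
            )
            coords.to_csv(out / f"pcoa_{level}.tsv", sep="\t")
            manifest["outputs"].append(str(out / f"pcoa_{level}.tsv"))
            entry: dict = {
                "proportion_explained_axis1": float(ordn.proportion_explained[0])
                if len(ordn.proportion_explained)
                else 0.0
            }
            if len(types_present) >= 2:
                perm = community.permanova(
                    dm, labels, n_perm=config.n_permutations, seed=config.seed
                )
                entry["permanova"] = {
                    "pseudo_f": perm.pseudo_f,
                    "r_squared": perm.r_squared,
                    "p_value": perm.p_value,
                    "n_permutations": perm.n_permutations,
                }
                group_sizes = pd.Series(list(labels.values())).value_counts()
                if group_sizes.min() >= 2:
                    disp = community.permdisp(
                        dm, labels, n_perm=config.n_permutations, seed=config.seed
                    )
                    entry["permdisp"] = {
                        "f_statistic": disp.f_statistic,
                        "p_value": disp.p_value,
                        "group_mean_distance": disp.group_mean_distance,
                    }
            results["beta"][level] = entry
        manifest["stages"].append(stage)

        stage = "paired_correlation"
        if len(reports) == 2:
            (ta_name, rep_a), (tb_name, rep_b) = sorted(reports.items())
            pairs = _pairs_between(
                metadata, rep_a.retained_table, rep_b.retained_table, ta_name, tb_name
            )
            results["paired_correlation"] = {}
            for level_name, tab_a, tab_b in (
                (
                    "asv",
                    rep_a.retained_table,
                    rep_b.retained_table,
                ),
                (
                    config.rank,
                    aggregate_by_rank(rep_a.retained_table, taxonomy, config.rank),
                    aggregate_by_rank(rep_b.retained_table, taxonomy, config.rank),
                ),
            ):
                feats = community.select_shared_features(
                    tab_a, tab_b, min_total=config.min_shared_total
                )
                if pairs and feats:
                    corrs, avg_rho = community.paired_spearman(
                        tab_a, tab_b, pairs, feats
                    )
                    results["paired_correlation"][level_name] = {
                        "n_pairs": len(pairs),
                        "n_features": len(feats),
                        "average_rho": avg_rho,
                        "n_significant_bonferroni": sum(
                            1
                            for c in corrs
                            if c.p_bonferroni is not None and c.p_bonferroni < 0.05
                        ),
                    }
        manifest["stages"].append(stage)

    except Exception as exc:  # noqa: BLE001 - single fail path with marker
        (out / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    results_path = out / "results.json"
    results_path.write_text(json.dumps(results, indent=2, default=float))
    manifest["outputs"].append(str(results_path))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _write(path: Path, df: pd.DataFrame, manifest: dict) -> None:
    df.to_csv(path, sep="\t")
    manifest["outputs"].append(str(path))
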