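"""Synthetic low-biomass 16S studies with known contamination structure.

The generator emulates a paired two-sample-type design (meconium and
amniotic fluid from the same cow-calf couples, plus empty-instrument field
controls per type) in which every sequenced read comes from one of two
feature classes:

* contaminant taxa — reagent/environment DNA with the *same* expected
  absolute load in specimens and field controls (the regime a control-based
  prevalence/abundance filter presupposes);
* signal taxa — genuine biological DNA, present only in specimens, each
  taxon carried by a random subset of specimens.

Per-sample absolute loads are lognormal; a sample's composition is its load
vector normalised; observed counts are Dirichlet-multinomial at a lognormal
sequencing depth (depth is set by library preparation, not by load). qPCR
copy numbers are the scaled true signal load plus a lognormal background
draw, with multiplicative measurement noise.

Default calibration anchors (means/SDs of depths, qPCR backgrounds and
specimen copy numbers) follow the published bovine cesarean-section study
this design emulates; every feature is labelled in the ground truth so
filter sensitivity and specificity are measurable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log, sqrt

import numpy as np
import pandas as pd

from .io_formats import (
    FeatureTable,
    SampleClass,
    SampleMetadata,
    TaxonomyMap,
)

__all__ = [
    "SampleTypeConfig",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_study",
    "simulate_qpcr",
    "lognormal_params",
    "qpcr_frame",
    "write_study",
]


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be positive and sd non-negative")
    cv2 = (sd / mean) ** 2
    sigma2 = log(1.0 + cv2)
    return log(mean) - sigma2 / 2.0, sqrt(sigma2)


@dataclass(frozen=True)
class SampleTypeConfig:
    """One sample type's group sizes, depths and load calibration.

    Depth and qPCR anchors are arithmetic mean/SD pairs of the lognormal
    draws; ``signal_total_mean`` is the expected summed absolute signal
    load per specimen (copies), so the expected specimen qPCR reading is
    ``qpcr_signal_scale * signal_total_mean + qpcr_background_mean``.
    """

    name: str
    n_specimens: int
    n_controls: int
    depth_mean: float
    depth_sd: float
    control_depth_mean: float
    control_depth_sd: float
    k_signal: int
    signal_presence_prob: float
    signal_total_mean: float
    signal_load_log_sd: float
    qpcr_background_mean: float
    qpcr_background_sd: float
    qpcr_signal_scale: float = 1.0

    @property
    def signal_load_log_mean(self) -> float:
        """Per-taxon lognormal mu giving the configured total signal mean."""
        per_taxon = self.signal_total_mean / (
            self.k_signal * self.signal_presence_prob
        )
        return log(per_taxon) - self.signal_load_log_sd**2 / 2.0


#: Group sizes, sequencing depths and qPCR levels of the emulated study:
#: 23 sequenced cow-calf couples; 11 meconium and 8 amniotic-fluid field
#: controls; raw depth anchors 92,266 (36,235) and 127,797 (22,376) for
#: specimens, 126,800 (21,164) and 136,488 (12,663) for controls; qPCR
#: anchors 4,350/980 (meconium) and 3,170/1,610 (amniotic fluid).
MECONIUM_DEFAULTS = SampleTypeConfig(
    name="meconium",
    n_specimens=23,
    n_controls=11,
    depth_mean=92_266.0,
    depth_sd=36_235.0,
    control_depth_mean=126_800.0,
    control_depth_sd=21_164.0,
    k_signal=25,
    signal_presence_prob=0.3,
    signal_total_mean=4_350.0 - 980.0,
    signal_load_log_sd=1.5,
    qpcr_background_mean=980.0,
    qpcr_background_sd=850.0,
)

AMNION_DEFAULTS = SampleTypeConfig(
    name="amnion",
    n_specimens=23,
    n_controls=8,
    depth_mean=127_797.0,
    depth_sd=22_376.0,
    control_depth_mean=136_488.0,
    control_depth_sd=12_663.0,
    k_signal=25,
    signal_presence_prob=0.3,
    signal_total_mean=3_170.0 - 1_610.0,
    signal_load_log_sd=1.5,
    qpcr_background_mean=1_610.0,
    qpcr_background_sd=790.0,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Full study configuration; identical seed -> identical outputs."""

    seed: int = 0
    n_pairs: int = 23
    sample_types: tuple[SampleTypeConfig, ...] = (
        MECONIUM_DEFAULTS,
        AMNION_DEFAULTS,
    )
    k_contaminant: int = 40
    #: signal taxa common to both sample types' pools (counted within each
    #: type's k_signal); the substrate of the paired-correlation analysis
    k_signal_shared: int = 6
    contaminant_total_mean: float = 980.0
    contaminant_taxon_log_sd: float = 1.0  # spread of per-taxon base loads
    contaminant_sample_log_sd: float = 0.6  # sample-to-sample wobble
    dm_concentration: float = 100.0  # Dirichlet precision; lower = noisier
    qpcr_noise_log_sd: float = 0.25
    signal_leak_prob: float = 0.0  # chance a signal taxon leaks into a control

    def __post_init__(self) -> None:
        if self.k_contaminant < 0:
            raise ValueError("k_contaminant must be >= 0")
        any_controls = any(t.n_controls > 0 for t in self.sample_types)
        if self.k_contaminant == 0 and any_controls:
            raise ValueError(
                "k_contaminant = 0 with field controls requested: "
                "controls would be empty"
            )
        if self.dm_concentration <= 0:
            raise ValueError("dm_concentration must be positive")
        if not 0.0 <= self.signal_leak_prob <= 1.0:
            raise ValueError("signal_leak_prob must be in [0, 1]")
        for t in self.sample_types:
            if not 0.0 <= t.signal_presence_prob <= 1.0:
                raise ValueError("signal_presence_prob must be in [0, 1]")

    def with_types(self, **changes) -> "SimulationConfig":
        """Copy with every sample type's config fields replaced."""
        new_types = tuple(replace(t, **changes) for t in self.sample_types)
        return replace(self, sample_types=new_types)


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    table: FeatureTable
    metadata: dict[str, SampleMetadata]
    taxonomy: TaxonomyMap
    ground_truth: dict[str, str]  # feature -> "contaminant" | "signal"
    true_loads: pd.DataFrame  # absolute loads, features x samples
    qpcr_copies: dict[str, float] = field(default_factory=dict)

    def signal_load_total(self, sample_id: str) -> float:
        sig = [f for f, lbl in self.ground_truth.items() if lbl == "signal"]
        return float(self.true_loads.loc[sig, sample_id].sum())


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _synthetic_taxonomy(feature_ids: list[str]) -> TaxonomyMap:
    """Synthetic SILVA-style lineages; pairs of ASVs share a genus."""
    lineages = {}
    for i, fid in enumerate(feature_ids):
        g = i // 2
        lineages[fid] = (
            "Bacteria",
            f"Phylum{g % 6:02d}",
            f"Class{g % 12:02d}",
            f"Order{g % 18:02d}",
            f"Family{g % 24:02d}",
            f"Genus{g:03d}",
        )
    return TaxonomyMap(lineages)


def _draw_counts(
    rng: np.random.Generator,
    loads: np.ndarray,
    depth: int,
    concentration: float,
) -> np.ndarray:
    """Dirichlet-multinomial counts given a sample's absolute load vector."""
    total = loads.sum()
    counts = np.zeros(loads.shape, dtype=np.int64)
    if total <= 0 or depth <= 0:
        return counts
    present = loads > 0
    alpha = concentration * loads[present] / total
    p = rng.dirichlet(alpha)
    counts[present] = rng.multinomial(depth, p)
    return counts


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one complete study (counts, metadata, taxonomy, qPCR)."""
    rng = np.random.default_rng(config.seed)

    contam_ids = [f"contam{i:03d}" for i in range(config.k_contaminant)]
    n_shared = min(
        config.k_signal_shared, *(t.k_signal for t in config.sample_types)
    ) if config.sample_types else 0
    shared_ids = [f"signal_shared_{i:03d}" for i in range(n_shared)]
    signal_ids: dict[str, list[str]] = {}
    unique_ids: list[str] = []
    for tcfg in config.sample_types:
        own = [
            f"signal_{tcfg.name}_{i:03d}" for i in range(tcfg.k_signal - n_shared)
        ]
        unique_ids.extend(own)
        signal_ids[tcfg.name] = shared_ids + own
    feature_ids = contam_ids + shared_ids + unique_ids
    f_index = {f: i for i, f in enumerate(feature_ids)}
    nf = len(feature_ids)

    # per-taxon contaminant base loads, shared by every sample in the study
    if config.k_contaminant:
        mu_c = (
            log(config.contaminant_total_mean / config.k_contaminant)
            - (config.contaminant_taxon_log_sd**2 + config.contaminant_sample_log_sd**2)
            / 2.0
        )
        contam_base = rng.normal(mu_c, config.contaminant_taxon_log_sd, config.k_contaminant)
    else:
        contam_base = np.empty(0)

    metadata: dict[str, SampleMetadata] = {}
    sample_ids: list[str] = []
    load_cols: dict[str, np.ndarray] = {}
    count_cols: dict[str, np.ndarray] = {}

    for tcfg in config.sample_types:
        if tcfg.n_specimens > config.n_pairs:
            raise ValueError(
                f"{tcfg.name}: n_specimens exceeds n_pairs ({config.n_pairs})"
            )
        sig_rows = [f_index[f] for f in signal_ids[tcfg.name]]
        groups = [
            (SampleClass.SPECIMEN, tcfg.n_specimens, tcfg.depth_mean, tcfg.depth_sd),
            (
                SampleClass.FIELD_CONTROL,
                tcfg.n_controls,
                tcfg.control_depth_mean,
                tcfg.control_depth_sd,
            ),
        ]
        for klass, n, dmean, dsd in groups:
            mu_d, sd_d = lognormal_params(dmean, dsd)
            for i in range(n):
                if klass is SampleClass.SPECIMEN:
                    sid = f"{tcfg.name}_S{i + 1:02d}"
                    pair = f"pair{i + 1:02d}"
                else:
                    sid = f"{tcfg.name}_C{i + 1:02d}"
                    pair = None
                loads = np.zeros(nf)
                if config.k_contaminant:
                    loads[: config.k_contaminant] = rng.lognormal(
                        contam_base, config.contaminant_sample_log_sd
                    )
                if sig_rows and tcfg.k_signal:
                    if klass is SampleClass.SPECIMEN:
                        p_present = tcfg.signal_presence_prob
                    else:
                        p_present = config.signal_leak_prob
                    present = rng.random(tcfg.k_signal) < p_present
                    if present.any():
                        draws = rng.lognormal(
                            tcfg.signal_load_log_mean,
                            tcfg.signal_load_log_sd,
                            int(present.sum()),
                        )
                        loads[np.array(sig_rows)[present]] = draws
                depth = int(round(rng.lognormal(mu_d, sd_d)))
                counts = _draw_counts(rng, loads, depth, config.dm_concentration)
                sample_ids.append(sid)
                load_cols[sid] = loads
                count_cols[sid] = counts
                metadata[sid] = SampleMetadata(
                    sample_id=sid,
                    sample_class=klass,
                    sample_type=tcfg.name,
                    pair_id=pair,
                )

    counts = np.column_stack([count_cols[s] for s in sample_ids])
    loads_df = pd.DataFrame(
        np.column_stack([load_cols[s] for s in sample_ids]),
        index=feature_ids,
        columns=sample_ids,
    )
    table = FeatureTable(counts, feature_ids, sample_ids)
    ground_truth = {f: "contaminant" for f in contam_ids}
    for t in config.sample_types:
        ground_truth.update({f: "signal" for f in signal_ids[t.name]})

    study = SimulatedStudy(
        config=config,
        table=table,
        metadata=metadata,
        taxonomy=_synthetic_taxonomy(feature_ids),
        ground_truth=ground_truth,
        true_loads=loads_df,
    )
    study.qpcr_copies = simulate_qpcr(study, config, rng)
    return study


def simulate_qpcr(
    study: SimulatedStudy,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> dict[str, float]:
    """qPCR copy numbers per sample.

    Specimens read ``scale * true signal load + background``; field controls
    read background alone; both with multiplicative lognormal noise. The
    noise draw has unit mean so calibration anchors are preserved.
    """
    config = config or study.config
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else config.seed + 1)
    type_cfg = {t.name: t for t in config.sample_types}
    mu_noise = -config.qpcr_noise_log_sd**2 / 2.0
    copies: dict[str, float] = {}
    for sid, rec in study.metadata.items():
        tcfg = type_cfg[rec.sample_type]
        mu_b, sd_b = lognormal_params(
            tcfg.qpcr_background_mean, tcfg.qpcr_background_sd
        )
        background = rng.lognormal(mu_b, sd_b)
        if rec.sample_class is SampleClass.SPECIMEN:
            value = tcfg.qpcr_signal_scale * study.signal_load_total(sid) + background
        else:
            value = background
        noise = rng.lognormal(mu_noise, config.qpcr_noise_log_sd)
        copies[sid] = float(value * noise)
    return copies


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def qpcr_frame(
    study: SimulatedStudy,
    slope: float = -3.3219280948873623,
    intercept: float = 40.0,
    standards: tuple[float, ...] = (1e1, 1e2, 1e3, 1e4, 1e5, 1e6, 1e7),
) -> pd.DataFrame:
    """Render the study's copy numbers as a qPCR result sheet.

    Copy numbers are converted to Cq through an ideal standard curve
    (default: perfect doubling efficiency) and emitted together with the
    standard dilution series, so the sheet can be re-quantified by the
    qPCR module. Samples with zero copies are recorded as non-detects.
    """
    rows = []
    for c in standards:
        rows.append(
            {
                "run_id": "run1",
                "sample_id": f"std_{c:g}",
                "role": "standard",
                "copies": c,
                "cq": slope * np.log10(c) + intercept,
                "replicate": 0,
            }
        )
    for sid, copies in study.qpcr_copies.items():
        cq = slope * np.log10(copies) + intercept if copies > 0 else np.nan
        rows.append(
            {
                "run_id": "run1",
                "sample_id": sid,
                "role": "unknown",
                "copies": np.nan,
                "cq": cq,
                "replicate": 0,
            }
        )
    return pd.DataFrame(rows)


def write_study(study: SimulatedStudy, out_dir) -> dict[str, str]:
    """Write the study as the pipeline's plain-text input bundle.

    Emits feature table, metadata and taxonomy TSVs, a qPCR CSV and the
    ground-truth labels; returns the paths keyed by role.
    """
    from pathlib import Path

    from .io_formats import write_feature_table, write_metadata, write_taxonomy

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": str(out / "feature_table.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "taxonomy": str(out / "taxonomy.tsv"),
        "qpcr": str(out / "qpcr.csv"),
        "ground_truth": str(out / "ground_truth.tsv"),
    }
    write_feature_table(study.table, paths["table"])
    write_metadata(study.metadata, paths["metadata"])
    write_taxonomy(study.taxonomy, paths["taxonomy"])
    qpcr_frame(study).to_csv(paths["qpcr"], index=False)
    pd.DataFrame(
        {
            "feature_id": list(study.ground_truth),
            "label": list(study.ground_truth.values()),
        }
    ).to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
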