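import numpy as np
import pytest

from lowbiom.io_formats import (
    FeatureTable,
    SampleClass,
    SampleMetadata,
    TaxonomyMap,
)


@pytest.fixture
def toy_table() -> FeatureTable:
    counts = np.array(
        [
            [5, 0, 2],
            [1, 3, 4],
            [0, 7, 1],
        ]
    )
    return FeatureTable(counts, ["f1", "f2", "f3"], ["s1", "s2", "s3"])


def make_metadata(specimens, controls, sample_type="meconium"):
    md = {}
    for i, s in enumerate(specimens):
        md[s] = SampleMetadata(s, SampleClass.SPECIMEN, sample_type, f"pair{i}")
    for c in controls:
        md[c] = SampleMetadata(c, SampleClass.FIELD_CONTROL, sample_type, None)
    return md


def random_table(rng, n_features=None, n_samples=None, max_count=50, sparsity=0.4):
    """Small random count table for oracle comparisons."""
    nf = n_features if n_features is not None else rng.integers(2, 31)
    ns = n_samples if n_samples is not None else rng.integers(3, 11)
    counts = rng.integers(0, max_count, size=(nf, ns))
    counts[rng.random(size=counts.shape) < sparsity] = 0
    fids = [f"f{i}" for i in range(nf)]
    sids = [f"s{j}" for j in range(ns)]
    return FeatureTable(counts, fids, sids)


def brute_force_removal(table, specimen_ids, control_ids, prev_ratio=2.0,
                        abund_ratio=10.0, presence=1):
    """Independent per-feature evaluation of the two filter inequalities.

    Deliberately written with plain Python loops, no shared code with the
    implementation.
    """
    df = table.to_dataframe()
    depths = {s: df[s].sum() for s in df.columns}
    removed = set()
    for fid in df.index:
        prev_s = sum(df.at[fid, s] >= presence for s in specimen_ids) / len(specimen_ids)
        prev_c = sum(df.at[fid, s] >= presence for s in control_ids) / len(control_ids)
        ra_s = [df.at[fid, s] / depths[s] if depths[s] > 0 else 0.0 for s in specimen_ids]
        ra_c = [df.at[fid, s] / depths[s] if depths[s] > 0 else 0.0 for s in control_ids]
        mra_s = sum(ra_s) / len(ra_s)
        mra_c = sum(ra_c) / len(ra_c)
        if prev_s <= prev_ratio * prev_c and mra_s <= abund_ratio * mra_c:
            removed.add(fid)
    return removed


@pytest.fixture
def simple_taxonomy() -> TaxonomyMap:
    return TaxonomyMap(
        {
            "f1": ("Bacteria", "Proteobacteria", "Gamma", "Pseudomonadales",
                   "Moraxellaceae", "Acinetobacter"),
            "f2": ("Bacteria", "Proteobacteria", "Gamma", "Pseudomonadales",
                   "Moraxellaceae", "Acinetobacter"),
            "f3": ("Bacteria", "Proteobacteria", "Beta", "Burkholderiales",
                   "Burkholderiaceae"),
        }
    )
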