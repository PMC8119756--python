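"""Community-level statistics on decontaminated feature tables.

Covers the descriptive and inferential layer of a two-group amplicon study:
per-sample relative abundances, Shannon diversity (natural log, no
rarefaction), Bray-Curtis dissimilarities, classical PCoA, one-way PERMANOVA
with permutation p-values, homogeneity of group dispersions (betadisper-style),
and paired Spearman correlations between sample types of the same subject
with Bonferroni correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .io_formats import FeatureTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "DispersionResult",
    "PairedCorrelation",
    "relative_abundance",
    "shannon",
    "shannon_per_sample",
    "bray_curtis",
    "pcoa",
    "permanova",
    "permdisp",
    "select_shared_features",
    "paired_spearman",
]


class CommunityError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise CommunityError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise CommunityError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise CommunityError("distance matrix diagonal must be zero")
        if np.any(self.d < -1e-12):
            raise CommunityError("distances must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    eigenvalues: np.ndarray  # positive, descending
    coordinates: np.ndarray  # samples x retained axes
    proportion_explained: np.ndarray


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass
class DispersionResult:
    f_statistic: float
    p_value: float
    group_mean_distance: dict[str, float]
    n_permutations: int
    seed: int | None


@dataclass
class PairedCorrelation:
    pair_id: str
    rho: float | None  # None when a vector is constant
    p_raw: float | None
    p_bonferroni: float | None
    n_features: int


# ---------------------------------------------------------------------------
# Descriptive layer
# ---------------------------------------------------------------------------


def relative_abundance(table: FeatureTable) -> pd.DataFrame:
    """Per-sample proportions (columns sum to 1)."""
    df = table.to_dataframe().astype(float)
    depths = df.sum(axis=0)
    empty = depths[depths == 0]
    if len(empty):
        raise CommunityError(
            f"zero-depth sample(s): {', '.join(map(str, empty.index))}"
        )
    return df / depths


def shannon(proportions, atol: float = 1e-8) -> float:
    """Shannon entropy H = -sum p ln p of one composition (natural log)."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise CommunityError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > atol:
        raise CommunityError(f"proportions must sum to 1 (got {p.sum():.6g})")
    return float(sps.entropy(p))


def shannon_per_sample(table: FeatureTable) -> pd.Series:
    """Shannon diversity of every sample, computed on proportions."""
    props = relative_abundance(table)
    return props.apply(lambda col: shannon(col.to_numpy()), axis=0)


def bray_curtis(props: pd.DataFrame | FeatureTable, raw_counts: bool = False) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    d(x, y) = 1 - 2 * sum_i min(x_i, y_i) / (sum x + sum y).

    By default the input table is first converted to per-sample proportions
    so that unequal sequencing depths do not masquerade as composition
    differences; ``raw_counts=True`` computes the distance on counts as-is.
    """
    if isinstance(props, FeatureTable):
        df = props.to_dataframe().astype(float) if raw_counts else relative_abundance(props)
    else:
        df = props.astype(float)
    x = df.to_numpy().T  # samples x features
    if x.shape[0] < 2:
        raise CommunityError("need at least two samples")
    d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # two all-zero samples: defined as identical
    return DistanceMatrix(list(df.columns), d)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------


def pcoa(dm: DistanceMatrix, eig_rtol: float = 1e-10) -> OrdinationResult:
    """Classical metric scaling (principal coordinates analysis).

    Double-centers B = -0.5 * J D^2 J, eigendecomposes, and keeps the axes
    with positive eigenvalues; coordinates are eigenvectors scaled by
    sqrt(eigenvalue). Negative eigenvalues (non-Euclidean distances) are
    discarded without correction; proportions explained are relative to the
    positive-eigenvalue total.
    """
    d = dm.d
    n = d.shape[0]
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = eig_rtol * max(abs(eigvals[0]), 1.0) if n else 0.0
    keep = eigvals > tol
    eigvals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(eigvals)
    total = eigvals.sum()
    prop = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return OrdinationResult(
        sample_ids=list(dm.sample_ids),
        eigenvalues=eigvals,
        coordinates=coords,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------


def _group_masks(labels: list[str]) -> tuple[list[str], np.ndarray]:
    names = sorted(set(labels))
    masks = np.stack([np.array([l == g for l in labels]) for g in names])
    return names, masks


def _ss_within(d2: np.ndarray, masks: np.ndarray) -> float:
    ss = 0.0
    for m in masks:
        ng = int(m.sum())
        if ng > 1:
            ss += d2[np.ix_(m, m)].sum() / (2.0 * ng)
    return ss


def _pseudo_f(d2: np.ndarray, masks: np.ndarray, ss_total: float):
    n = d2.shape[0]
    g = masks.shape[0]
    ss_w = _ss_within(d2, masks)
    ss_b = ss_total - ss_w
    if ss_w <= 0:
        # all points within each group coincide: perfect separation
        f = np.inf if ss_b > 0 else 0.0
    else:
        f = (ss_b / (g - 1)) / (ss_w / (n - g))
    return f, ss_w


def permanova(
    dm: DistanceMatrix,
    labels: dict[str, str] | list[str],
    n_perm: int = 9999,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous
    per-group terms; the pseudo-F compares between- to within-group sums of
    squares. The p-value counts label permutations with F at least the
    observed, with the identity permutation included:
    p = (hits + 1) / (n_perm + 1). ``exhaustive=True`` enumerates all
    distinct label arrangements instead (p = hits / total, identity
    included among the arrangements).
    """
    lab = _labels_in_order(dm.sample_ids, labels)
    names, masks = _group_masks(lab)
    n = len(lab)
    if len(names) < 2:
        raise CommunityError("PERMANOVA needs at least two groups")
    if n <= len(names):
        raise CommunityError("fewer samples than (groups + 1)")
    d2 = dm.d**2
    ss_total = d2.sum() / (2.0 * n)
    f_obs, ss_w = _pseudo_f(d2, masks, ss_total)
    r2 = 1.0 - ss_w / ss_total if ss_total > 0 else 0.0

    if ss_total == 0:
        return PermanovaResult(0.0, 0.0, 1.0, n_perm, seed)

    lab_arr = np.array(lab)
    if exhaustive:
        hits = 0
        total = 0
        for perm in _distinct_arrangements(lab_arr):
            _, pmasks = _group_masks(list(perm))
            f_p, _ = _pseudo_f(d2, pmasks, ss_total)
            total += 1
            if f_p >= f_obs - 1e-12:
                hits += 1
        p = hits / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(lab_arr)
            pmasks = np.stack([perm == g for g in names])
            f_p, _ = _pseudo_f(d2, pmasks, ss_total)
            if f_p >= f_obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        n_used = n_perm
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_used,
        seed=seed,
    )


def _labels_in_order(sample_ids: list[str], labels) -> list[str]:
    if isinstance(labels, dict):
        missing = [s for s in sample_ids if s not in labels]
        if missing:
            raise CommunityError(f"missing group label for sample(s) {missing}")
        return [labels[s] for s in sample_ids]
    labels = list(labels)
    if len(labels) != len(sample_ids):
        raise CommunityError("labels length does not match samples")
    return labels


def _distinct_arrangements(labels: np.ndarray):
    """All distinct multiset permutations of the label vector."""
    n = len(labels)
    names = sorted(set(labels.tolist()))
    counts = {g: int((labels == g).sum()) for g in names}
    total = factorial(n)
    for c in counts.values():
        total //= factorial(c)
    if total > 2_000_000:
        raise CommunityError(
            f"{total} distinct arrangements: too many to enumerate"
        )

    def rec(positions: list[int], remaining: dict[str, int], current: list[str]):
        if not positions:
            yield list(current)
            return
        for g in names:
            if remaining[g] > 0:
                remaining[g] -= 1
                current.append(g)
                yield from rec(positions[1:], remaining, current)
                current.pop()
                remaining[g] += 1

    yield from rec(list(range(n)), dict(counts), [])


def permdisp(
    dm: DistanceMatrix,
    labels: dict[str, str] | list[str],
    n_perm: int = 9999,
    seed: int | None = 0,
) -> DispersionResult:
    """Homogeneity of multivariate dispersions (betadisper-style).

    Samples are embedded by PCoA (positive-eigenvalue axes only), each
    sample's dispersion z_i is its Euclidean distance to its group centroid
    in that space, F is the one-way ANOVA statistic on z, and the p-value
    permutes z among samples. The imaginary-axis bookkeeping some reference
    implementations apply to negative eigenvalues is intentionally omitted.
    """
    lab = _labels_in_order(dm.sample_ids, labels)
    names, masks = _group_masks(lab)
    if len(names) < 2:
        raise CommunityError("need at least two groups")
    small = [g for g, m in zip(names, masks) if m.sum() < 2]
    if small:
        raise CommunityError(f"group(s) with fewer than two samples: {small}")
    ord_res = pcoa(dm)
    coords = ord_res.coordinates
    z = np.empty(len(lab))
    group_means: dict[str, float] = {}
    for g, m in zip(names, masks):
        centroid = coords[m].mean(axis=0)
        dist = np.linalg.norm(coords[m] - centroid, axis=1)
        z[m] = dist
        group_means[g] = float(dist.mean())

    def anova_f(values: np.ndarray) -> float:
        groups = [values[m] for m in masks]
        if all(np.ptp(v) == 0 for v in groups) and np.ptp(values) == 0:
            return 0.0
        f = sps.f_oneway(*groups).statistic
        return 0.0 if np.isnan(f) else float(f)

    f_obs = anova_f(z)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if anova_f(rng.permutation(z)) >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return DispersionResult(
        f_statistic=float(f_obs),
        p_value=float(p),
        group_mean_distance=group_means,
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Paired correlations
# ---------------------------------------------------------------------------


def select_shared_features(
    table_a: FeatureTable,
    table_b: FeatureTable,
    min_total: int = 100,
    per_sample: bool = False,
) -> list[str]:
    """Features abundant enough for paired correlation analysis.

    Default: total count over all samples of both tables strictly exceeds
    ``min_total``. ``per_sample=True`` instead requires > min_total in every
    single sample — the stricter reading of "present more than N times in
    all samples".
    """
    shared = [f for f in table_a.feature_ids if f in set(table_b.feature_ids)]
    if not shared:
        import warnings

        warnings.warn("tables share no features", stacklevel=2)
        return []
    a = table_a.filter_features(shared).counts
    b = table_b.filter_features(shared).counts
    if per_sample:
        keep = (a > min_total).all(axis=1) & (b > min_total).all(axis=1)
    else:
        keep = (a.sum(axis=1) + b.sum(axis=1)) > min_total
    return [f for f, k in zip(shared, keep) if k]


#: Feature-count limit below which Spearman p-values use exact permutation.
SPEARMAN_EXACT_LIMIT = 8


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all permutations of one rank vector."""
    k = len(xr)
    hits = 0
    total = 0
    denom_x = np.sqrt(((xr - xr.mean()) ** 2).sum())
    yc = yr - yr.mean()
    denom_y = np.sqrt((yc**2).sum())
    for perm in itertools.permutations(range(k)):
        r = float((xr[list(perm)] - xr.mean()) @ yc) / (denom_x * denom_y)
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            hits += 1
    return hits / total


def paired_spearman(
    table_a: FeatureTable,
    table_b: FeatureTable,
    pairs: dict[str, tuple[str, str]],
    features: list[str],
) -> tuple[list[PairedCorrelation], float | None]:
    """Spearman correlation of paired sample profiles over selected features.

    ``pairs`` maps pair_id -> (sample in table_a, sample in table_b). The
    correlation uses absolute counts over the given features with midranks
    for ties. Per-pair p-values come from the t-distribution approximation,
    or exact rank-permutation enumeration when the feature count is at most
    8. Bonferroni m = number of pairs tested. Pairs with a constant vector
    have undefined rho, are flagged (rho=None) and excluded from the
    average; the second return value is the arithmetic mean of defined rho.
    """
    if not features:
        raise CommunityError("no features selected for correlation")
    a_df = table_a.filter_features(features).to_dataframe()
    b_df = table_b.filter_features(features).to_dataframe()
    m = len(pairs)
    results: list[PairedCorrelation] = []
    rhos: list[float] = []
    k = len(features)
    for pid, (sa, sb) in pairs.items():
        if sa not in a_df.columns or sb not in b_df.columns:
            raise CommunityError(f"pair {pid!r}: sample missing from table")
        va = a_df[sa].to_numpy(dtype=float)
        vb = b_df[sb].to_numpy(dtype=float)
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            results.append(PairedCorrelation(pid, None, None, None, k))
            continue
        rho, p_t = sps.spearmanr(va, vb)
        rho = float(rho)
        if k <= SPEARMAN_EXACT_LIMIT:
            xr, yr = sps.rankdata(va), sps.rankdata(vb)
            p_raw = _spearman_exact_p(xr, yr, rho)
        else:
            p_raw = float(p_t)
        p_bonf = min(1.0, m * p_raw)
        results.append(PairedCorrelation(pid, rho, p_raw, p_bonf, k))
        rhos.append(rho)
    avg = float(np.mean(rhos)) if rhos else None
    return results, avg
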