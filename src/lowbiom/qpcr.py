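"""Absolute 16S rRNA gene quantification from qPCR and small-sample testing.

A standard dilution series with known copy numbers calibrates a linear
standard curve Cq = slope * log10(copies) + intercept; unknown samples are
inverted through the curve and scaled to the reporting unit (per swab, per
100 ul of fluid, ...). Amplification efficiency is ``10**(-1/slope) - 1``
(1.0 for a perfect doubling per cycle, slope -3.3219).

Specimen and field-control copy numbers are compared with a two-tailed
Mann-Whitney U test. For the small group sizes typical of these studies the
p-value is exact: all C(n1+n2, n1) assignments of the pooled observations to
groups are enumerated and the two-tailed p is the probability of an
assignment whose U lies at least as far from the null mean n1*n2/2 as the
observed one. Larger samples fall back to the normal approximation with tie
and continuity corrections.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from functools import lru_cache
from math import comb, erfc, sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StandardCurve",
    "QpcrMeasurement",
    "GroupComparison",
    "MannWhitneyMethod",
    "fit_standard_curve",
    "cq_to_copies",
    "mann_whitney_u",
    "read_qpcr_csv",
    "quantify_run",
    "quantify",
    "compare_groups",
]

#: Maximum pooled sample size for exact enumeration.
EXACT_LIMIT = 20


class QpcrError(ValueError):
    pass


class MannWhitneyMethod(str, enum.Enum):
    EXACT_ENUMERATION = "exact_enumeration"
    NORMAL_APPROXIMATION = "normal_approximation"


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def predict_cq(self, copies: float) -> float:
        return self.slope * np.log10(copies) + self.intercept


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    cq: float | None  # None = not detected
    replicate: int = 0


@dataclass(frozen=True)
class GroupComparison:
    u_statistic: float
    n1: int
    n2: int
    p_two_tailed: float
    method: MannWhitneyMethod


# ---------------------------------------------------------------------------
# Standard curve
# ---------------------------------------------------------------------------


def fit_standard_curve(copies, cq) -> StandardCurve:
    """Least-squares fit of Cq against log10 of standard copy numbers."""
    copies = np.asarray(copies, dtype=float)
    cq = np.asarray(cq, dtype=float)
    if copies.shape != cq.shape or copies.ndim != 1:
        raise QpcrError("copies and cq must be 1-D and of equal length")
    if copies.size < 3:
        raise QpcrError("standard curve needs at least 3 dilution points")
    if np.any(copies <= 0):
        raise QpcrError("standard copy numbers must be positive")
    x = np.log10(copies)
    if np.ptp(x) == 0:
        raise QpcrError("standard series has zero variance in log10(copies)")
    fit = sps.linregress(x, cq)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def cq_to_copies(
    cq: float | None,
    curve: StandardCurve,
    unit_scale: float = 1.0,
    not_detected_as_zero: bool = False,
) -> float | None:
    """Invert the standard curve: copies per reporting unit.

    ``cq=None`` marks a non-detect; by default it propagates as ``None``
    (exclude from downstream summaries), or maps to 0.0 when
    ``not_detected_as_zero`` is set.
    """
    if unit_scale <= 0:
        raise QpcrError("unit_scale must be positive")
    if cq is None:
        return 0.0 if not_detected_as_zero else None
    if not np.isfinite(cq):
        raise QpcrError(f"non-finite Cq value {cq!r}")
    return float(unit_scale * 10.0 ** ((cq - curve.intercept) / curve.slope))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _combination_matrix(n: int, k: int) -> np.ndarray:
    """All C(n, k) index subsets as a (C, k) int array."""
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def _u_from_ranks(rank_sum_x: float, n1: int) -> float:
    return rank_sum_x - n1 * (n1 + 1) / 2.0


def mann_whitney_u(x, y) -> GroupComparison:
    """Two-tailed Mann-Whitney U test with exact small-sample enumeration.

    U is computed from midrank sums (ties get their average rank). For
    pooled sizes up to 20 the test enumerates every assignment of the
    pooled values to the two groups; the two-tailed p-value is the
    proportion of assignments with |U - n1*n2/2| >= the observed distance.
    Otherwise a normal approximation with tie correction and a 0.5
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise QpcrError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_from_ranks(ranks[:n1].sum(), n1)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= EXACT_LIMIT:
        combos = _combination_matrix(n1 + n2, n1)
        rank_sums = ranks[combos].sum(axis=1)
        u_all = rank_sums - n1 * (n1 + 1) / 2.0
        d_obs = abs(u_obs - mu)
        # tolerance guards midrank float error in the distance comparison
        hits = np.count_nonzero(np.abs(u_all - mu) >= d_obs - 1e-9)
        p = hits / comb(n1 + n2, n1)
        method = MannWhitneyMethod.EXACT_ENUMERATION
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var == 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, erfc(z / sqrt(2.0)))
        method = MannWhitneyMethod.NORMAL_APPROXIMATION
    return GroupComparison(
        u_statistic=float(u_obs),
        n1=n1,
        n2=n2,
        p_two_tailed=float(min(p, 1.0)),
        method=method,
    )


# ---------------------------------------------------------------------------
# qPCR workbook handling
# ---------------------------------------------------------------------------

_QPCR_COLS = ("run_id", "sample_id", "role", "cq")


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    """Read a qPCR result sheet.

    Columns: run_id, sample_id, role in {unknown, standard, ntc}, copies
    (standards only), cq (empty = not detected), replicate (optional).
    """
    df = pd.read_csv(path, dtype={"run_id": str, "sample_id": str, "role": str})
    missing = [c for c in _QPCR_COLS if c not in df.columns]
    if missing:
        raise QpcrError(f"{path}: missing qPCR column(s) {missing}")
    bad = set(df["role"].dropna()) - {"unknown", "standard", "ntc"}
    if bad:
        raise QpcrError(f"{path}: unknown role value(s) {sorted(bad)}")
    if "copies" not in df.columns:
        df["copies"] = np.nan
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return df


def quantify_run(
    run: pd.DataFrame,
    unit_scale: float = 1.0,
    replicate_average: str = "copies",
    not_detected_as_zero: bool = False,
) -> tuple[StandardCurve, dict[str, float]]:
    """Quantify one qPCR run against its own standard series.

    ``replicate_average`` chooses whether technical replicates are combined
    as the mean of back-calculated copies (default) or as the mean Cq
    converted once.
    """
    if replicate_average not in ("copies", "cq"):
        raise QpcrError("replicate_average must be 'copies' or 'cq'")
    standards = run[run["role"] == "standard"].dropna(subset=["cq", "copies"])
    curve = fit_standard_curve(standards["copies"], standards["cq"])
    results: dict[str, float] = {}
    unknowns = run[run["role"] == "unknown"]
    for sid, grp in unknowns.groupby("sample_id", sort=False):
        cqs = [None if pd.isna(c) else float(c) for c in grp["cq"]]
        if replicate_average == "cq":
            detected = [c for c in cqs if c is not None]
            mean_cq = float(np.mean(detected)) if detected else None
            value = cq_to_copies(mean_cq, curve, unit_scale, not_detected_as_zero)
        else:
            copies = [
                cq_to_copies(c, curve, unit_scale, not_detected_as_zero)
                for c in cqs
            ]
            copies = [c for c in copies if c is not None]
            value = float(np.mean(copies)) if copies else None
        if value is not None:
            results[str(sid)] = value
    return curve, results


def quantify(
    qpcr: pd.DataFrame,
    unit_scale: float = 1.0,
    replicate_average: str = "copies",
    not_detected_as_zero: bool = False,
) -> dict[str, float]:
    """Quantify all runs; each run is calibrated by its own standard series."""
    out: dict[str, float] = {}
    for _, run in qpcr.groupby("run_id", sort=False):
        _, res = quantify_run(run, unit_scale, replicate_average, not_detected_as_zero)
        dup = set(res) & set(out)
        if dup:
            raise QpcrError(f"sample(s) quantified in multiple runs: {sorted(dup)}")
        out.update(res)
    return out


def compare_groups(
    copies: dict[str, float],
    group_of: dict[str, str],
    group_a: str,
    group_b: str,
) -> GroupComparison:
    """Mann-Whitney comparison of copy numbers between two labelled groups."""
    a = [v for s, v in copies.items() if group_of.get(s) == group_a]
    b = [v for s, v in copies.items() if group_of.get(s) == group_b]
    return mann_whitney_u(a, b)
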