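"""Size-factor normalization and Welch/BH differential abundance.

The normalization follows the median-of-ratios scheme: a pseudo-reference
``R_i`` is built per feature as the geometric mean across samples, per-sample
size factors ``S_j`` are the median of the ratios ``I_ij / R_i`` over features
with strictly positive values in every sample, and normalized values are
``N_ij = I_ij / S_j``.

Differential abundance is a two-sided Welch t-test on log2-transformed
normalized values with Benjamini-Hochberg adjustment.  The same engine is
applied to count matrices (RNA-seq, Ribo-seq) and to strictly positive
intensity matrices (TMT-like proteomics); the only knob that differs is the
pseudocount added before the log transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceMatrix",
    "SizeFactors",
    "NormalizedMatrix",
    "filter_features",
    "compute_size_factors",
    "normalize_matrix",
    "welch_t",
    "welch_differential",
    "bh_adjust",
]


class NormalizationError(ValueError):
    """Raised when size factors cannot be computed for a matrix."""


@dataclass
class AbundanceMatrix:
    """Raw feature-by-sample nonnegative measurements.

    Parameters
    ----------
    data
        Feature-by-sample values; the index holds feature identifiers and the
        columns hold sample identifiers.  Missing values are represented as
        NaN.  Negative values are rejected.
    conditions
        Mapping from sample identifier to condition label; must cover every
        column of ``data``.
    """

    data: pd.DataFrame
    conditions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        values = self.data.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("abundance matrix contains negative values")
        missing = [s for s in self.data.columns if s not in self.conditions]
        if self.conditions and missing:
            raise ValueError(f"samples without condition label: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def condition_samples(self) -> dict[str, list[str]]:
        """Samples per condition, preserving column order."""
        out: dict[str, list[str]] = {}
        for s in self.data.columns:
            out.setdefault(self.conditions[s], []).append(s)
        return out


@dataclass
class SizeFactors:
    """Pseudo-reference ``R_i`` and per-sample size factors ``S_j``."""

    reference: pd.Series
    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be strictly positive")


@dataclass
class NormalizedMatrix:
    """Size-factor-normalized matrix ``N_ij = I_ij / S_j`` with provenance."""

    data: pd.DataFrame
    size_factors: SizeFactors
    conditions: Mapping[str, str] = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def filter_features(matrix: AbundanceMatrix, require_complete: bool = False) -> AbundanceMatrix:
    """Drop unusable feature rows.

    All-zero rows (NaN counts as zero) are always removed.  With
    ``require_complete`` every row containing a missing or zero entry is also
    removed — the completeness rule used for proteomics, where only features
    detected in every sample are tested.

    Raises
    ------
    ValueError
        If no feature survives the filter.
    """
    values = matrix.data.to_numpy(dtype=float)
    filled = np.nan_to_num(values, nan=0.0)
    keep = (filled != 0).any(axis=1)
    if require_complete:
        keep &= np.isfinite(values).all(axis=1) & (values != 0).all(axis=1)
    if not keep.any():
        raise ValueError("feature filter removed every row")
    return AbundanceMatrix(matrix.data.loc[keep], dict(matrix.conditions))


def compute_size_factors(matrix: AbundanceMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    ``R_i = exp(mean_j log I_ij)`` over features with strictly positive,
    non-missing values in every sample; ``S_j = median_i (I_ij / R_i)`` over
    those same features.  Features with any zero or missing entry do not
    enter the pseudo-reference or the median (the geometric mean is undefined
    at zero) but are still normalized downstream.
    """
    values = matrix.data.to_numpy(dtype=float)
    eligible = np.isfinite(values).all(axis=1) & (values > 0).all(axis=1)
    if not eligible.any():
        raise NormalizationError(
            "no feature has strictly positive values in every sample; "
            "size factors are undefined"
        )
    sub = values[eligible]
    log_ref = np.log(sub).mean(axis=1)
    ratios = sub / np.exp(log_ref)[:, None]
    factors = np.median(ratios, axis=0)
    reference = pd.Series(np.exp(log_ref), index=matrix.data.index[eligible], name="R_i")
    return SizeFactors(reference, pd.Series(factors, index=matrix.data.columns, name="S_j"))


def normalize_matrix(matrix: AbundanceMatrix, sf: SizeFactors) -> NormalizedMatrix:
    """Divide every sample column by its size factor."""
    missing = [s for s in matrix.data.columns if s not in sf.factors.index]
    if missing:
        raise ValueError(f"no size factor for samples: {missing}")
    data = matrix.data / sf.factors.reindex(matrix.data.columns)
    return NormalizedMatrix(data, sf, dict(matrix.conditions))


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-sided Welch t-test of ``a`` versus ``b`` row-wise.

    Parameters
    ----------
    a, b
        Arrays of shape ``(n_features, n_replicates)``; the statistic tests
        ``mean(a) - mean(b)`` per row.

    Returns
    -------
    t, df, p, degenerate
        Welch t statistic, Welch-Satterthwaite degrees of freedom, two-sided
        p-value, and a flag marking rows where both group variances are zero.
        Degenerate rows report ``p = 1`` when the means agree and ``p = 0``
        otherwise (never NaN).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch test needs at least 2 replicates per group")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    degenerate = se2 == 0
    df = np.where(degenerate, float(n1 + n2 - 2), df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    equal = degenerate & (m1 == m2)
    unequal = degenerate & (m1 != m2)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(unequal, np.sign(m1 - m2) * np.inf, t)
    p = np.where(unequal, 0.0, p)
    return t, df, p, degenerate


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Output order matches input order.  NaN entries propagate as NaN and are
    excluded from the ranking; all finite entries must lie in [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    ps = p[mask]
    if ps.size == 0:
        return out
    if (ps < 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = ps.size
    order = np.argsort(ps, kind="mergesort")
    scaled = ps[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    out[mask] = q
    return out


def _directions(log2fc: np.ndarray) -> np.ndarray:
    out = np.full(log2fc.shape, "flat", dtype=object)
    out[log2fc > 0] = "up"
    out[log2fc < 0] = "down"
    return out


def welch_differential(
    norm: NormalizedMatrix,
    threshold: float = 0.05,
    pseudocount: float = 0.5,
    treated: str | None = None,
    control: str | None = None,
) -> pd.DataFrame:
    """Per-feature Welch test on log2 normalized values between two conditions.

    Parameters
    ----------
    norm
        Normalized matrix carrying condition labels for every sample.
    threshold
        BH q-value cut-off for the ``significant`` flag.
    pseudocount
        Added before the log2 transform; use 0.5 for counts and 0 for
        strictly positive intensities.
    treated, control
        Condition labels; when omitted, labels named ``"treated"`` and
        ``"control"`` are used if present, otherwise the two labels in sorted
        order are taken as (control, treated).

    Returns
    -------
    pandas.DataFrame
        Indexed by feature id with columns ``log2fc`` (treated minus control
        mean of log2 values), ``t``, ``df``, ``p``, ``q``, ``significant``,
        ``direction`` and ``degenerate``.
    """
    groups: dict[str, list[str]] = {}
    for s in norm.data.columns:
        groups.setdefault(norm.conditions[s], []).append(s)
    if treated is None or control is None:
        labels = sorted(groups)
        if {"treated", "control"} <= set(labels):
            control, treated = "control", "treated"
        elif len(labels) == 2:
            control, treated = labels
        else:
            raise ValueError(f"cannot infer contrast from conditions {labels}")
    for label in (treated, control):
        if label not in groups:
            raise ValueError(f"condition {label!r} not present")
        if len(groups[label]) < 2:
            raise ValueError(f"condition {label!r} has fewer than 2 samples")

    log2 = np.log2(norm.data.to_numpy(dtype=float) + pseudocount)
    idx = {s: i for i, s in enumerate(norm.data.columns)}
    a = log2[:, [idx[s] for s in groups[treated]]]
    b = log2[:, [idx[s] for s in groups[control]]]
    t, df, p, degenerate = welch_t(a, b)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    q = bh_adjust(p)
    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "significant": q < threshold,
            "direction": _directions(log2fc),
            "degenerate": degenerate,
        },
        index=norm.data.index,
    )
    result.index.name = "feature_id"
    return result
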