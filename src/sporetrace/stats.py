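"""Population-level statistics: PERMANOVA, scaled PCA, rank correlation, growth.

PERMANOVA is implemented from first principles on Euclidean distances:
SS_total = sum of squared pairwise distances / n, within-group SS analogously
per group, pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)), and the p-value
from label permutations with the +1 correction.  Single-factor partitioning
only.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateInputError,
    InvalidDesignError,
    InvalidInputError,
    OutOfRangeError,
)


@dataclass
class PermanovaResult:
    factor: str
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str  # "random" | "exhaustive"


def _ss_decomposition(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within, ss_total - ss_within


def _pseudo_f(ss_between: float, ss_within: float, n: int, g: int) -> float:
    if ss_within <= 0:  # perfect separation
        return float("inf")
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def _batched_within(d2: np.ndarray, label_matrix: np.ndarray) -> np.ndarray:
    """SS_within for many label vectors at once (rows of ``label_matrix``)."""
    ss = np.zeros(label_matrix.shape[0])
    for g in np.unique(label_matrix):
        mask = (label_matrix == g).astype(float)
        n_g = mask.sum(axis=1)
        ss += np.einsum("pi,ij,pj->p", mask, d2, mask) / (2.0 * n_g)
    return ss


def permanova(
    X,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
    factor: str = "group",
) -> PermanovaResult:
    """One-factor PERMANOVA on Euclidean distances with permutation p-value.

    ``exhaustive=True`` enumerates all n! label arrangements (n <= 9) and
    reports p as the fraction with pseudo-F >= observed; otherwise ``n_perm``
    random permutations are drawn and p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    X = np.asarray(X, dtype=float)
    labels, _ = pd.factorize(np.asarray(grouping))
    n = X.shape[0]
    if labels.shape[0] != n:
        raise InvalidInputError("grouping length must match number of rows")
    groups, counts = np.unique(labels, return_counts=True)
    g = len(groups)
    if g < 2:
        raise InvalidDesignError("need at least 2 groups")
    if (counts < 2).any():
        raise InvalidDesignError("every group needs at least 2 samples")

    d2 = squareform(pdist(X, metric="euclidean") ** 2)
    ss_total, ss_within, ss_between = _ss_decomposition(d2, labels)
    if ss_total <= 0:
        raise DegenerateInputError("all samples identical; no variance to partition")
    f_obs = _pseudo_f(ss_between, ss_within, n, g)
    r2 = ss_between / ss_total

    if exhaustive:
        if math.factorial(n) > 500_000:
            raise InvalidInputError(f"exhaustive enumeration infeasible for n={n}")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            _, ss_w, ss_b = _ss_decomposition(d2, labels[list(perm)])
            if _pseudo_f(ss_b, ss_w, n, g) >= f_obs - 1e-12:
                count += 1
            total += 1
        return PermanovaResult(factor, r2, f_obs, count / total, total, seed, "exhaustive")

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
    ss_w = _batched_within(d2, perms)
    ss_b = ss_total - ss_w
    with np.errstate(divide="ignore"):
        f_perm = np.where(
            ss_w > 0, (ss_b / (g - 1)) / (np.where(ss_w > 0, ss_w, 1.0) / (n - g)), np.inf
        )
    count = int((f_perm >= f_obs - 1e-12).sum())
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(factor, r2, f_obs, p, n_perm, seed, "random")


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    dropped_columns: list


def pca_scores(X, scale: bool = True) -> PCAResult:
    """PCA on column-standardized data via SVD.

    Zero-variance columns are dropped with a warning; an all-constant matrix
    raises DegenerateInputError.  Explained-variance fractions sum to 1.
    """
    frame = pd.DataFrame(X)
    sd = frame.std(ddof=1)
    dropped = list(frame.columns[(sd == 0) | sd.isna()])
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
        frame = frame.drop(columns=dropped)
    if frame.shape[1] < 1 or frame.shape[0] < 2:
        raise DegenerateInputError("not enough varying data for PCA")
    Z = frame.to_numpy(dtype=float)
    Z = Z - Z.mean(axis=0)
    if scale:
        Z = Z / Z.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    evr = s**2 / (s**2).sum()
    return PCAResult(scores=u * s, loadings=vt.T, explained_variance_ratio=evr,
                     dropped_columns=dropped)


def aggregate_replicate_means(freqs: pd.DataFrame, by=("condition", "incubation", "mix")) -> pd.DataFrame:
    """Average technical replicates into one row per grouping key; columns are
    strain frequencies (the sample matrix for PCA/PERMANOVA)."""
    wide = freqs.pivot_table(
        index=[*by, "replicate"], columns="strain_id", values="frequency", aggfunc="mean"
    )
    return wide.groupby(level=list(range(len(by)))).mean()


def input_output_correlation(
    initial: pd.Series | np.ndarray,
    finals: pd.DataFrame | dict,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Spearman correlation of initial vs final strain frequencies per condition.

    P-values are adjusted across conditions by Benjamini-Hochberg (default) or
    Holm.
    """
    if adjust not in {"bh", "holm"}:
        raise InvalidInputError("adjust must be 'bh' or 'holm'")
    finals = pd.DataFrame(finals)
    initial = np.asarray(initial, dtype=float)
    rows = []
    for cond in finals.columns:
        final = finals[cond].to_numpy(dtype=float)
        if final.shape[0] != initial.shape[0]:
            raise InvalidInputError(
                f"length mismatch for {cond}: {final.shape[0]} vs {initial.shape[0]}"
            )
        rho, p = sps.spearmanr(initial, final)
        rows.append({"condition": cond, "rho": float(rho), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    method = "fdr_bh" if adjust == "bh" else "holm"
    out["p_adjusted"] = multipletests(out["p_raw"], method=method)[1]
    out["adjustment"] = adjust
    return out


@dataclass
class GrowthCurve:
    """Optical-density time series on a regular sampling grid."""

    time_min: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_min.shape != self.od.shape:
            raise InvalidInputError("time and OD arrays must have the same length")
        if self.time_min.size < 2:
            raise InvalidInputError("need at least 2 time points")
        if not (np.diff(self.time_min) > 0).all():
            raise InvalidInputError("time points must be strictly increasing")


def growth_increment(curve: GrowthCurve, horizon_min: float = 16 * 60) -> float:
    """OD increment after ``horizon_min``: reading nearest to the horizon
    (ties to the earlier point) minus the reading at the first time point."""
    if horizon_min > curve.time_min[-1]:
        raise OutOfRangeError(
            f"horizon {horizon_min} min beyond curve end {curve.time_min[-1]} min"
        )
    idx = int(np.argmin(np.abs(curve.time_min - horizon_min)))
    return float(curve.od[idx] - curve.od[0])
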