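"""Linear discriminant analysis: scatter statistics, Fisher's ratio, and the
closed-form discriminant direction.

For two classes B and U with feature means mu_B, mu_U and per-class sample
covariances S_B, S_U, the within-scatter is S_w = S_B + S_U and the
between-scatter the rank-one S_b = (mu_B - mu_U)(mu_B - mu_U)^T. Fisher's
ratio

    J(w) = (w^T S_b w) / (w^T (S_w + lambda*I) w)

is maximised by w ∝ (S_w + lambda*I)^{-1} (mu_B - mu_U); the small ridge
lambda keeps the problem well-posed when S_w is rank deficient (as happens
whenever the feature width exceeds the sample count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

DEFAULT_LAMBDA = 0.05


@dataclass(frozen=True)
class ScatterStats:
    """Class means and scatter matrices of a two-class feature set."""

    mu_B: np.ndarray
    mu_U: np.ndarray
    S_B: np.ndarray
    S_U: np.ndarray

    @property
    def S_w(self) -> np.ndarray:
        return self.S_B + self.S_U

    @property
    def mean_gap(self) -> np.ndarray:
        return self.mu_B - self.mu_U

    @property
    def S_b(self) -> np.ndarray:
        gap = self.mean_gap
        return np.outer(gap, gap)


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        data = data.to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(data, dtype=float))


def scatter_stats(data_B, data_U) -> ScatterStats:
    """Means and per-class sample covariances (ddof=1) of the two data sets."""
    xb, xu = _as_matrix(data_B), _as_matrix(data_U)
    if xb.shape[1] != xu.shape[1]:
        raise ValueError(
            f"dimension mismatch: B has {xb.shape[1]} columns, U has {xu.shape[1]}"
        )
    if len(xb) < 2 or len(xu) < 2:
        raise ValueError("each class needs at least 2 rows")
    return ScatterStats(
        mu_B=xb.mean(axis=0),
        mu_U=xu.mean(axis=0),
        S_B=np.cov(xb, rowvar=False, ddof=1).reshape(xb.shape[1], xb.shape[1]),
        S_U=np.cov(xu, rowvar=False, ddof=1).reshape(xu.shape[1], xu.shape[1]),
    )


def fisher_ratio(w: np.ndarray, stats: ScatterStats, lambda_reg: float = 0.0) -> float:
    """J(w); invariant under rescaling of w."""
    w = np.asarray(w, dtype=float)
    denom_mat = stats.S_w + lambda_reg * np.eye(len(w))
    denom = w @ denom_mat @ w
    if not w.any():
        raise ValueError("w must be nonzero")
    return float((w @ stats.mean_gap) ** 2 / denom)


def lda_direction(stats: ScatterStats, lambda_reg: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Unit-norm maximiser of Fisher's ratio, oriented so w^T mu_B >= w^T mu_U."""
    dim = len(stats.mu_B)
    m = stats.S_w + lambda_reg * np.eye(dim)
    try:
        w = linalg.solve(m, stats.mean_gap, assume_a="sym")
    except linalg.LinAlgError:
        raise linalg.LinAlgError(
            "regularised within-scatter matrix is singular; increase lambda_reg"
        ) from None
    if not np.all(np.isfinite(w)):
        raise linalg.LinAlgError(
            "regularised within-scatter matrix is singular; increase lambda_reg"
        )
    norm = np.linalg.norm(w)
    if norm == 0:
        # equal class means: any direction is as good (J = 0); pick e_1
        w = np.zeros(dim)
        w[0] = 1.0
        return w
    w = w / norm
    if w @ stats.mean_gap < 0:
        w = -w
    return w


def optimal_fisher_ratio(stats: ScatterStats, lambda_reg: float = DEFAULT_LAMBDA) -> float:
    """J at the optimum: gap^T (S_w + lambda I)^{-1} gap (rank-one S_b)."""
    m = stats.S_w + lambda_reg * np.eye(len(stats.mu_B))
    return float(stats.mean_gap @ linalg.solve(m, stats.mean_gap, assume_a="sym"))


def split_by_label(table: pd.DataFrame, feature_cols=None):
    """Split a labelled descriptor table into (B features, U features)."""
    if "label" not in table.columns:
        raise ValueError("table needs a 'label' column with values 'B'/'U'")
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in ("label", "time")]
    b = table.loc[table["label"] == "B", feature_cols].to_numpy(dtype=float)
    u = table.loc[table["label"] == "U", feature_cols].to_numpy(dtype=float)
    if len(b) == 0 or len(u) == 0:
        raise ValueError("both classes 'B' and 'U' must be present")
    return b, u
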