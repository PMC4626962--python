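"""Multivariate screening: correlation matrix and PCA with varimax rotation.

The screening stage asks which covariates move with PM2.5 (pairwise
Pearson correlations with two-sided significance flags from the
t-transform of r) and how the eight variables organize into a few
components (PCA on the correlation matrix of standardized variables,
Kaiser eigenvalue-greater-than-one retention, varimax rotation of the
retained loadings).

Varimax is implemented here directly as the classic pairwise Jacobi
rotation scheme; the test suite cross-checks it against an independent
reference implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import VARIABLES

__all__ = [
    "CorrelationResult",
    "correlation_matrix",
    "varimax",
    "LoadingMatrix",
    "pca_varimax",
]


@dataclass
class CorrelationResult:
    r: pd.DataFrame            # pairwise Pearson r (NaN for constant columns)
    p: pd.DataFrame            # two-sided p-values, t-transform with n-2 df
    stars: pd.DataFrame        # "**" p<0.01, "*" p<0.05, "" otherwise
    n: int

    def formatted(self) -> pd.DataFrame:
        """Matrix of '0.796**'-style strings mirroring a published table."""
        def cell(i, j):
            v = self.r.iat[i, j]
            if np.isnan(v):
                return "undefined"
            return f"{v:.3f}{self.stars.iat[i, j]}"

        k = len(self.r)
        return pd.DataFrame(
            [[cell(i, j) for j in range(k)] for i in range(k)],
            index=self.r.index, columns=self.r.columns,
        )

    def write_csv(self, path) -> None:
        self.formatted().to_csv(path, index_label="variable")


def correlation_matrix(
    records: pd.DataFrame, variables: list[str] | None = None
) -> CorrelationResult:
    """Pairwise Pearson correlations over complete rows, with p-flags.

    Rows with any missing value among *variables* are dropped (listwise
    deletion).  Constant columns yield NaN in their row/column.
    """
    variables = variables or VARIABLES
    data = records[variables].dropna()
    n = len(data)
    if n < 3:
        raise ValueError(f"need >= 3 complete rows, got {n}")
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    np.fill_diagonal(R, np.where(sd == 0, np.nan, 1.0))

    with np.errstate(invalid="ignore", divide="ignore"):
        rr = np.clip(R, -1.0, 1.0)
        t = rr * np.sqrt((n - 2) / (1.0 - rr * rr))
        P = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    P[np.isinf(t)] = 0.0
    np.fill_diagonal(P, 0.0)

    stars = np.where(P < 0.01, "**", np.where(P < 0.05, "*", ""))
    stars = np.where(np.isnan(R), "", stars)
    idx = pd.Index(variables)
    return CorrelationResult(
        r=pd.DataFrame(R, index=idx, columns=idx),
        p=pd.DataFrame(P, index=idx, columns=idx),
        stars=pd.DataFrame(stars, index=idx, columns=idx),
        n=n,
    )


def varimax(
    loadings: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> np.ndarray:
    """Orthogonal varimax rotation by pairwise Jacobi sweeps.

    Maximizes the summed variance of squared loadings per column; sweeps
    over all column pairs until the rotation criterion improves by less
    than *tol*.  Raw varimax (no row normalization).
    """
    L = np.array(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L

    def criterion(M):
        sq = M * M
        return float(np.sum(sq * sq) - np.sum(sq.sum(axis=0) ** 2) / p)

    last = criterion(L)
    for _ in range(max_iter):
        for a in range(k - 1):
            for b in range(a + 1, k):
                x, y = L[:, a], L[:, b]
                u = x * x - y * y
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                C = float(u @ u - v @ v)
                D = 2.0 * float(u @ v)
                num = D - 2.0 * A * B / p
                den = C - (A * A - B * B) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                L[:, a], L[:, b] = c * x + s * y, -s * x + c * y
        now = criterion(L)
        if now - last < tol:
            break
        last = now
    return L


def _fix_column_signs(L: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude loading is positive."""
    L = L.copy()
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


@dataclass
class LoadingMatrix:
    """Rotated component loadings and retained-variance bookkeeping."""

    variables: list[str]
    loadings: pd.DataFrame             # variables x retained components
    eigenvalues: np.ndarray            # all p eigenvalues, descending
    explained_cumulative: np.ndarray   # cumulative % variance, retained comps
    n_retained: int

    def write_csv(self, path) -> None:
        out = self.loadings.round(4).copy()
        out.loc["Cumulative %"] = np.round(self.explained_cumulative, 2)
        out.to_csv(path, index_label="variable")


def pca_varimax(
    records: pd.DataFrame,
    variables: list[str] | None = None,
    kaiser_after_rotation: bool = False,
    n_components: int | None = None,
) -> LoadingMatrix:
    """PCA of standardized variables with Kaiser retention and varimax.

    Variables are standardized to unit variance, the correlation matrix is
    eigendecomposed, components with eigenvalue > 1 are retained (Kaiser
    rule, applied to the unrotated eigenvalues by default), and the
    retained loadings are varimax-rotated.  With
    ``kaiser_after_rotation=True`` the rule is re-applied to the rotated
    sums of squared loadings and the component set re-rotated if any drop
    below one.  ``n_components`` overrides the retention rule with a fixed
    component count (published analyses of these eight variables retain
    four components even though only two population eigenvalues exceed
    one).  Cumulative explained % is computed from the rotated sums of
    squared loadings; its final entry (total retained variance) is
    invariant under rotation.
    """
    variables = variables or VARIABLES
    data = records[variables].dropna()
    if len(data) < len(variables) + 1:
        raise ValueError(
            f"need >= {len(variables) + 1} complete rows, got {len(data)}"
        )
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant variable(s) {bad} cannot be standardized")
    R = np.corrcoef(X, rowvar=False)

    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    if np.any(w < -1e-8):  # pragma: no cover - correlation matrices are PSD
        warnings.warn("correlation matrix has negative eigenvalues; clipping")
    w = np.clip(w, 0.0, None)

    if n_components is not None:
        if not 1 <= n_components <= len(variables):
            raise ValueError(f"n_components must be in [1, {len(variables)}]")
        k = int(n_components)
    else:
        k = max(int(np.sum(w > 1.0)), 1)
    rank = int(np.sum(w > 1e-12))
    if k > rank:
        warnings.warn(
            f"rank-deficient input: retaining {rank} of {k} Kaiser components"
        )
        k = rank

    def rotate(kk: int) -> np.ndarray:
        L = V[:, :kk] * np.sqrt(w[:kk])
        return _fix_column_signs(varimax(L))

    L_rot = rotate(k)
    if kaiser_after_rotation:
        while k > 1:
            ss = np.sum(L_rot * L_rot, axis=0)
            if np.all(ss > 1.0):
                break
            k = int(np.sum(ss > 1.0)) or 1
            L_rot = rotate(k)

    p = len(variables)
    ss_rot = np.sum(L_rot * L_rot, axis=0)
    cum = np.cumsum(ss_rot) / p * 100.0
    cols = [str(j + 1) for j in range(k)]
    return LoadingMatrix(
        variables=list(variables),
        loadings=pd.DataFrame(L_rot, index=variables, columns=cols),
        eigenvalues=w,
        explained_cumulative=cum,
        n_retained=k,
    )
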