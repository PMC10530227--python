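"""Correlation-matrix PCA of presence cells, with projection of absences.

The habitat space is shaped by the presence data alone: variables are
standardized by the presence means and standard deviations (so every
variable carries the same weight), the correlation matrix is
eigendecomposed, and any other rows — the absence cells — are projected
into that fixed space with the presence standardization.  Variable
diagnostics follow the usual correlation-PCA conventions:
contribution(j, q) = 100 * loading(j, q)^2 and cos^2(j, q) =
loading(j, q)^2 * lambda_q, the squared correlation between variable j
and score q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCSpace", "fit_pca", "project"]


@dataclass
class PCSpace:
    """A presence-data PC space.

    loadings columns are unit eigenvectors of the presence correlation
    matrix (all P of them, orthonormal); ``q`` is the number of retained
    axes used for projection and clustering.  Standard deviations use
    the n-denominator so that score variances equal the eigenvalues.
    """

    var_names: list[str]
    mean: np.ndarray  # (P,) presence means
    sd: np.ndarray  # (P,) presence s.d. (ddof=0)
    loadings: np.ndarray  # (P, P) orthonormal columns
    eigenvalues: np.ndarray  # (P,) descending
    explained_pct: np.ndarray  # (P,)
    scores: np.ndarray  # (M, q) presence scores on retained axes
    contributions: np.ndarray  # (P, P), % per axis column
    cos2: np.ndarray  # (P, P)
    q: int

    @property
    def p(self) -> int:
        return len(self.var_names)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.p)]
        return pd.DataFrame(self.loadings, index=self.var_names, columns=cols)


def _standardize(space: PCSpace, X: np.ndarray) -> np.ndarray:
    return (X - space.mean) / space.sd


def fit_pca(presence: pd.DataFrame, var_names: list[str], q: int = 4) -> PCSpace:
    """PCA on the correlation matrix of the presence rows.

    Requires at least P+1 rows and no zero-variance variable (which
    would make the correlation undefined); the error names the offending
    variable.  Eigenvector signs follow a deterministic convention: the
    entry of largest absolute loading on each axis is positive.
    """
    X = presence[var_names].to_numpy(dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} presence rows, got {n}")
    if q < 1 or q > p:
        raise ValueError("q must lie in 1..P")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    zero = np.nonzero(sd < 1e-12)[0]
    if zero.size:
        raise ValueError(f"zero-variance variable: {var_names[zero[0]]!r}")

    Z = (X - mean) / sd
    corr = Z.T @ Z / n
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: the largest-|loading| entry of each axis positive
    flip = eigvec[np.argmax(np.abs(eigvec), axis=0), np.arange(p)] < 0
    eigvec[:, flip] *= -1.0

    contributions = 100.0 * eigvec**2
    cos2 = eigvec**2 * eigval[None, :]
    space = PCSpace(
        var_names=list(var_names),
        mean=mean,
        sd=sd,
        loadings=eigvec,
        eigenvalues=eigval,
        explained_pct=100.0 * eigval / p,
        scores=np.empty((0, q)),
        contributions=contributions,
        cos2=cos2,
        q=q,
    )
    space.scores = _standardize(space, X) @ eigvec[:, :q]
    return space


def project(space: PCSpace, rows: pd.DataFrame) -> np.ndarray:
    """Project rows into the presence PC space (first ``q`` axes).

    Standardization uses the *presence* means and s.d., so projecting
    the presence rows themselves reproduces their stored scores.
    """
    missing = [v for v in space.var_names if v not in rows.columns]
    if missing:
        raise ValueError(f"rows are missing variables: {missing}")
    X = rows[space.var_names].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("rows contain missing values")
    return _standardize(space, X) @ space.loadings[:, : space.q]
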