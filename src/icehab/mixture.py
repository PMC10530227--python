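"""Gaussian mixtures with the VEI covariance structure, fit by EM.

VEI denotes diagonal component covariances Sigma_k = lambda_k * B that
share one diagonal shape matrix B with det(B) = 1 while each component
keeps its own volume lambda_k > 0 ("Varying volume, Equal shape,
Identity orientation").  The mixture density is

    p(x) = sum_k pi_k * phi(x; mu_k, lambda_k B)

and the free-parameter count is K*d means + (K-1) mixing weights +
K volumes + (d-1) shape parameters under the unit-determinant
constraint.

Model selection runs EM over a range of K and picks the fit minimising
BIC = -2*loglik + df*ln(n) (reported on this positive scale; the signed
mclust-style 2*loglik - df*ln(n) is written alongside).  ICL subtracts
twice the posterior entropy from the signed BIC, penalising fuzzy
partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "VEIMixtureModel",
    "CellScores",
    "count_df",
    "bic_value",
    "fit_vei",
    "information_criteria",
    "select_model",
    "assign",
]

VOLUME_FLOOR = 1e-12


def count_df(K: int, d: int) -> int:
    """Free parameters of a K-component, d-dimensional VEI mixture.

    K*d component means, K-1 independent mixing weights, K volumes and
    d-1 shape entries (the d-th is fixed by det(B) = 1).
    """
    if K < 1 or d < 1:
        raise ValueError("K and d must be >= 1")
    return K * d + (K - 1) + K + (d - 1)


def bic_value(loglik: float, df: int, n: int) -> float:
    """BIC on the positive penalised-deviance scale: -2*loglik + df*ln(n)."""
    return -2.0 * loglik + df * np.log(n)


@dataclass
class VEIMixtureModel:
    """A fitted VEI Gaussian mixture."""

    weights: np.ndarray  # (K,) pi_k, sums to 1
    means: np.ndarray  # (K, d)
    volumes: np.ndarray  # (K,) lambda_k > 0
    shape: np.ndarray  # (d,) diagonal of B, det(B) = 1
    loglik: float = np.nan
    df: int = 0
    bic: float = np.nan  # positive scale, -2 loglik + df ln n
    bic_signed: float = np.nan  # mclust scale, 2 loglik - df ln n
    icl: float = np.nan  # signed scale, <= bic_signed
    n: int = 0
    n_iter: int = 0
    converged: bool = False
    seed: int | None = None

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def covariances(self) -> np.ndarray:
        """(K, d) diagonal covariances lambda_k * B."""
        return self.volumes[:, None] * self.shape[None, :]

    def component_log_density(self, X: np.ndarray) -> np.ndarray:
        """(n, K) matrix of log pi_k + log phi_k(x)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.d:
            raise ValueError(f"points have dimension {X.shape[1]}, model has {self.d}")
        var = self.covariances()  # (K, d)
        diff = X[:, None, :] - self.means[None, :, :]
        maha = np.sum(diff**2 / var[None, :, :], axis=2)
        logdet = np.sum(np.log(var), axis=1)
        lognorm = -0.5 * (self.d * np.log(2.0 * np.pi) + logdet)
        return np.log(self.weights)[None, :] + lognorm[None, :] - 0.5 * maha

    def log_density(self, X: np.ndarray) -> np.ndarray:
        return logsumexp(self.component_log_density(X), axis=1)

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        lp = self.component_log_density(X)
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.K, size=n, p=self.weights)
        sd = np.sqrt(self.covariances())
        return self.means[comp] + sd[comp] * rng.standard_normal((n, self.d))

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "d": self.d,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "volumes": self.volumes.tolist(),
            "shape": self.shape.tolist(),
            "loglik": float(self.loglik),
            "df": int(self.df),
            "bic": float(self.bic),
            "bic_signed": float(self.bic_signed),
            "icl": float(self.icl),
            "n": int(self.n),
            "seed": self.seed,
            "conventions": {
                "bic": "-2*loglik + df*ln(n) (positive scale)",
                "bic_signed": "2*loglik - df*ln(n) (mclust scale)",
                "icl": "bic_signed - 2*posterior_entropy (signed scale)",
            },
        }


class _ComponentCollapse(RuntimeError):
    pass


def _m_step_vei(
    X: np.ndarray, resp: np.ndarray, shape0: np.ndarray, inner_tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Constrained M-step: standard pi/mu updates, then the (lambda, B)
    fixed-point iteration under det(B) = 1."""
    n, d = X.shape
    nk = resp.sum(axis=0)
    if np.any(nk < max(d, 1.0)):
        raise _ComponentCollapse("component with too few effective members")
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    # per-component diagonal weighted scatter W_k
    W = np.stack(
        [resp[:, k] @ (X - means[k]) ** 2 for k in range(resp.shape[1])]
    )  # (K, d)

    B = shape0.copy()
    volumes = np.sum(W / B[None, :], axis=1) / (d * nk)
    if d == 1:
        return weights, means, np.maximum(volumes, VOLUME_FLOOR), np.ones(1)
    for _ in range(200):
        B_new = np.sum(W / volumes[:, None], axis=0)
        B_new = B_new / np.exp(np.mean(np.log(B_new)))  # det(B) = 1
        vol_new = np.sum(W / B_new[None, :], axis=1) / (d * nk)
        if np.any(vol_new < VOLUME_FLOOR):
            raise _ComponentCollapse("volume collapsed below floor")
        delta = max(
            np.max(np.abs(B_new - B) / np.maximum(B, 1e-300)),
            np.max(np.abs(vol_new - volumes) / np.maximum(volumes, 1e-300)),
        )
        B, volumes = B_new, vol_new
        if delta < inner_tol:
            break
    return weights, means, volumes, B


def _em_single_start(
    X: np.ndarray,
    labels: np.ndarray,
    K: int,
    max_iter: int,
    tol: float,
) -> VEIMixtureModel:
    n, d = X.shape
    resp = np.zeros((n, K))
    resp[np.arange(n), labels] = 1.0

    shape = np.ones(d)
    model = None
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        weights, means, volumes, shape = _m_step_vei(X, resp, shape)
        model = VEIMixtureModel(weights=weights, means=means, volumes=volumes, shape=shape)
        lp = model.component_log_density(X)
        ll_n = logsumexp(lp, axis=1)
        ll = float(ll_n.sum())
        if ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
            raise RuntimeError("EM log-likelihood decreased")  # pragma: no cover
        resp = np.exp(lp - ll_n[:, None])
        if abs(ll - prev_ll) < tol * max(1.0, abs(prev_ll)):
            model.converged = True
            model.loglik = ll
            model.n_iter = it
            return model
        prev_ll = ll
    model.loglik = prev_ll
    model.n_iter = max_iter
    return model


def fit_vei(
    X: np.ndarray,
    K: int,
    n_starts: int = 10,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> VEIMixtureModel:
    """Fit a K-component VEI mixture by multi-start EM.

    Each start is seeded with hard k-means labels; the best converged
    log-likelihood is kept.  Starts whose components collapse (effective
    size below d, or volume below 1e-12) are discarded; if every start
    collapses an error is raised.  Requires n > df so the model is
    identifiable.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    df = count_df(K, d)
    if n <= df:
        raise ValueError(f"n={n} must exceed the {df} free parameters of K={K}, d={d}")

    rng = np.random.default_rng(seed)
    best: VEIMixtureModel | None = None
    failures: list[str] = []
    for s in range(n_starts):
        if K == 1:
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=K,
                n_init=1,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(X)
            labels = km.labels_
        try:
            model = _em_single_start(X, labels, K, max_iter, tol)
        except _ComponentCollapse as err:
            failures.append(str(err))
            continue
        if best is None or model.loglik > best.loglik:
            best = model
        if K == 1:
            break  # deterministic: all starts identical
    if best is None:
        raise RuntimeError(f"all {n_starts} EM starts collapsed for K={K}: {failures[-1]}")
    best.df = df
    best.n = n
    best.seed = seed
    information_criteria(best, X)
    return best


def information_criteria(model: VEIMixtureModel, X: np.ndarray) -> tuple[float, float]:
    """Fill in and return (BIC, ICL) for a fitted model.

    BIC is reported on the positive scale -2*loglik + df*ln(n) and also
    stored signed (2*loglik - df*ln(n), the mclust convention).  ICL is
    the signed BIC minus twice the posterior entropy
    -sum_n sum_k gamma_nk ln gamma_nk, so ICL <= signed BIC with
    equality for a perfectly crisp partition.
    """
    n = model.n if model.n else np.atleast_2d(X).shape[0]
    model.n = n
    if not model.df:
        model.df = count_df(model.K, model.d)
    model.bic = bic_value(model.loglik, model.df, n)
    model.bic_signed = -model.bic
    resp = model.responsibilities(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(resp > 0, resp * np.log(resp), 0.0))
    model.icl = model.bic_signed - 2.0 * ent
    return model.bic, model.icl


def select_model(
    X: np.ndarray,
    k_range: range = range(2, 8),
    n_starts: int = 10,
    seed: int = 0,
    **kwargs,
) -> tuple[VEIMixtureModel, pd.DataFrame]:
    """Fit VEI mixtures over ``k_range`` and keep the minimum-BIC model.

    Returns the winning model and the full BIC/ICL table.  K values
    whose every EM start collapses are recorded as NaN rows; if no K
    fits at all an error is raised.
    """
    rows = []
    best: VEIMixtureModel | None = None
    ss = np.random.SeedSequence(seed)
    for K, child in zip(k_range, ss.spawn(len(k_range))):
        sub = int(child.generate_state(1)[0] % (2**31 - 1))
        try:
            model = fit_vei(X, K, n_starts=n_starts, seed=sub, **kwargs)
        except (RuntimeError, ValueError) as err:
            rows.append({"K": K, "loglik": np.nan, "df": count_df(K, np.atleast_2d(X).shape[1]),
                         "bic": np.nan, "icl": np.nan, "error": str(err)})
            continue
        rows.append({"K": K, "loglik": model.loglik, "df": model.df,
                     "bic": model.bic, "icl": model.icl, "error": ""})
        if best is None or model.bic < best.bic:
            best = model
    table = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("no mixture could be fitted for any K in the range")
    return best, table


@dataclass
class CellScores:
    """Soft and hard cluster assignments with accuracy/uncertainty.

    posterior rows sum to 1; ``z`` is the MAP label (ties to the lowest
    index); ``a`` = max posterior is the classification accuracy and
    ``u`` = 1 - a its uncertainty.  ``assigned`` holds the label where
    a >= tau and -1 otherwise; ``dual`` flags rows where two or more
    clusters each reach posterior >= tau (possible only for tau <= 0.5,
    e.g. colonies assignable to two clusters at a relaxed threshold).
    """

    posterior: np.ndarray  # (n, K)
    z: np.ndarray  # (n,) MAP labels, 0-based
    a: np.ndarray  # (n,) accuracy
    u: np.ndarray  # (n,) uncertainty = 1 - a
    tau: float
    assigned: np.ndarray  # (n,) label or -1
    dual: np.ndarray  # (n,) bool

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"cluster": self.z, "a": self.a, "u": self.u,
             "assigned": self.assigned, "dual": self.dual}
        )
        for k in range(self.posterior.shape[1]):
            df[f"post_{k}"] = self.posterior[:, k]
        return df


def assign(model: VEIMixtureModel, X: np.ndarray, tau: float = 0.8) -> CellScores:
    """Score points under a fitted mixture at certainty threshold ``tau``."""
    post = model.responsibilities(X)
    z = np.argmax(post, axis=1)
    a = post[np.arange(post.shape[0]), z]
    assigned = np.where(a >= tau, z, -1)
    dual = (post >= tau).sum(axis=1) >= 2
    return CellScores(posterior=post, z=z, a=a, u=1.0 - a, tau=tau, assigned=assigned, dual=dual)
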