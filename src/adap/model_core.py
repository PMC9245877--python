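"""Logistic-model kernel: loss, gradient, Hessian, deviance, prediction.

Every quantity exchanged between sites in the distributed protocol is a
functional of the per-site average negative log-likelihood

    L_k(beta) = (1/n_k) * sum_i [ -y_i x_i' beta + log(1 + exp(x_i' beta)) ]

so this module is the single source of truth for that kernel.  The loss is
per-observation averaged; ``deviance`` is the *total* negative log-likelihood
(n_k times the loss), which is the scale used for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.special import expit


class Role(str, Enum):
    """What a coefficient vector represents in the protocol."""

    truth = "truth"
    initial = "initial"
    local = "local"
    average = "average"
    pooled = "pooled"
    adap1 = "adap1"
    adap2 = "adap2"


@dataclass
class Coefficients:
    """A length-p coefficient vector (intercept first) plus its role."""

    beta: np.ndarray
    role: Role | str = Role.initial

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if isinstance(self.role, str):
            self.role = Role(self.role)

    @property
    def p(self) -> int:
        return self.beta.shape[0]


def as_beta(beta) -> np.ndarray:
    """Accept a Coefficients or any array-like; return a 1-d float array."""
    if isinstance(beta, Coefficients):
        return beta.beta
    return np.asarray(beta, dtype=float).ravel()


@dataclass
class SiteDataset:
    """One site's individual-level data.

    X is n_k x p with the first column identically 1 (the intercept);
    y is a {0,1} outcome vector of length n_k.
    """

    X: np.ndarray
    y: np.ndarray
    site_id: str = "site"

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-d, got shape {self.X.shape}")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            bad = np.unique(self.y[~np.isin(self.y, (0.0, 1.0))])
            raise ValueError(f"y must contain only 0/1; found values {bad}")
        if self.X.shape[0] > 0 and not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be identically 1 (intercept)")

    @property
    def n_k(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def has_both_classes(self) -> bool:
        return bool(self.y.min() == 0.0 and self.y.max() == 1.0)

    def subset(self, idx: np.ndarray, site_id: str | None = None) -> "SiteDataset":
        return SiteDataset(self.X[idx], self.y[idx], site_id or self.site_id)


def _check_dims(ds: SiteDataset, beta: np.ndarray) -> None:
    if ds.p != beta.shape[0]:
        raise ValueError(
            f"dimension mismatch: X is {ds.X.shape} but beta has length {beta.shape[0]}"
        )


def log1pexp(z: np.ndarray) -> np.ndarray:
    """log(1 + exp(z)), overflow-safe: z + log1p(exp(-z)) for z > 0."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z > 0
    out[pos] = z[pos] + np.log1p(np.exp(-z[pos]))
    out[~pos] = np.log1p(np.exp(z[~pos]))
    return out


def logistic_loss(ds: SiteDataset, beta) -> float:
    """Average negative log-likelihood L_k(beta) over the site's rows."""
    b = as_beta(beta)
    _check_dims(ds, b)
    eta = ds.X @ b
    return float(np.sum(-ds.y * eta + log1pexp(eta)) / ds.n_k)


def logistic_gradient(ds: SiteDataset, beta) -> np.ndarray:
    """(1/n_k) X' (expit(X beta) - y)."""
    b = as_beta(beta)
    _check_dims(ds, b)
    resid = expit(ds.X @ b) - ds.y
    return ds.X.T @ resid / ds.n_k


def logistic_hessian(ds: SiteDataset, beta) -> np.ndarray:
    """(1/n_k) X' W X with W = diag(mu (1 - mu)); positive semidefinite."""
    b = as_beta(beta)
    _check_dims(ds, b)
    mu = expit(ds.X @ b)
    w = mu * (1.0 - mu)
    H = (ds.X * w[:, None]).T @ ds.X / ds.n_k
    return 0.5 * (H + H.T)


def deviance(ds: SiteDataset, beta) -> float:
    """Total negative log-likelihood: n_k * logistic_loss."""
    return ds.n_k * logistic_loss(ds, beta)


def predict_prob(X: np.ndarray, beta) -> np.ndarray:
    """Fitted event probabilities expit(X beta), rowwise."""
    b = as_beta(beta)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != b.shape[0]:
        raise ValueError(
            f"dimension mismatch: X is {X.shape} but beta has length {b.shape[0]}"
        )
    return expit(X @ b)
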