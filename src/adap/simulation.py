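"""Simulation engine: multi-site generative settings, metrics, comparisons.

Five study designs are emulated, all sharing the same backbone -- covariates
drawn from a (p-1)-variate normal with exchangeable correlation, an all-ones
intercept column, and Bernoulli outcomes from a logistic model with a sparse
true coefficient vector:

1. fixed lead size n1=1000, K sites with n_k = 1000 * 10^{u_k}, u_k ~ U(-1,1),
   rho = 0.1, beta* = (-2.5, 0.5 x 10, 0 x 189), p = 200.
2. as 1 but heterogeneous covariates: per-site mean shift mu_k1 ~ U(-1,1) on
   the first covariate (the lead site gets the smallest shift) and per-site
   rho_k ~ U(0.1, 0.5).
3. total N = 10,000 over K = 11 sites; the lead holds n1 and the rest is
   split evenly; rho = 0.5; beta* = (-2, 1.5, 1, 1, 1, 1, 0 x 194).
4. K = 10 equal sites of size n; rho = 0.5; beta* as setting 1.
5. variable-selection design: K = 10 sites of 1000, rho = 0.5, intercept -2,
   ten covariates share a magnitude in {0.1, ..., 0.5}, the rest are zero.

Estimation error is the mean over replicates of ||beta_hat - beta*||_2; the
true/false positive rates are exact integer-count ratios over replicates of
nonzero estimates at truly nonzero / truly zero positions (intercept
excluded).  Paired one-sided t-tests compare per-replicate errors between
methods on identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .estimators import EstimatorResult, MultiSiteStudy, fit_all
from .model_core import Coefficients, Role, SiteDataset, as_beta

__all__ = [
    "SimulationSetting", "MetricsRow", "generate_study", "estimation_error",
    "selection_rates", "paired_one_sided_t", "run_replicates",
    "run_table_experiment",
]

DEFAULT_METHODS = ("local", "average", "pooled", "adap1", "adap2")


@dataclass
class SimulationSetting:
    """Full generative specification of one simulation design."""

    setting_id: int
    K: int
    p: int = 200
    n1: int = 1000
    site_size_rule: str = "lognormal"  # lognormal | fixed | split
    n: int = 1000          # per-site size under the "fixed" rule
    N_total: int = 10000   # total size under the "split" rule
    rho: float = 0.1
    rho_uniform: tuple | None = None   # per-site rho_k ~ U(lo, hi)
    mu_hetero: bool = False            # per-site mean shift on covariate 1
    beta_star: np.ndarray = None
    magnitude: float | None = None     # setting-5 signal size
    n_replicates: int = 200
    n_signals: int = 10

    def __post_init__(self) -> None:
        if self.beta_star is None:
            self.beta_star = self._default_beta()
        self.beta_star = np.asarray(self.beta_star, dtype=float)
        if self.beta_star.size != self.p:
            raise ValueError(
                f"beta_star has length {self.beta_star.size}, expected p={self.p}")
        if self.rho_uniform is None and not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")

    def _default_beta(self) -> np.ndarray:
        beta = np.zeros(self.p)
        if self.setting_id == 3:
            beta[0] = -2.0
            beta[1:6] = [1.5, 1.0, 1.0, 1.0, 1.0]
        elif self.setting_id == 5:
            beta[0] = -2.0
            beta[1:1 + self.n_signals] = self.magnitude or 0.5
        else:
            beta[0] = -2.5
            beta[1:1 + self.n_signals] = 0.5
        return beta

    @classmethod
    def preset(cls, setting_id: int, **overrides) -> "SimulationSetting":
        """The stated study conditions for settings 1-5 (overridable)."""
        base = {
            1: dict(K=5, rho=0.1, site_size_rule="lognormal"),
            2: dict(K=5, rho_uniform=(0.1, 0.5), mu_hetero=True,
                    site_size_rule="lognormal", rho=0.1),
            3: dict(K=11, rho=0.5, site_size_rule="split", n1=1000),
            4: dict(K=10, rho=0.5, site_size_rule="fixed", n=300),
            5: dict(K=10, rho=0.5, site_size_rule="fixed", n=1000,
                    magnitude=0.5, n_replicates=400),
        }[setting_id]
        base.update(overrides)
        return cls(setting_id=setting_id, **base)


def _exchangeable_normal(rng, n: int, d: int, rho: float, mu1: float = 0.0):
    """n draws of N_d(mu, Sigma), Sigma exchangeable with correlation rho.

    Uses the one-factor representation z = sqrt(rho) g 1 + sqrt(1-rho) eps,
    exact for this covariance, avoiding a d x d Cholesky.
    """
    g = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, d))
    z = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * eps
    if mu1 != 0.0:
        z[:, 0] += mu1
    return z


def _site_sizes(s: SimulationSetting, rng) -> list[int]:
    if s.site_size_rule == "lognormal":
        # collaborating sizes n1 * 10^u span two orders of magnitude around
        # the lead size (n1 = 1000 in the full-scale designs)
        sizes = [s.n1]
        for _ in range(s.K - 1):
            u = rng.uniform(-1.0, 1.0)
            sizes.append(max(int(round(s.n1 * 10.0 ** u)), 20))
        return sizes
    if s.site_size_rule == "fixed":
        return [s.n] * s.K
    if s.site_size_rule == "split":
        rest = s.N_total - s.n1
        if rest < 0:
            raise ValueError("lead size exceeds total N")
        m = s.K - 1
        sizes = [s.n1] + [rest // m] * m
        for i in range(rest % m):  # spread any remainder one-by-one
            sizes[1 + i] += 1
        return sizes
    raise ValueError(f"unknown site_size_rule {s.site_size_rule!r}")


def generate_study(s: SimulationSetting, replicate_seed) -> MultiSiteStudy:
    """Draw one multi-site study under the setting's covariate/outcome law."""
    rng = np.random.default_rng(replicate_seed)
    sizes = _site_sizes(s, rng)
    if s.rho_uniform is not None:
        rhos = rng.uniform(*s.rho_uniform, size=s.K)
    else:
        rhos = np.full(s.K, s.rho)
    mus = np.zeros(s.K)
    if s.mu_hetero:
        mus = rng.uniform(-1.0, 1.0, size=s.K)
        # the lead site's patients sit at the low end of the shifted covariate
        imin = int(np.argmin(mus))
        mus[0], mus[imin] = mus[imin], mus[0]
    sites = []
    for k in range(s.K):
        z = _exchangeable_normal(rng, sizes[k], s.p - 1, rhos[k], mus[k])
        X = np.hstack([np.ones((sizes[k], 1)), z])
        y = (rng.uniform(size=sizes[k]) < expit(X @ s.beta_star)).astype(float)
        sites.append(SiteDataset(X, y, f"site_{k + 1}"))
    return MultiSiteStudy(sites, lead_index=0)


@dataclass
class MetricsRow:
    method: str
    estimation_error: float
    n_replicates: int
    tpr: float | None = None
    fpr: float | None = None
    errors: np.ndarray | None = None       # per-replicate ||beta_hat - beta*||
    tpr_reps: np.ndarray | None = None     # per-replicate TPR
    fpr_reps: np.ndarray | None = None


def _betas(results) -> np.ndarray:
    rows = []
    for r in results:
        rows.append(r.beta_hat.beta if isinstance(r, EstimatorResult) else as_beta(r))
    return np.array(rows)


def estimation_error(results, beta_star) -> MetricsRow:
    """Mean over replicates of the Euclidean distance to the truth."""
    B = _betas(results)
    bs = as_beta(beta_star)
    errs = np.linalg.norm(B - bs[None, :], axis=1)
    method = results[0].method if isinstance(results[0], EstimatorResult) else "?"
    return MetricsRow(method, float(errs.mean()), len(results), errors=errs)


def selection_rates(results, beta_star) -> tuple[float, float]:
    """(TPR, FPR) as exact count ratios; the intercept is excluded."""
    B = _betas(results)[:, 1:]
    bs = as_beta(beta_star)[1:]
    pos = bs != 0.0
    neg = ~pos
    nz = B != 0.0
    tp = int(nz[:, pos].sum())
    fp = int(nz[:, neg].sum())
    R = B.shape[0]
    tpr = tp / (R * int(pos.sum())) if pos.any() else float("nan")
    fpr = fp / (R * int(neg.sum())) if neg.any() else float("nan")
    return tpr, fpr


def paired_one_sided_t(metric_a, metric_b) -> tuple[float, float]:
    """Paired t-test of H1: mean(a) < mean(b) on per-replicate metrics.

    Identical vectors give t = 0 and p = 1 (no evidence of improvement).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired vectors of length >= 2")
    d = a - b
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        return (-np.inf, 0.0) if d.mean() < 0 else (np.inf, 1.0)
    t = d.mean() / (sd / np.sqrt(n))
    p = float(stats.t.cdf(t, df=n - 1))
    return float(t), p


def _replicate_seed(master: int, *tags: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(t) for t in tags))


def run_replicates(setting: SimulationSetting, n_replicates: int,
                   methods=DEFAULT_METHODS, seed: int = 0,
                   **fit_kwargs) -> dict[str, list[EstimatorResult]]:
    """Fit all requested methods on n_replicates independent draws.

    Within a replicate every method sees the identical study, so
    per-replicate metrics are paired across methods.
    """
    out: dict[str, list[EstimatorResult]] = {m: [] for m in methods}
    for r in range(n_replicates):
        study = generate_study(setting, _replicate_seed(seed, setting.setting_id, r))
        res = fit_all(study, methods, seed=seed + 7919 * r + 1, **fit_kwargs)
        for m in methods:
            out[m].append(res[m])
    return out


def summarize_replicates(results: dict[str, list[EstimatorResult]],
                         beta_star, with_selection: bool = False
                         ) -> dict[str, MetricsRow]:
    rows = {}
    for m, res in results.items():
        row = estimation_error(res, beta_star)
        row.method = m
        if with_selection:
            bs = as_beta(beta_star)[1:]
            B = _betas(res)[:, 1:]
            pos, neg = bs != 0.0, bs == 0.0
            row.tpr, row.fpr = selection_rates(res, beta_star)
            row.tpr_reps = (B[:, pos] != 0).mean(axis=1)
            row.fpr_reps = (B[:, neg] != 0).mean(axis=1)
        rows[m] = row
    return rows


def run_table_experiment(magnitudes=(0.1, 0.2, 0.3, 0.4, 0.5),
                         n_replicates: int = 400, methods=DEFAULT_METHODS,
                         seed: int = 0, setting_overrides: dict | None = None,
                         **fit_kwargs) -> pd.DataFrame:
    """The variable-selection grid (setting 5): TPR/FPR per magnitude/method.

    Returns a tidy table with Monte-Carlo standard errors computed from the
    replicate-level rates, floored at the binomial precision of the run.
    """
    rows = []
    for mi, mag in enumerate(magnitudes):
        setting = SimulationSetting.preset(5, magnitude=float(mag),
                                           n_replicates=n_replicates,
                                           **(setting_overrides or {}))
        results = run_replicates(setting, n_replicates, methods,
                                 seed=seed + 1000 * mi, **fit_kwargs)
        summary = summarize_replicates(results, setting.beta_star,
                                       with_selection=True)
        for m in methods:
            row = summary[m]
            rows.append({
                "magnitude": mag, "method": m,
                "tpr": row.tpr, "fpr": row.fpr,
                "tpr_se": mc_se(row.tpr_reps),
                "fpr_se": mc_se(row.fpr_reps),
                "estimation_error": row.estimation_error,
                "n_replicates": n_replicates,
            })
    return pd.DataFrame(rows)


def mc_se(rate_reps: np.ndarray, floor: float = 0.01) -> float:
    """Monte-Carlo standard error of a replicate-level rate, floored.

    The floor guards against a degenerate zero SE when every replicate
    attains the same rate (e.g. TPR pinned at 1.0).
    """
    r = np.asarray(rate_reps, dtype=float)
    return float(max(r.std(ddof=1) / np.sqrt(r.size), floor))
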