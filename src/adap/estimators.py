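"""The five estimators: local, average, pooled, ADAP1, ADAP2.

All five share the same tuning machinery (regularization path + 5-fold CV
minimizing held-out deviance), so differences between them reflect the
information each is allowed to use, not solver details:

* local  -- lead site's rows only; no communication.
* average -- each site fits its own CV-tuned model; the lead receives the
  K-1 coefficient vectors and returns the sample-size-weighted mean.
* pooled -- all rows concatenated; the gold standard, but requires sharing
  individual-level data and is flagged as not privacy-preserving.
* ADAP1 / ADAP2 -- the one-shot protocol: the lead fits an initial estimate,
  broadcasts it, collects first-order (ADAP1) or first- plus second-order
  (ADAP2) gradient packets, builds the surrogate objective and tunes it with
  the modified CV.  Collaborating sites' rows are touched only inside
  ``make_packet``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gradient_exchange import CommLedger, build_surrogate, comm_cost, make_packet
from .model_core import Coefficients, Role, SiteDataset
from .path_solver import PenaltySpec, cv_fit, modified_cv

__all__ = ["MultiSiteStudy", "EstimatorResult", "fit_local", "fit_average",
           "fit_pooled", "fit_adap", "fit_all"]

logger = logging.getLogger(__name__)


@dataclass
class MultiSiteStudy:
    """K sites' datasets plus the designated lead site (0-based index)."""

    sites: list[SiteDataset]
    lead_index: int = 0

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("study needs at least one site")
        ps = {ds.p for ds in self.sites}
        if len(ps) != 1:
            raise ValueError(f"all sites must share p; got {sorted(ps)}")
        if not 0 <= self.lead_index < len(self.sites):
            raise ValueError(f"lead_index {self.lead_index} out of range")
        sizes = [ds.n_k for ds in self.sites]
        if len(self.sites) > 1 and sizes[self.lead_index] == min(sizes) and \
                sizes.count(min(sizes)) == 1:
            logger.warning(
                "lead site %s is the smallest site (n=%d); a larger lead "
                "site is recommended", self.lead.site_id, self.lead.n_k)

    @property
    def K(self) -> int:
        return len(self.sites)

    @property
    def p(self) -> int:
        return self.sites[0].p

    @property
    def N(self) -> int:
        return sum(ds.n_k for ds in self.sites)

    @property
    def lead(self) -> SiteDataset:
        return self.sites[self.lead_index]

    @property
    def collaborators(self) -> list[SiteDataset]:
        return [ds for i, ds in enumerate(self.sites) if i != self.lead_index]

    def pooled(self) -> SiteDataset:
        # canonical site order so the pooled fit (and its CV folds) does not
        # depend on how the study listed its sites
        order = sorted(range(self.K), key=lambda i: str(self.sites[i].site_id))
        X = np.vstack([self.sites[i].X for i in order])
        y = np.concatenate([self.sites[i].y for i in order])
        return SiteDataset(X, y, "pooled")


@dataclass
class EstimatorResult:
    method: str
    beta_hat: Coefficients
    lambda_selected: float | list[float] | None
    comm: CommLedger
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "beta_hat": self.beta_hat.beta.tolist(),
            "lambda_selected": self.lambda_selected,
            "comm_total": self.comm.total,
            "comm_broadcast": self.comm.broadcast_scalars,
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if np.isscalar(v) or isinstance(v, (str, bool))},
        }


def _cv_kwargs(kwargs: dict) -> dict:
    allowed = {"folds", "n_lambda", "lambda_min_ratio", "tol", "max_iter",
               "cv_correction", "patience"}
    return {k: v for k, v in kwargs.items() if k in allowed}


def fit_local(study: MultiSiteStudy, pen: PenaltySpec | None = None,
              seed: int = 0, **kwargs) -> EstimatorResult:
    """CV-tuned penalized fit on the lead site only."""
    path = cv_fit(study.lead, pen, seed=seed, **_cv_kwargs(kwargs))
    beta = Coefficients(path.beta_selected.beta, Role.local)
    return EstimatorResult("local", beta, path.lambda_selected, CommLedger(),
                           {"cv_deviance": path.cv_deviance})


def fit_average(study: MultiSiteStudy, pen: PenaltySpec | None = None,
                seed: int = 0, **kwargs) -> EstimatorResult:
    """Sample-size-weighted average of per-site CV-tuned fits.

    A site too small to support the full fold count is tuned with fewer
    folds; a site with fewer than two observations in a class cannot be
    CV-tuned at all and contributes its null (intercept-only) fit, with a
    warning.  Its n_k/N weight keeps the impact proportionate.
    """
    from scipy.special import logit

    betas, lams = [], []
    for k, ds in enumerate(study.sites):
        kw = _cv_kwargs(kwargs)
        folds = kw.pop("folds", 5)
        min_class = int(min((ds.y == 0).sum(), (ds.y == 1).sum()))
        if min_class < 2:
            logger.warning(
                "site %s has %d observations in its rarest class; using its "
                "null model in the average", ds.site_id, min_class)
            prev = min(max(ds.y.mean(), 1.0 / (ds.n_k + 1)),
                       1.0 - 1.0 / (ds.n_k + 1))
            beta0 = np.zeros(ds.p)
            beta0[0] = float(logit(prev))
            betas.append(beta0)
            lams.append(None)
            continue
        if min_class < folds:
            logger.warning("site %s: reducing CV folds to %d",
                           ds.site_id, min_class)
            folds = min_class
        path = cv_fit(ds, pen, folds=folds, seed=seed + k, **kw)
        betas.append(path.beta_selected.beta)
        lams.append(path.lambda_selected)
    wts = np.array([ds.n_k for ds in study.sites], dtype=float)
    wts /= wts.sum()
    beta = Coefficients(np.einsum("k,kp->p", wts, np.array(betas)), Role.average)
    ledger = CommLedger()
    ledger.scalars_sent_per_site = {
        ds.site_id: study.p for i, ds in enumerate(study.sites)
        if i != study.lead_index}
    return EstimatorResult("average", beta, lams, ledger,
                           {"site_betas": np.array(betas)})


def fit_pooled(study: MultiSiteStudy, pen: PenaltySpec | None = None,
               seed: int = 0, **kwargs) -> EstimatorResult:
    """CV-tuned fit on all rows concatenated (gold standard, shares data)."""
    pooled = study.pooled()
    path = cv_fit(pooled, pen, seed=seed, **_cv_kwargs(kwargs))
    beta = Coefficients(path.beta_selected.beta, Role.pooled)
    ledger = CommLedger()
    ledger.scalars_sent_per_site = {
        ds.site_id: ds.n_k * study.p for i, ds in enumerate(study.sites)
        if i != study.lead_index}
    return EstimatorResult("pooled", beta, path.lambda_selected, ledger,
                           {"privacy_preserving": False,
                            "cv_deviance": path.cv_deviance})


def fit_adap(study: MultiSiteStudy, order: int = 1, init: str = "local",
             pen: PenaltySpec | None = None, seed: int = 0,
             beta_bar: Coefficients | None = None, **kwargs) -> EstimatorResult:
    """The one-shot protocol end to end (order=1: ADAP1, order=2: ADAP2)."""
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    if init not in ("local", "average"):
        raise ValueError(f"init must be 'local' or 'average', got {init!r}")
    extra_broadcast = 0
    if beta_bar is None:
        if init == "local":
            beta_bar = fit_local(study, pen, seed=seed, **kwargs).beta_hat
        else:
            beta_bar = fit_average(study, pen, seed=seed, **kwargs).beta_hat
            extra_broadcast = study.p * (study.K - 1)  # per-site estimates round

    packets = [make_packet(ds, beta_bar, order) for ds in study.collaborators]
    path = modified_cv(study.lead, packets, beta_bar, order, pen,
                       seed=seed, **_cv_kwargs(kwargs))
    role = Role.adap1 if order == 1 else Role.adap2
    beta = Coefficients(path.beta_selected.beta, role)
    ledger = comm_cost(study.K, study.p, order)
    ledger.scalars_sent_per_site = {
        ds.site_id: v for ds, v in zip(study.collaborators,
                                       ledger.scalars_sent_per_site.values())}
    ledger.broadcast_scalars += extra_broadcast
    return EstimatorResult(f"adap{order}", beta, path.lambda_selected, ledger,
                           {"cv_deviance": path.cv_deviance,
                            "beta_bar": beta_bar.beta, "init": init})


_FITTERS = {
    "local": fit_local,
    "average": fit_average,
    "pooled": fit_pooled,
    "adap1": lambda study, **kw: fit_adap(study, order=1, **kw),
    "adap2": lambda study, **kw: fit_adap(study, order=2, **kw),
}


def fit_all(study: MultiSiteStudy, methods=("local", "average", "pooled",
                                            "adap1", "adap2"),
            pen: PenaltySpec | None = None, seed: int = 0,
            **kwargs) -> dict[str, EstimatorResult]:
    """Fit the requested estimators on one study, sharing the local init.

    When both ADAP orders are requested the CV-tuned local fit is reused as
    the broadcast anchor for both, exactly as a real lead site would.
    """
    out: dict[str, EstimatorResult] = {}
    need_local_anchor = any(m in methods for m in ("adap1", "adap2"))
    local_res = None
    if "local" in methods or need_local_anchor:
        local_res = fit_local(study, pen, seed=seed, **kwargs)
    if "local" in methods:
        out["local"] = local_res
    for m in methods:
        if m == "local":
            continue
        if m in ("adap1", "adap2"):
            out[m] = fit_adap(study, order=int(m[-1]), pen=pen, seed=seed,
                              beta_bar=local_res.beta_hat, **kwargs)
        else:
            out[m] = _FITTERS[m](study, pen=pen, seed=seed, **kwargs)
    return out
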