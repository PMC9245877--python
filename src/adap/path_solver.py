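"""Penalized optimization of surrogate-shaped objectives.

Solves  min_beta  S(beta) + P_lambda(beta)  where the smooth part is

    S(beta) = L1(beta) + c' beta + (1/2)(beta - beta_bar)' D (beta - beta_bar)

(c = 0, D = 0 recovers a plain local objective) and the penalty is

    P_lambda(beta) = lambda * (alpha ||beta||_1 + (1 - alpha) ||beta||_2^2)

with the intercept unpenalized by default.  The algorithm is the classic
nested loop: an outer IRLS quadratic approximation of the logistic term at
the current iterate -- the linear correction c and quadratic correction D
enter the subproblem exactly -- and an inner cyclic coordinate descent with
soft thresholding.  Work is restricted to an active set; after the IRLS
loop converges on that set, the exact smooth gradient is scanned for KKT
violations and the set is expanded until none remain, so returned solutions
satisfy the penalized stationarity conditions of the true objective.
Paths over a decreasing log-spaced lambda grid are warm-started, carrying
both coefficients and linear predictor between nodes.

Convergence is declared when the curvature-weighted squared coefficient
update max_j h_j (delta beta_j)^2 falls below ``tol`` (default 1e-7), for
both the coordinate cycles and the IRLS iterations -- the standard criterion
for coordinate-descent GLM paths.  Tighter tolerances trade time for
precision and are used by the equivalence tests.

Because D is a difference of positive-semidefinite matrices it can be
indefinite; the coordinate-wise curvature h_j = (IRLS curvature)_j + D_jj is
clipped below at 1e-4 times the mean IRLS curvature so every coordinate step
remains a descent step on the local model.

Model selection uses the modified K-fold cross-validation of the one-shot
protocol: only the *lead* site's rows are folded, the remote gradient
aggregates stay fixed, the correction terms are recomputed on the retained
folds, and the held-out deviance (total negative log-likelihood) is averaged
over folds; ties are broken toward the larger lambda.  The descent down the
grid stops once the mean held-out deviance has not improved for ``patience``
consecutive nodes (the curve is past its minimum), which skips the saturated
tail of the path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import expit

from .gradient_exchange import (
    GradientPacket,
    SurrogateObjective,
    build_surrogate,
    surrogate_gradient,
)
from .model_core import Coefficients, Role, SiteDataset, as_beta, deviance

__all__ = [
    "PenaltySpec",
    "RegularizationPath",
    "ConvergenceError",
    "DivergenceError",
    "local_objective",
    "lambda_grid",
    "fit_penalized",
    "fit_path",
    "modified_cv",
    "cv_fit",
    "stratified_folds",
]

_EMPTY = np.zeros((1, 1))
_WEIGHT_FLOOR = 1e-5


class ConvergenceError(RuntimeError):
    """Raised when IRLS fails to converge; carries the last iterate."""

    def __init__(self, msg: str, beta: np.ndarray, kkt_residual: float):
        super().__init__(msg)
        self.beta = beta
        self.kkt_residual = kkt_residual


class DivergenceError(ConvergenceError):
    """The penalized objective is unbounded below at this lambda."""


@dataclass
class PenaltySpec:
    """Lasso (alpha=1) or elastic-net penalty specification."""

    family: str = "lasso"
    alpha: float = 1.0
    penalize_intercept: bool = False
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.family == "lasso":
            self.alpha = 1.0
        elif self.family != "elastic_net":
            raise ValueError(f"unknown penalty family {self.family!r}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class RegularizationPath:
    lambdas: np.ndarray
    betas: np.ndarray  # n_fitted x p (may stop above the grid's tail)
    cv_deviance: np.ndarray | None = None
    cv_deviance_folds: np.ndarray | None = None  # n_fitted x folds
    lambda_selected: float | None = None
    beta_selected: Coefficients | None = None
    n_lambda: int = 0
    lambda_min_ratio: float = 0.0

    @property
    def df(self) -> np.ndarray:
        """Number of nonzero non-intercept coefficients per path node."""
        return (self.betas[:, 1:] != 0).sum(axis=1)

    def to_frame(self):
        """Tidy export: one row per lambda (lambda, df, deviance, coefs)."""
        import pandas as pd

        L = self.betas.shape[0]
        data = {"lambda": self.lambdas[:L], "df": self.df}
        if self.cv_deviance is not None:
            data["cv_deviance"] = self.cv_deviance[:L]
        if self.cv_deviance_folds is not None:
            for f in range(self.cv_deviance_folds.shape[1]):
                data[f"deviance_fold{f + 1}"] = self.cv_deviance_folds[:L, f]
        frame = pd.DataFrame(data)
        for j in range(self.betas.shape[1]):
            frame[f"beta{j}"] = self.betas[:, j]
        return frame


def local_objective(ds: SiteDataset) -> SurrogateObjective:
    """A site's own penalized-regression objective as a trivial surrogate."""
    p = ds.p
    return SurrogateObjective(ds, np.zeros(p), np.zeros(p), None, 1, ds.n_k, 1)


# ---------------------------------------------------------------------------
# inner coordinate descent (numba)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _node_kernel(Xf, X2f, yr, rows, c, D, bbar, use_D, beta, eta, active,
                 pen_mask, lam, alpha, tol, max_outer):
    """Full IRLS + active-set coordinate descent for a single lambda.

    Operates on the row subset ``rows`` of the shared design (Fortran order,
    so column traversal is contiguous).  ``beta``, ``eta`` (linear predictor
    on the subset) and ``active`` are updated in place, giving warm starts
    across path nodes for free.  Returns 0 on success, 1 if IRLS stalled,
    2 if the active set failed to stabilize.

    Within one IRLS iteration the quadratic model is solved by cyclic
    soft-thresholding over the active set, maintaining the working residual
    r = z - X beta and, for second-order surrogates, u = D (beta - bbar).
    After the IRLS loop converges the exact smooth gradient is scanned over
    the inactive coordinates; violators join the active set and the solve
    repeats, so the returned point satisfies the true KKT conditions.
    """
    n = rows.size
    p = beta.size
    thr = lam * alpha
    l2 = 2.0 * lam * (1.0 - alpha)
    mu = np.empty(n)
    w = np.empty(n)
    wr = np.empty(n)   # w * (working residual z - eta)
    z = np.empty(n)
    u = np.zeros(p)
    beta_prev = np.empty(p)
    for _round in range(50):
        # gather active columns contiguously so the hot loops vectorize
        nact = 0
        for j in range(p):
            if active[j]:
                nact += 1
        idx = np.empty(nact, np.int64)
        t = 0
        for j in range(p):
            if active[j]:
                idx[t] = j
                t += 1
        Xa = np.empty((nact, n))
        for t in range(nact):
            j = idx[t]
            for i in range(n):
                Xa[t, i] = Xf[rows[i], j]
        ha = np.empty(nact)
        converged = False
        for _outer in range(max_outer):
            for i in range(n):
                m = 1.0 / (1.0 + np.exp(-eta[i]))
                mu[i] = m
                ww = m * (1.0 - m)
                if ww < _WEIGHT_FLOOR:
                    ww = _WEIGHT_FLOOR
                w[i] = ww
                wr[i] = yr[i] - m
                z[i] = eta[i] + wr[i] / ww
            hsum = 0.0
            for t in range(nact):
                s = 0.0
                for i in range(n):
                    s += w[i] * Xa[t, i] * Xa[t, i]
                ha[t] = s / n
                hsum += ha[t]
            eps_curv = 1e-4 * hsum / max(nact, 1)
            if use_D:
                for q in range(p):
                    s = 0.0
                    for j in range(p):
                        s += D[q, j] * (beta[j] - bbar[j])
                    u[q] = s
            for j in range(p):
                beta_prev[j] = beta[j]
            # --- cyclic coordinate descent on the quadratic model ---
            for _cycle in range(10000):
                maxd2 = 0.0
                for t in range(nact):
                    j = idx[t]
                    hj = ha[t]
                    if use_D:
                        hj += D[j, j]
                    if hj < eps_curv:
                        hj = eps_curv
                    s = 0.0
                    for i in range(n):
                        s += Xa[t, i] * wr[i]
                    gj = -s / n + c[j]
                    if use_D:
                        gj += u[j]
                    bj = beta[j]
                    if pen_mask[j]:
                        num = hj * bj - gj
                        if num > thr:
                            bnew = (num - thr) / (hj + l2)
                        elif num < -thr:
                            bnew = (num + thr) / (hj + l2)
                        else:
                            bnew = 0.0
                    else:
                        bnew = bj - gj / hj
                    d = bnew - bj
                    if d != 0.0:
                        beta[j] = bnew
                        for i in range(n):
                            wr[i] -= w[i] * Xa[t, i] * d
                        if use_D:
                            for q in range(p):
                                u[q] += D[q, j] * d
                        d2 = hj * d * d
                        if d2 > maxd2:
                            maxd2 = d2
                # divergence guard: the surrogate's linear/indefinite
                # corrections can make the penalized objective unbounded
                # below at small lambda; detect runaway coefficients
                bmax = 0.0
                for t in range(nact):
                    ab = abs(beta[idx[t]])
                    if ab > bmax:
                        bmax = ab
                if not (maxd2 <= 1e10) or bmax > 1e6:
                    return 3
                if maxd2 < tol:
                    break
            for i in range(n):
                eta[i] = z[i] - wr[i] / w[i]
            d2o = 0.0
            for t in range(nact):
                dd = beta[idx[t]] - beta_prev[idx[t]]
                v = ha[t] * dd * dd
                if v > d2o:
                    d2o = v
            if d2o < tol:
                converged = True
                break
        if not converged:
            return 1
        # --- exact-gradient KKT scan over inactive coordinates ---
        contig = n == Xf.shape[0]  # full data: unit-stride columns
        for i in range(n):
            mu[i] = (1.0 / (1.0 + np.exp(-eta[i]))) - yr[i]
        anyviol = False
        for j in range(p):
            if pen_mask[j] and not active[j]:
                s = 0.0
                if contig:
                    for i in range(n):
                        s += mu[i] * Xf[i, j]
                else:
                    for i in range(n):
                        s += mu[i] * Xf[rows[i], j]
                g = s / n + c[j]
                if use_D:
                    g += u[j]
                if abs(g) > thr * (1.0 + 1e-9):
                    active[j] = True
                    anyviol = True
        if not anyviol:
            return 0
    return 2


class _Workspace:
    """Per-objective solver state shared across path nodes.

    Holds Fortran-ordered views of the full lead design plus a row-index
    subset, so cross-validation folds reuse the same arrays without copies.
    """

    def __init__(self, s: SurrogateObjective, Xf: np.ndarray | None = None,
                 X2f: np.ndarray | None = None,
                 rows: np.ndarray | None = None, full_X=None):
        self.s = s
        base_X = full_X if full_X is not None else s.lead.X
        self.Xf = np.asfortranarray(base_X) if Xf is None else Xf
        self.X2f = np.square(self.Xf) if X2f is None else X2f
        self.rows = (np.arange(s.lead.n_k, dtype=np.int64)
                     if rows is None else np.asarray(rows, dtype=np.int64))
        self.yr = np.ascontiguousarray(s.lead.y)
        self.use_D = s.order == 2 and s.D is not None
        self.D = np.ascontiguousarray(s.D) if self.use_D else _EMPTY
        self.c = np.ascontiguousarray(s.c)
        self.bbar = np.ascontiguousarray(s.beta_bar)
        p = self.Xf.shape[1]
        self.beta = np.zeros(p)      # warm state carried along a path
        self.eta = np.zeros(self.rows.size)

    def set_state(self, beta: np.ndarray) -> None:
        self.beta = np.asarray(beta, dtype=float).copy()
        self.eta = self.Xf[self.rows] @ self.beta


def _solve_node(ws: _Workspace, lam: float, alpha: float, pen_mask: np.ndarray,
                tol: float, max_outer: int) -> np.ndarray:
    """IRLS + active-set CD for one lambda, warm-started from ws state."""
    active = (ws.beta != 0.0) | ~pen_mask
    status = _node_kernel(ws.Xf, ws.X2f, ws.yr, ws.rows, ws.c, ws.D, ws.bbar,
                          ws.use_D, ws.beta, ws.eta, active, pen_mask,
                          lam, alpha, tol, max_outer)
    if status != 0:
        if status == 3:
            # runaway coefficients: the penalized surrogate is unbounded
            # below at this lambda (possible when the linear correction c is
            # large or D is indefinite); the workspace state is invalid now
            raise DivergenceError(
                f"penalized surrogate objective appears unbounded below at "
                f"lambda={lam:.4g} (diverging coefficients)",
                ws.beta, float("inf"))
        g = surrogate_gradient(ws.s, ws.beta)
        res = _kkt_residual(g, ws.beta, lam, alpha, pen_mask)
        what = ("IRLS did not converge in %d outer iterations" % max_outer
                if status == 1 else "active set failed to stabilize")
        raise ConvergenceError(
            f"{what} (lambda={lam:.4g}, KKT residual {res:.3g})", ws.beta, res)
    return ws.beta


def _kkt_residual(g: np.ndarray, beta: np.ndarray, lam: float, alpha: float,
                  pen_mask: np.ndarray) -> float:
    """Max violation of the penalized stationarity conditions."""
    l2 = 2.0 * lam * (1.0 - alpha)
    res = 0.0
    for j in range(beta.size):
        if not pen_mask[j]:
            res = max(res, abs(g[j]))
        elif beta[j] == 0.0:
            res = max(res, abs(g[j]) - lam * alpha)
        else:
            res = max(res, abs(g[j] + lam * alpha * np.sign(beta[j]) + l2 * beta[j]))
    return res


def _pen_mask(p: int, pen: PenaltySpec) -> np.ndarray:
    mask = np.ones(p, dtype=bool)
    if not pen.penalize_intercept:
        mask[0] = False
    return mask


def _null_solution(s: SurrogateObjective, pen: PenaltySpec, tol: float = 1e-10) -> np.ndarray:
    """Optimum of the smooth objective with all penalized coordinates at 0."""
    from .model_core import logistic_hessian

    p = s.lead.p
    mask = _pen_mask(p, pen)
    beta = np.zeros(p)
    if mask.all():
        return beta  # fully penalized: the null point is the origin
    free = np.flatnonzero(~mask)
    for _ in range(200):
        g = surrogate_gradient(s, beta)
        if np.max(np.abs(g[free])) < tol:
            break
        H = logistic_hessian(s.lead, beta)
        if s.order == 2 and s.D is not None:
            H = H + s.D
        Hf = H[np.ix_(free, free)] + 1e-10 * np.eye(free.size)
        step = np.clip(np.linalg.solve(Hf, g[free]), -2.0, 2.0)
        beta[free] -= step
    return beta


def lambda_grid(objective: SurrogateObjective, n_lambda: int = 100,
                lambda_min_ratio: float | None = None,
                pen: PenaltySpec | None = None) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max (all-null fit) down."""
    pen = pen or PenaltySpec()
    if n_lambda < 2:
        raise ValueError("n_lambda must be at least 2")
    mask = _pen_mask(objective.lead.p, pen)
    if not mask.any():
        raise ValueError("objective has no penalized coordinates")
    if lambda_min_ratio is None:
        n, p = objective.lead.X.shape
        lambda_min_ratio = 1e-3 if n > p else 1e-2
    beta0 = _null_solution(objective, pen)
    g = surrogate_gradient(objective, beta0)
    lam_max = float(np.max(np.abs(g[mask]))) / pen.alpha
    lam_max *= 1.0 + 1e-6  # keep the first node's solution exactly null
    if lam_max <= 0:
        raise ValueError("degenerate objective: zero gradient at the null fit")
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def fit_penalized(objective: SurrogateObjective, pen: PenaltySpec,
                  warm_start=None, tol: float = 1e-7,
                  max_iter: int = 100) -> Coefficients:
    """Solve the penalized surrogate problem at the fixed lambda in ``pen``."""
    if pen.lam is None:
        raise ValueError("PenaltySpec.lam must be set for fit_penalized")
    if not objective.lead.has_both_classes():
        raise ValueError("lead data must contain both outcome classes")
    p = objective.lead.p
    ws = _Workspace(objective)
    if warm_start is not None:
        start = as_beta(warm_start)
        if start.size != p:
            raise ValueError(f"warm start has length {start.size}, expected {p}")
        ws.set_state(start)
    mask = _pen_mask(p, pen)
    beta = _solve_node(ws, pen.lam, pen.alpha, mask, tol, max_iter)
    return Coefficients(beta.copy(), Role.initial)


def fit_path(objective: SurrogateObjective, pen: PenaltySpec | None = None,
             n_lambda: int = 100, lambda_min_ratio: float | None = None,
             tol: float = 1e-7, max_iter: int = 100,
             lambdas: np.ndarray | None = None) -> RegularizationPath:
    """Warm-started solution path along a decreasing lambda grid."""
    pen = pen or PenaltySpec()
    if not objective.lead.has_both_classes():
        raise ValueError("lead data must contain both outcome classes")
    if lambdas is None:
        lambdas = lambda_grid(objective, n_lambda, lambda_min_ratio, pen)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    p = objective.lead.p
    ws = _Workspace(objective)
    mask = _pen_mask(p, pen)
    betas = np.zeros((lambdas.size, p))
    for i, lam in enumerate(lambdas):
        betas[i] = _solve_node(ws, float(lam), pen.alpha, mask, tol, max_iter)
    return RegularizationPath(lambdas=lambdas, betas=betas, n_lambda=lambdas.size,
                              lambda_min_ratio=float(lambdas[-1] / lambdas[0]))


def stratified_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Outcome-stratified fold labels (0..folds-1), seeded and reproducible."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    assign = np.empty(y.size, dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def _remote_aggregates(packets: list[GradientPacket], p: int, order: int):
    n_rem = sum(pk.n_k for pk in packets)
    g_sum = np.zeros(p)
    H_sum = np.zeros((p, p)) if order == 2 else None
    for pk in packets:
        g_sum += pk.n_k * pk.grad1
        if order == 2:
            H_sum += pk.n_k * pk.grad2
    return n_rem, g_sum, H_sum


def modified_cv(lead: SiteDataset, packets: list[GradientPacket], beta_bar,
                order: int = 1, pen: PenaltySpec | None = None,
                folds: int = 5, seed: int = 0, n_lambda: int = 100,
                lambda_min_ratio: float | None = None, tol: float = 1e-7,
                max_iter: int = 100, cv_correction: str = "retained",
                patience: int = 15) -> RegularizationPath:
    """Modified K-fold CV over the lead site's rows, then a full-data refit.

    Each round leaves out one fold of lead data; the surrogate is rebuilt
    with L1 (and, in the default ``cv_correction='retained'`` mode, the
    correction-term gradients) computed on the retained folds while the
    remote packet aggregates stay fixed.  ``cv_correction='full'`` keeps the
    full-lead-data correction terms.  The selected lambda minimizes the mean
    held-out deviance; ties go to the larger lambda (sparser model).  The
    grid walk stops ``patience`` nodes past the running minimum
    (``patience=None`` evaluates the whole grid).
    """
    pen = pen or PenaltySpec()
    bbar = as_beta(beta_bar)
    from .model_core import logistic_gradient, logistic_hessian

    counts = [int((lead.y == c).sum()) for c in (0, 1)]
    if min(counts) < folds:
        raise ValueError(
            f"lead site needs at least {folds} observations per class for "
            f"{folds}-fold CV; got {counts}")

    s_full = build_surrogate(lead, packets, bbar, order)
    grid = lambda_grid(s_full, n_lambda, lambda_min_ratio, pen)
    n_rem, g_rem, H_rem = _remote_aggregates(packets, lead.p, order)

    assign = stratified_folds(lead.y, folds, seed)
    Xf_shared = np.asfortranarray(lead.X)
    X2f_shared = np.square(Xf_shared)
    fold_ws, fold_te = [], []
    for f in range(folds):
        tr_rows = np.flatnonzero(assign != f)
        tr = lead.subset(tr_rows)
        te = lead.subset(np.flatnonzero(assign == f))
        if not tr.has_both_classes():
            raise ValueError(f"training fold {f} has a single outcome class")
        if cv_correction == "retained":
            g_tr = logistic_gradient(tr, bbar)
            N_f = tr.n_k + n_rem
            c_f = (tr.n_k * g_tr + g_rem) / N_f - g_tr
            D_f = None
            if order == 2:
                H_tr = logistic_hessian(tr, bbar)
                D_f = (tr.n_k * H_tr + H_rem) / N_f - H_tr
                D_f = 0.5 * (D_f + D_f.T)
            s_fold = SurrogateObjective(tr, bbar, c_f, D_f, order,
                                        int(N_f), len(packets) + 1)
        elif cv_correction == "full":
            s_fold = s_full.with_lead(tr, s_full.c)
        else:
            raise ValueError(f"unknown cv_correction mode {cv_correction!r}")
        fold_ws.append(_Workspace(s_fold, Xf=Xf_shared, X2f=X2f_shared,
                                  rows=tr_rows))
        fold_te.append(te)

    mask = _pen_mask(lead.p, pen)
    dev = np.full((grid.size, folds), np.nan)
    mean_dev = np.full(grid.size, np.inf)
    best_i, best_val = 0, np.inf
    last = grid.size - 1
    for i, lam in enumerate(grid):
        try:
            for f in range(folds):
                b = _solve_node(fold_ws[f], float(lam), pen.alpha, mask,
                                tol, max_iter)
                dev[i, f] = deviance(fold_te[f], b)
        except DivergenceError:
            # the surrogate is unbounded below here; every smaller lambda
            # is worse, so stop the walk and select among evaluated nodes
            import logging

            logging.getLogger(__name__).info(
                "CV walk stopped at node %d: surrogate unbounded below "
                "lambda=%.4g", i, lam)
            last = max(i - 1, 0)
            if i == 0:
                raise
            break
        mean_dev[i] = dev[i].mean()
        if mean_dev[i] < best_val:  # strict: ties keep the larger lambda
            best_val, best_i = mean_dev[i], i
        elif patience is not None and i - best_i >= patience:
            last = i
            break

    full_ws = _Workspace(s_full, Xf=Xf_shared, X2f=X2f_shared)
    betas = np.zeros((last + 1, lead.p))
    for i in range(last + 1):
        try:
            betas[i] = _solve_node(full_ws, float(grid[i]), pen.alpha, mask,
                                   tol, max_iter)
        except DivergenceError:
            if i <= best_i:
                raise
            betas = betas[:i]
            last = i - 1
            break
    return RegularizationPath(
        lambdas=grid, betas=betas, cv_deviance=mean_dev[:last + 1],
        cv_deviance_folds=dev[:last + 1], lambda_selected=float(grid[best_i]),
        beta_selected=Coefficients(betas[best_i].copy()),
        n_lambda=grid.size, lambda_min_ratio=float(grid[-1] / grid[0]))


def cv_fit(ds: SiteDataset, pen: PenaltySpec | None = None, folds: int = 5,
           seed: int = 0, **kwargs) -> RegularizationPath:
    """Plain CV-tuned penalized fit on a single dataset (no remote packets)."""
    return modified_cv(ds, [], np.zeros(ds.p), order=1, pen=pen, folds=folds,
                       seed=seed, **kwargs)
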