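"""Group-based trajectory model for monthly binary adherence indicators.

A G-component finite mixture: membership probabilities follow an
intercept-only multinomial logit, and within each group the monthly
indicators are independent Bernoulli with success probability given by a
logistic polynomial in (standardized) month. Estimation is by EM with
posterior-weighted IRLS M-steps; standard errors come from the numerically
differentiated observed information of the full mixture log-likelihood.

BIC follows the trajectory-modeling convention logL - (k/2) ln N with N the
number of patients (larger is better); N = patient-months is available via
``n_convention="observations"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit, logsumexp

from .basis import month_design

__all__ = [
    "TrajectorySpec",
    "GBTMParams",
    "GBTMFit",
    "loglik",
    "posterior",
    "fit_em",
    "bic",
    "wald_highest_terms",
    "match_groups",
    "LINPRED_CLIP",
]

LINPRED_CLIP = 12.0  # bounds the likelihood under separation (e.g. all-1 months)
_RIDGE = 1e-8
MAX_ORDER = 5


@dataclass(frozen=True)
class TrajectorySpec:
    """Group count and per-group polynomial orders."""

    G: int
    orders: tuple

    def __post_init__(self):
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if len(self.orders) != self.G:
            raise ValueError("orders must have one entry per group")
        if any(not 0 <= o <= MAX_ORDER for o in self.orders):
            raise ValueError(f"orders must lie in 0..{MAX_ORDER}")

    @property
    def n_params(self) -> int:
        return (self.G - 1) + sum(o + 1 for o in self.orders)

    def with_order(self, group: int, order: int) -> "TrajectorySpec":
        orders = list(self.orders)
        orders[group] = order
        return TrajectorySpec(self.G, tuple(orders))

    @classmethod
    def common(cls, G: int, order: int) -> "TrajectorySpec":
        return cls(G, (order,) * G)


@dataclass
class GBTMParams:
    """Mixing probabilities and per-group trajectory coefficients."""

    pi: np.ndarray
    beta: list  # list of per-group coefficient arrays (increasing powers)

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.beta = [np.asarray(b, dtype=float) for b in self.beta]
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a probability simplex")
        if len(self.beta) != self.pi.size:
            raise ValueError("one coefficient vector per mixture component")

    @property
    def G(self) -> int:
        return self.pi.size

    @property
    def spec(self) -> TrajectorySpec:
        return TrajectorySpec(self.G, tuple(b.size - 1 for b in self.beta))

    def trajectory_probs(self, n_months: int) -> np.ndarray:
        """G x T monthly success probabilities."""
        out = np.empty((self.G, n_months))
        for g, b in enumerate(self.beta):
            eta = np.clip(month_design(n_months, b.size - 1) @ b,
                          -LINPRED_CLIP, LINPRED_CLIP)
            out[g] = expit(eta)
        return out


@dataclass
class GBTMFit:
    spec: TrajectorySpec
    params: GBTMParams
    loglik: float
    bic: float
    posteriors: np.ndarray
    labels: np.ndarray  # 1-based modal assignment
    n_patients: int
    n_months: int
    converged: bool
    n_iter: int
    n_starts: int
    best_start: int
    _se: dict | None = field(default=None, repr=False)

    @property
    def assigned_shares(self) -> np.ndarray:
        return np.bincount(self.labels - 1, minlength=self.spec.G) / self.labels.size

    def standard_errors(self, panel: np.ndarray | None = None) -> dict:
        """SEs of all free parameters from the observed information (cached)."""
        if self._se is None:
            if panel is None:
                raise ValueError("panel required to compute standard errors")
            self._se = _observed_info_se(self.params, np.asarray(panel))
        return self._se


def _validate_panel(panel) -> np.ndarray:
    Y = np.asarray(panel)
    if Y.ndim != 2 or Y.size == 0:
        raise ValueError("panel must be a non-empty 2-D array")
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("panel entries must be binary 0/1")
    return Y.astype(float)


def _log_components(params: GBTMParams, Y: np.ndarray) -> np.ndarray:
    """N x G matrix of per-group log densities log f_g(y_i)."""
    T = Y.shape[1]
    probs = params.trajectory_probs(T)  # G x T
    logp = np.log(probs)
    log1mp = np.log1p(-probs)
    # sum_t [ y log p + (1-y) log(1-p) ] = Y @ (logp - log1mp)^T + sum log1mp
    return Y @ (logp - log1mp).T + log1mp.sum(axis=1)


def loglik(params: GBTMParams, panel) -> float:
    """Mixture log-likelihood, computed in log space with max-shift."""
    Y = _validate_panel(panel)
    logf = _log_components(params, Y)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
    return float(logsumexp(logpi + logf, axis=1).sum())


def posterior(params: GBTMParams, panel) -> np.ndarray:
    """N x G posterior membership probabilities (rows sum to 1)."""
    Y = _validate_panel(panel)
    logf = _log_components(params, Y)
    with np.errstate(divide="ignore"):
        a = np.log(params.pi) + logf
    a -= a.max(axis=1, keepdims=True)
    W = np.exp(a)
    W /= W.sum(axis=1, keepdims=True)
    return W


def _weighted_logistic(X: np.ndarray, trials: np.ndarray, successes: np.ndarray,
                       beta0: np.ndarray, max_iter: int = 50,
                       tol: float = 1e-10) -> np.ndarray:
    """Binomial IRLS on collapsed per-month counts, with a tiny ridge."""
    beta = beta0.copy()
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -LINPRED_CLIP, LINPRED_CLIP)
        mu = expit(eta)
        grad = X.T @ (successes - trials * mu) - _RIDGE * beta
        w = trials * mu * (1 - mu)
        H = X.T @ (X * w[:, None]) + _RIDGE * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _init_responsibilities(Y: np.ndarray, G: int, rng: np.random.Generator,
                           first: bool = False) -> np.ndarray:
    """Partition of jittered adherence row-sums, smoothed one-hot.

    The first start uses equal-size quantile blocks; later starts draw the
    block proportions from a flat Dirichlet so restarts explore genuinely
    different basins.
    """
    n = Y.shape[0]
    if G == 1:
        return np.ones((n, 1))
    score = Y.sum(axis=1) + rng.normal(0, 0.25, n)
    order = np.argsort(score)
    props = np.full(G, 1.0 / G) if first else rng.dirichlet(np.ones(G))
    cuts = np.minimum(np.round(np.cumsum(props[:-1]) * n).astype(int), n - 1)
    blocks = np.split(order, np.maximum.accumulate(np.maximum(cuts, 1)))
    W = np.full((n, G), 0.1 / (G - 1))
    for g, idx in enumerate(blocks):
        W[idx, g] = 0.9
    W /= W.sum(axis=1, keepdims=True)
    return W


def _em_once(Y: np.ndarray, spec: TrajectorySpec, W: np.ndarray,
             tol: float, max_iter: int) -> tuple[GBTMParams, float, bool, int]:
    n, T = Y.shape
    designs = [month_design(T, o) for o in spec.orders]
    betas = [np.zeros(o + 1) for o in spec.orders]
    pi = W.mean(axis=0)
    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step
        pi = np.clip(W.mean(axis=0), 1e-10, None)
        pi /= pi.sum()
        for g in range(spec.G):
            trials = W[:, g].sum() * np.ones(T)
            successes = Y.T @ W[:, g]
            betas[g] = _weighted_logistic(designs[g], trials, successes, betas[g])
        params = GBTMParams(pi=pi, beta=[b.copy() for b in betas])
        # E-step + log-likelihood
        logf = _log_components(params, Y)
        with np.errstate(divide="ignore"):
            a = np.log(params.pi) + logf
        ll = float(logsumexp(a, axis=1).sum())
        if ll + 1e-8 < prev_ll:
            warnings.warn(
                f"EM log-likelihood decreased by {prev_ll - ll:.3g} at iter {it}",
                RuntimeWarning,
            )
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * (abs(prev_ll) + 1.0):
            converged = True
            break
        prev_ll = ll
        a -= a.max(axis=1, keepdims=True)
        W = np.exp(a)
        W /= W.sum(axis=1, keepdims=True)
    return params, ll, converged, it


def fit_em(panel, spec: TrajectorySpec, starts: int = 10, seed: int = 0,
           tol: float = 1e-7, max_iter: int = 500,
           n_convention: str = "patients") -> GBTMFit:
    """Fit the mixture by EM, keeping the best of ``starts`` initializations.

    Deterministic given ``seed``. Ties across starts keep the earliest start.
    Non-convergence is recorded on the fit, not raised.
    """
    Y = _validate_panel(panel)
    n = Y.shape[0]
    if n < spec.G:
        raise ValueError("need at least as many patients as groups")
    rng = np.random.default_rng(seed)
    best = None
    for s in range(starts):
        W0 = _init_responsibilities(Y, spec.G, rng, first=(s == 0))
        params, ll, conv, it = _em_once(Y, spec, W0, tol, max_iter)
        if best is None or ll > best[1] + 1e-10:
            best = (params, ll, conv, it, s)
    params, ll, conv, it, s = best
    post = posterior(params, Y)
    labels = np.argmax(post, axis=1) + 1  # ties break toward the lowest index
    fit = GBTMFit(
        spec=spec, params=params, loglik=ll,
        bic=np.nan, posteriors=post, labels=labels,
        n_patients=n, n_months=Y.shape[1],
        converged=conv, n_iter=it, n_starts=starts, best_start=s,
    )
    fit.bic = bic(fit, n_convention=n_convention)
    return fit


def bic(fit: GBTMFit, n_convention: str = "patients") -> float:
    """logL - (k/2) ln N; larger is better. N = patients by default."""
    if n_convention == "patients":
        N = fit.n_patients
    elif n_convention == "observations":
        N = fit.n_patients * fit.n_months
    else:
        raise ValueError("n_convention must be 'patients' or 'observations'")
    k = fit.spec.n_params
    return fit.loglik - 0.5 * k * np.log(N)


# ---------------------------------------------------------------------------
# standard errors and Wald tests
# ---------------------------------------------------------------------------

def _pack(params: GBTMParams) -> np.ndarray:
    with np.errstate(divide="ignore"):
        alpha = np.log(params.pi[1:] / params.pi[0]) if params.G > 1 else np.empty(0)
    alpha = np.clip(alpha, -30, 30)
    return np.concatenate([alpha] + [b for b in params.beta])


def _unpack(theta: np.ndarray, spec: TrajectorySpec) -> GBTMParams:
    G = spec.G
    alpha = theta[: G - 1]
    eta = np.concatenate([[0.0], alpha])
    pi = np.exp(eta - logsumexp(eta))
    beta, pos = [], G - 1
    for o in spec.orders:
        beta.append(theta[pos : pos + o + 1])
        pos += o + 1
    return GBTMParams(pi=pi, beta=beta)


def _observed_info_se(params: GBTMParams, panel: np.ndarray) -> dict:
    """SEs from a central-difference Hessian of the mixture log-likelihood."""
    Y = _validate_panel(panel)
    spec = params.spec
    theta = _pack(params)
    k = theta.size

    def f(t):
        return loglik(_unpack(t, spec), Y)

    h = 1e-4
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            val = (f(theta + ei + ej) - f(theta + ei - ej)
                   - f(theta - ei + ej) + f(theta - ei - ej)) / (4 * h * h)
            H[i, j] = H[j, i] = val
    info = -H
    singular = False
    try:
        cov = np.linalg.inv(info)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        singular = True
        cov = np.linalg.pinv(info)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.abs(np.diag(cov)))
    G = spec.G
    beta_se, pos = [], G - 1
    for o in spec.orders:
        beta_se.append(se[pos : pos + o + 1])
        pos += o + 1
    return {"alpha": se[: G - 1], "beta": beta_se, "singular": singular}


def wald_highest_terms(fit: GBTMFit, panel) -> list[dict]:
    """Per group: z and two-sided p for the highest-order coefficient.

    For an order-0 group the intercept is its highest term. A singular
    information matrix flags the result and reports p = 1 (non-significant).
    """
    se = fit.standard_errors(panel)
    out = []
    for g in range(fit.spec.G):
        coef = fit.params.beta[g][-1]
        s = se["beta"][g][-1]
        flagged = bool(se["singular"]) or not np.isfinite(s) or s == 0
        if flagged:
            warnings.warn(f"group {g + 1}: unusable SE; reporting p=1", RuntimeWarning)
            z, p = np.nan, 1.0
        else:
            z = coef / s
            p = 2 * stats.norm.sf(abs(z))
        out.append({"group": g + 1, "order": fit.spec.orders[g],
                    "coef": float(coef), "se": float(s), "z": float(z),
                    "p": float(p), "flagged": flagged})
    return out


def match_groups(fitted_probs: np.ndarray, reference_probs: np.ndarray) -> np.ndarray:
    """Resolve label switching: permutation mapping fitted groups to reference.

    Minimizes total L2 distance between monthly mean curves. Returns ``perm``
    with ``perm[ref_group] = fitted_group`` (0-based).
    """
    from scipy.optimize import linear_sum_assignment

    cost = np.linalg.norm(
        reference_probs[:, None, :] - fitted_probs[None, :, :], axis=2
    )
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm
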