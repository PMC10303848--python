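"""Fractional multinomial logit for posterior membership probabilities.

Maximizes the multinomial quasi-log-likelihood sum_i sum_g s_ig ln mu_ig
where the outcome rows s_i are simplex vectors (here: posterior group
probabilities) and mu has the multinomial-logit mean with one group's
coefficients fixed at zero. Inference uses the heteroskedasticity-robust
sandwich covariance; effects are reported as adjusted odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FmlogitFit", "fit_fmlogit", "robust_vcov", "aor_table",
           "build_design"]

_SHARE_TOL = 1e-8


@dataclass
class FmlogitFit:
    gamma: np.ndarray            # (G-1) x P, non-reference groups in order
    vcov: np.ndarray | None      # robust covariance of vec(gamma), row-major
    qll: float
    ref_group: int               # 0-based index of the reference group
    group_names: list
    coef_names: list
    converged: bool
    n_iter: int
    n_obs: int

    @property
    def nonref_groups(self) -> list:
        return [g for g in range(len(self.group_names)) if g != self.ref_group]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Fitted mean matrix; rows sum to 1."""
        return _means(self.gamma, X, self.ref_group)

    def se(self) -> np.ndarray:
        if self.vcov is None:
            raise ValueError("no covariance attached; call robust_vcov first")
        return np.sqrt(np.diag(self.vcov)).reshape(self.gamma.shape)


def _means(gamma: np.ndarray, X: np.ndarray, ref: int) -> np.ndarray:
    n = X.shape[0]
    Gm1 = gamma.shape[0]
    eta = np.empty((n, Gm1 + 1))
    cols = [g for g in range(Gm1 + 1) if g != ref]
    eta[:, ref] = 0.0
    for j, g in enumerate(cols):
        eta[:, g] = X @ gamma[j]
    eta -= eta.max(axis=1, keepdims=True)
    mu = np.exp(eta)
    mu /= mu.sum(axis=1, keepdims=True)
    return mu


def _check_inputs(shares, design):
    S = np.asarray(shares, dtype=float)
    X = np.asarray(design, dtype=float)
    if S.ndim != 2 or S.shape[1] < 2:
        raise ValueError("shares must be N x G with G >= 2")
    if np.any(S < -_SHARE_TOL) or np.any(S > 1 + _SHARE_TOL):
        raise ValueError("share entries must lie in [0, 1]")
    if np.any(np.abs(S.sum(axis=1) - 1) > _SHARE_TOL):
        raise ValueError(f"share rows must sum to 1 within {_SHARE_TOL}")
    if X.shape[0] != S.shape[0]:
        raise ValueError("shares and design must have the same row count")
    return S, X


def _name_collinear(X: np.ndarray, names: list) -> list:
    """Columns whose removal restores full rank, via pivoted QR."""
    from scipy.linalg import qr

    _, R, piv = qr(X, pivoting=True, mode="economic")
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * abs(R[0, 0])))
    return [names[j] for j in sorted(piv[rank:])]


def fit_fmlogit(shares, design, ref_group: int = 0,
                coef_names: list | None = None,
                group_names: list | None = None,
                max_iter: int = 100, grad_tol: float = 1e-6,
                compute_vcov: bool = True) -> FmlogitFit:
    """Newton-with-step-halving fit starting from zero coefficients.

    The quasi-log-likelihood is concave in the stacked coefficients, so the
    zero start is safe. Converged when the gradient sup-norm < ``grad_tol``.
    """
    S, X = _check_inputs(shares, design)
    n, G = S.shape
    P = X.shape[1]
    coef_names = coef_names or [f"x{j}" for j in range(P)]
    group_names = group_names or [f"group{g + 1}" for g in range(G)]
    # constant columns are only legal as a single all-ones intercept
    const = np.nonzero(X.std(axis=0) == 0)[0]
    bad = [coef_names[j] for j in const if not np.all(X[:, j] == 1.0)]
    if len(const) - len(bad) > 1:
        bad += [coef_names[j] for j in const if np.all(X[:, j] == 1.0)][1:]
    if bad:
        raise ValueError(f"zero-variance covariate column(s): {bad}")
    if np.linalg.matrix_rank(X) < P:
        raise ValueError(
            f"design is rank deficient; collinear column(s): "
            f"{_name_collinear(X, coef_names)}"
        )
    if not 0 <= ref_group < G:
        raise ValueError("ref_group out of range")

    cols = [g for g in range(G) if g != ref_group]
    gamma = np.zeros((G - 1, P))

    def qll(gm):
        mu = _means(gm, X, ref_group)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(S > 0, S * np.log(mu), 0.0)
        return float(terms.sum())

    cur = qll(gamma)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = _means(gamma, X, ref_group)
        resid = S[:, cols] - mu[:, cols]          # n x (G-1)
        grad = (X.T @ resid).T.reshape(-1)        # vec over groups (row-major)
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        # Hessian of the quasi-log-likelihood (negative definite)
        k = (G - 1) * P
        H = np.zeros((k, k))
        for a in range(G - 1):
            for b in range(a, G - 1):
                w = (mu[:, cols[a]] * ((a == b) - mu[:, cols[b]]))
                blk = -X.T @ (X * w[:, None])
                H[a * P:(a + 1) * P, b * P:(b + 1) * P] = blk
                H[b * P:(b + 1) * P, a * P:(a + 1) * P] = blk.T
        step = np.linalg.solve(H + 1e-12 * np.eye(k), -grad).reshape(G - 1, P)
        scale = 1.0
        for _ in range(30):
            cand = gamma + scale * step
            val = qll(cand)
            if val >= cur - 1e-12:
                gamma, cur = cand, val
                break
            scale /= 2
        else:  # pragma: no cover - concave objective
            break

    fit = FmlogitFit(gamma=gamma, vcov=None, qll=cur, ref_group=ref_group,
                     group_names=list(group_names), coef_names=list(coef_names),
                     converged=converged, n_iter=it, n_obs=n)
    if compute_vcov:
        fit.vcov = robust_vcov(fit, S, X)
    return fit


def robust_vcov(fit: FmlogitFit, shares, design) -> np.ndarray:
    """Sandwich A^-1 B A^-1 with A the quasi-likelihood Hessian and B the
    outer product of per-patient scores."""
    S, X = _check_inputs(shares, design)
    G = S.shape[1]
    P = X.shape[1]
    cols = fit.nonref_groups
    mu = _means(fit.gamma, X, fit.ref_group)
    resid = S[:, cols] - mu[:, cols]
    k = (G - 1) * P
    A = np.zeros((k, k))
    for a in range(G - 1):
        for b in range(a, G - 1):
            w = mu[:, cols[a]] * ((a == b) - mu[:, cols[b]])
            blk = -X.T @ (X * w[:, None])
            A[a * P:(a + 1) * P, b * P:(b + 1) * P] = blk
            A[b * P:(b + 1) * P, a * P:(a + 1) * P] = blk.T
    # per-patient score: kron(resid_i, x_i), summed outer products
    scores = (resid[:, :, None] * X[:, None, :]).reshape(len(S), k)
    B = scores.T @ scores
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular quasi-likelihood Hessian") from exc
    return Ainv @ B @ Ainv


def aor_table(fit: FmlogitFit, level: float = 0.95) -> pd.DataFrame:
    """Adjusted odds ratios exp(gamma) with Wald CIs and two-sided p-values."""
    se = fit.se()
    z975 = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for j, g in enumerate(fit.nonref_groups):
        for p, name in enumerate(fit.coef_names):
            gamma = fit.gamma[j, p]
            s = se[j, p]
            z = gamma / s if s > 0 else np.nan
            rows.append({
                "group": fit.group_names[g],
                "covariate": name,
                "coef": gamma,
                "se": s,
                "aor": np.exp(gamma),
                "ci_low": np.exp(gamma - z975 * s),
                "ci_high": np.exp(gamma + z975 * s),
                "p": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
            })
    return pd.DataFrame(rows)


def build_design(covariates: pd.DataFrame, columns: list,
                 missing_indicator: list | None = None) -> tuple[np.ndarray, list]:
    """Design matrix with intercept from named covariate columns.

    Categorical (object) columns are expanded to reference-coded dummies.
    Columns listed in ``missing_indicator`` contribute a ``<col>_missing``
    dummy, with missing values zero-filled in the main column (mirrors a
    missing-indicator design for scores that are not always observed).
    """
    missing_indicator = missing_indicator or []
    parts = [np.ones(len(covariates))]
    names = ["const"]
    for col in columns:
        if col not in covariates.columns:
            raise KeyError(f"covariate column missing: {col!r}")
        s = covariates[col]
        if s.dtype == object:
            cats = sorted(s.dropna().unique())
            for cat in cats[1:]:  # first category is the reference
                parts.append((s == cat).astype(float).to_numpy())
                names.append(f"{col}[{cat}]")
        else:
            v = s.astype(float).to_numpy()
            if col in missing_indicator:
                miss = ~np.isfinite(v)
                parts.append(np.where(miss, 0.0, v))
                names.append(col)
                parts.append(miss.astype(float))
                names.append(f"{col}_missing")
            else:
                parts.append(v)
                names.append(col)
    return np.column_stack(parts), names
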