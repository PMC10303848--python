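"""Two-stage trajectory-model specification search.

Stage 1 fits every combination of group count (1..max_groups) and common
polynomial order (0..max_order) — 30 candidates at the defaults — and keeps
the best-BIC converged fit. Stage 2 repeatedly drops the polynomial order of
the group whose highest-order coefficient has the largest non-significant
Wald p-value (one reduction per refit) until every group's highest retained
term is significant or the group has hit order 0. A final model whose
smallest assigned group falls below ``min_share`` triggers a flagged re-run
of stage 2 at G-1 groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gbtm import GBTMFit, TrajectorySpec, fit_em, wald_highest_terms

__all__ = ["SelectionResult", "grid_search", "reduce_orders", "select_model"]


@dataclass
class SelectionResult:
    grid: pd.DataFrame | None
    stage1_spec: TrajectorySpec | None
    trace: list
    final_fit: GBTMFit | None
    min_share_ok: bool = True
    fallback_used: bool = False
    floor_groups: tuple = ()


def grid_search(panel, max_groups: int = 5, max_order: int = 5,
                starts: int = 10, seed: int = 0, tol: float = 1e-7,
                max_iter: int = 500) -> SelectionResult:
    """Stage 1: BIC over the (group count) x (common order) grid."""
    rows = []
    fits = {}
    for G in range(1, max_groups + 1):
        for order in range(max_order + 1):
            spec = TrajectorySpec.common(G, order)
            try:
                fit = fit_em(panel, spec, starts=starts, seed=seed,
                             tol=tol, max_iter=max_iter)
                fits[(G, order)] = fit
                rows.append({"G": G, "order": order, "k": spec.n_params,
                             "loglik": fit.loglik, "bic": fit.bic,
                             "converged": fit.converged})
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"grid cell G={G}, order={order} failed: {exc}")
                rows.append({"G": G, "order": order, "k": spec.n_params,
                             "loglik": np.nan, "bic": np.nan, "converged": False})
    grid = pd.DataFrame(rows)
    ok = grid[grid["converged"]]
    if ok.empty:
        raise RuntimeError("no grid specification converged")
    best = ok.loc[ok["bic"].idxmax()]
    spec = TrajectorySpec.common(int(best["G"]), int(best["order"]))
    return SelectionResult(grid=grid, stage1_spec=spec, trace=[],
                           final_fit=fits[(int(best["G"]), int(best["order"]))])


def reduce_orders(panel, stage1: SelectionResult, alpha: float = 0.05,
                  min_share: float = 0.05, starts: int = 10, seed: int = 0,
                  tol: float = 1e-7, max_iter: int = 500,
                  _allow_fallback: bool = True) -> SelectionResult:
    """Stage 2: per-group polynomial-order reduction under Wald significance.

    Each step reduces only the group with the largest offending p-value,
    then refits; groups already at order 0 are never reduced further (floor),
    even with a non-significant intercept.
    """
    spec = stage1.stage1_spec
    fit = stage1.final_fit
    if fit is None or fit.spec != spec:
        fit = fit_em(panel, spec, starts=starts, seed=seed, tol=tol,
                     max_iter=max_iter)
    trace = []
    while True:
        tests = wald_highest_terms(fit, panel)
        offenders = [t for t in tests if t["p"] >= alpha and t["order"] > 0]
        if not offenders:
            break
        worst = max(offenders, key=lambda t: t["p"])
        g = worst["group"] - 1
        new_spec = fit.spec.with_order(g, fit.spec.orders[g] - 1)
        trace.append({"step": len(trace) + 1, "group": worst["group"],
                      "p": worst["p"], "from_order": fit.spec.orders[g],
                      "to_order": new_spec.orders[g],
                      "spec": new_spec.orders})
        fit = fit_em(panel, new_spec, starts=starts, seed=seed, tol=tol,
                     max_iter=max_iter)

    tests = wald_highest_terms(fit, panel)
    floor = tuple(t["group"] for t in tests if t["order"] == 0 and t["p"] >= alpha)

    min_share_ok = bool(fit.assigned_shares.min() >= min_share)
    fallback = False
    if not min_share_ok and fit.spec.G > 1 and _allow_fallback:
        warnings.warn(
            f"smallest assigned share {fit.assigned_shares.min():.3f} < "
            f"{min_share}; re-running reduction at G={fit.spec.G - 1}"
        )
        smaller = SelectionResult(
            grid=stage1.grid,
            stage1_spec=TrajectorySpec.common(fit.spec.G - 1,
                                              max(stage1.stage1_spec.orders)),
            trace=[], final_fit=None,
        )
        redo = reduce_orders(panel, smaller, alpha=alpha, min_share=min_share,
                             starts=starts, seed=seed, tol=tol,
                             max_iter=max_iter, _allow_fallback=False)
        redo.grid = stage1.grid
        redo.trace = trace + [{"step": len(trace) + 1, "group": None,
                               "p": None, "fallback_to_G": fit.spec.G - 1,
                               "spec": redo.final_fit.spec.orders}] + redo.trace
        redo.fallback_used = True
        return redo

    return SelectionResult(grid=stage1.grid, stage1_spec=spec, trace=trace,
                           final_fit=fit, min_share_ok=min_share_ok,
                           fallback_used=fallback, floor_groups=floor)


def select_model(panel, max_groups: int = 5, max_order: int = 5,
                 alpha: float = 0.05, min_share: float = 0.05,
                 starts: int = 10, seed: int = 0, tol: float = 1e-7,
                 max_iter: int = 500) -> SelectionResult:
    """Full two-stage search: grid, then order reduction."""
    stage1 = grid_search(panel, max_groups=max_groups, max_order=max_order,
                         starts=starts, seed=seed, tol=tol, max_iter=max_iter)
    return reduce_orders(panel, stage1, alpha=alpha, min_share=min_share,
                         starts=starts, seed=seed, tol=tol, max_iter=max_iter)
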