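"""Model-adequacy diagnostics for a fitted trajectory mixture.

Average posterior probability of assignment (APP, threshold 0.7), odds of
correct classification (OCC, threshold 5), relative entropy (normalized
classification entropy, threshold 0.7), group shares, and observed-vs-fitted
trajectory tables for spaghetti-plot export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gbtm import GBTMFit, GBTMParams

__all__ = [
    "DiagnosticsReport",
    "assign_groups",
    "app",
    "occ",
    "relative_entropy",
    "trajectory_tables",
    "diagnostics_report",
    "APP_THRESHOLD",
    "OCC_THRESHOLD",
    "ENTROPY_THRESHOLD",
]

APP_THRESHOLD = 0.7
OCC_THRESHOLD = 5.0
ENTROPY_THRESHOLD = 0.7
_OCC_CAP = 1e12


@dataclass
class DiagnosticsReport:
    app: np.ndarray
    occ: np.ndarray
    pi: np.ndarray
    assigned_share: np.ndarray
    entropy: float
    app_ok: bool
    occ_ok: bool
    entropy_ok: bool
    flags: list = field(default_factory=list)
    trajectories: pd.DataFrame | None = None
    spaghetti: pd.DataFrame | None = None

    @property
    def all_ok(self) -> bool:
        return self.app_ok and self.occ_ok and self.entropy_ok

    def to_dict(self) -> dict:
        return {
            "app": [None if np.isnan(a) else float(a) for a in self.app],
            "occ": [float(o) for o in self.occ],
            "pi": [float(p) for p in self.pi],
            "assigned_share": [float(s) for s in self.assigned_share],
            "relative_entropy": float(self.entropy),
            "app_ok": self.app_ok,
            "occ_ok": self.occ_ok,
            "entropy_ok": self.entropy_ok,
            "flags": list(self.flags),
        }


def _check_posteriors(posteriors) -> np.ndarray:
    P = np.asarray(posteriors, dtype=float)
    if P.ndim != 2 or P.size == 0:
        raise ValueError("posteriors must be a non-empty 2-D array")
    if np.any(P < -1e-12) or np.any(np.abs(P.sum(axis=1) - 1) > 1e-8):
        raise ValueError("posterior rows must be probabilities summing to 1")
    return P


def assign_groups(posteriors, flags: list | None = None) -> np.ndarray:
    """Modal assignment (1-based). Ties go to the lowest group index."""
    P = _check_posteriors(posteriors)
    labels = np.argmax(P, axis=1) + 1
    ties = (np.isclose(P, P.max(axis=1, keepdims=True))).sum(axis=1) > 1
    if ties.any() and flags is not None:
        flags.append(f"{int(ties.sum())} tie(s) broken toward the lowest group index")
    return labels


def app(posteriors, labels) -> np.ndarray:
    """Per-group mean posterior among assigned members; NaN for empty groups."""
    P = _check_posteriors(posteriors)
    labels = np.asarray(labels)
    G = P.shape[1]
    out = np.full(G, np.nan)
    for g in range(G):
        members = labels == g + 1
        if members.any():
            out[g] = P[members, g].mean()
    return out


def occ(app_g: float, pi_g: float) -> float:
    """Odds of correct classification: odds(APP) / odds(pi).

    Boundary APP or pi values are capped (with a warning) rather than
    returning inf/0.
    """
    if not 0 <= app_g <= 1 or not 0 <= pi_g <= 1:
        raise ValueError("app and pi must lie in [0, 1]")
    if app_g in (0.0, 1.0) or pi_g in (0.0, 1.0):
        warnings.warn("boundary APP/pi in OCC; capping", RuntimeWarning)
        a = min(max(app_g, 1e-12), 1 - 1e-12)
        p = min(max(pi_g, 1e-12), 1 - 1e-12)
        return float(min((a / (1 - a)) / (p / (1 - p)), _OCC_CAP))
    return float((app_g / (1 - app_g)) / (pi_g / (1 - pi_g)))


def relative_entropy(posteriors) -> float:
    """1 - (total posterior entropy) / (N ln G), with 0 ln 0 = 0.

    G = 1 returns 1 by convention.
    """
    P = _check_posteriors(posteriors)
    N, G = P.shape
    if G == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log(P), 0.0)
    return float(1.0 - terms.sum() / (N * np.log(G)))


def trajectory_tables(panel, posteriors, params: GBTMParams,
                      flags: list | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed vs fitted monthly means per assigned group, plus per-patient rows.

    Returns ``(trajectories, spaghetti)``: the first has one row per
    group-month with the assigned members' mean adherence and the fitted
    inverse-logit trajectory; the second one row per patient-month tagged by
    assigned group.
    """
    Y = np.asarray(panel)
    P = _check_posteriors(posteriors)
    labels = assign_groups(P)
    G, T = P.shape[1], Y.shape[1]
    fitted = params.trajectory_probs(T)
    rows = []
    for g in range(G):
        members = labels == g + 1
        if not members.any():
            if flags is not None:
                flags.append(f"group {g + 1} has no assigned members")
            continue
        obs = Y[members].mean(axis=0)
        for t in range(T):
            rows.append({"group": g + 1, "month": t + 1,
                         "observed": obs[t], "fitted": fitted[g, t],
                         "n_assigned": int(members.sum())})
    traj = pd.DataFrame(rows, columns=["group", "month", "observed", "fitted",
                                       "n_assigned"])
    spaghetti = pd.DataFrame({
        "patient": np.repeat(np.arange(Y.shape[0]), T),
        "group": np.repeat(labels, T),
        "month": np.tile(np.arange(1, T + 1), Y.shape[0]),
        "adherent": Y.reshape(-1).astype(int),
    })
    return traj, spaghetti


def diagnostics_report(fit: GBTMFit, panel=None) -> DiagnosticsReport:
    """Full adequacy report for a fitted model."""
    flags: list = []
    P = fit.posteriors
    labels = assign_groups(P, flags)
    apps = app(P, labels)
    pi = fit.params.pi
    occs = np.empty(fit.spec.G)
    for g in range(fit.spec.G):
        if np.isnan(apps[g]):
            flags.append(f"APP undefined for empty group {g + 1}")
            occs[g] = np.nan
        else:
            occs[g] = occ(apps[g], pi[g])
    ent = relative_entropy(P)
    if fit.spec.G == 1:
        flags.append("single-group model: entropy 1 by convention")
    share = np.bincount(labels - 1, minlength=fit.spec.G) / labels.size
    traj = spag = None
    if panel is not None:
        traj, spag = trajectory_tables(panel, P, fit.params, flags)
    valid = ~np.isnan(apps)
    return DiagnosticsReport(
        app=apps, occ=occs, pi=pi, assigned_share=share, entropy=ent,
        app_ok=bool(valid.any() and np.all(apps[valid] >= APP_THRESHOLD)),
        occ_ok=bool(valid.any() and np.all(occs[valid] > OCC_THRESHOLD)),
        entropy_ok=bool(ent >= ENTROPY_THRESHOLD),
        flags=flags, trajectories=traj, spaghetti=spag,
    )
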