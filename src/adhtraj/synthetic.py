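"""Synthetic cohort generator with latent trajectory-group structure.

Generates covariates, true group labels, a monthly binary adherence panel,
and claims-shaped tables (fills, enrollment, diagnoses) so the whole
pipeline is testable without external data. Group trajectories are
polynomials on the standardized month basis (logit scale); months are
conditionally independent given group by default, with an optional
persistence knob.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .basis import month_design

__all__ = [
    "Scenario",
    "SyntheticCohort",
    "ClaimsConfig",
    "simulate_panel",
    "simulate_claims",
    "simulate_cohort",
    "default_scenario",
    "scenario_names",
    "save_scenario",
    "load_scenario",
    "expit",
]

SIMPLEX_TOL = 1e-12


def expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# covariate generators: name -> callable(rng, n) -> ndarray
# ---------------------------------------------------------------------------

def _age(rng, n):
    return np.clip(np.round(rng.normal(75.4, 6.0, n)), 66, 99)


def _bernoulli(p):
    return lambda rng, n: rng.binomial(1, p, n)


def _region(rng, n):
    return rng.choice(["Northeast", "Midwest", "South", "West"], size=n,
                      p=[0.2, 0.25, 0.35, 0.2])


def _deprivation(rng, n):
    return np.clip(np.round(rng.normal(50, 25, n), 1), 0, 100)


def _poisson(lam):
    return lambda rng, n: rng.poisson(lam, n)


DEFAULT_COVARIATE_SPEC: dict[str, Callable] = {
    "age": _age,
    "female": _bernoulli(0.389),
    "nonwhite": _bernoulli(0.089),
    "region": _region,
    "deprivation_score": _deprivation,
    "comorbidity_count": _poisson(3.0),
    "medication_count": _poisson(10.0),
    "any_hospitalization": _bernoulli(0.3),
}


@dataclass(frozen=True)
class Scenario:
    """Data-generating configuration for a synthetic cohort.

    ``group_trajectories[g]`` holds polynomial coefficients (increasing
    powers) on the standardized month basis, logit scale. ``membership_coefs``
    is an optional (G-1) x P matrix of covariate effects on membership logits
    (group 1 is the reference, fixed at zero); covariate order follows
    ``membership_covariates``.
    """

    n_patients: int
    group_probs: tuple
    group_trajectories: tuple
    n_months: int = 12
    membership_coefs: tuple | None = None
    membership_covariates: tuple | None = None
    covariate_spec: tuple = tuple(DEFAULT_COVARIATE_SPEC)
    persistence: float = 0.0
    seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        probs = np.asarray(self.group_probs, dtype=float)
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.n_months < 2:
            raise ValueError("n_months must be >= 2")
        if probs.ndim != 1 or probs.size < 1:
            raise ValueError("group_probs must be a non-empty vector")
        if np.any(probs < 0):
            raise ValueError("group_probs entries must be >= 0")
        if abs(probs.sum() - 1.0) > SIMPLEX_TOL:
            raise ValueError(
                f"group_probs must sum to 1 within {SIMPLEX_TOL}; got {probs.sum()!r}"
            )
        if len(self.group_trajectories) != probs.size:
            raise ValueError(
                "group_trajectories length must match group_probs length "
                f"({len(self.group_trajectories)} vs {probs.size})"
            )
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must lie in [0, 1)")
        if self.membership_coefs is not None:
            mc = np.asarray(self.membership_coefs, dtype=float)
            if mc.shape[0] != probs.size - 1:
                raise ValueError("membership_coefs must have G-1 rows")
            if self.membership_covariates is None or mc.shape[1] != len(
                self.membership_covariates
            ):
                raise ValueError(
                    "membership_covariates must name one column per membership_coefs column"
                )

    @property
    def n_groups(self) -> int:
        return len(self.group_probs)

    def trajectory_probs(self) -> np.ndarray:
        """G x T matrix of monthly adherence probabilities per group."""
        out = np.empty((self.n_groups, self.n_months))
        for g, beta in enumerate(self.group_trajectories):
            beta = np.asarray(beta, dtype=float)
            X = month_design(self.n_months, beta.size - 1)
            out[g] = expit(X @ beta)
        return out


@dataclass
class SyntheticCohort:
    covariates: pd.DataFrame
    labels: np.ndarray  # true groups, 1-based
    panel: np.ndarray  # n_patients x n_months binary
    fills: pd.DataFrame | None = None
    enrollment: pd.DataFrame | None = None
    diagnoses: pd.DataFrame | None = None

    def __post_init__(self):
        n = len(self.covariates)
        if self.panel.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError("covariates, labels and panel must align")
        if self.covariates["patient_id"].duplicated().any():
            raise ValueError("duplicate patient ids")

    @property
    def panel_frame(self) -> pd.DataFrame:
        cols = [f"m{m}" for m in range(1, self.panel.shape[1] + 1)]
        df = pd.DataFrame(self.panel, columns=cols)
        df.insert(0, "patient_id", self.covariates["patient_id"].to_numpy())
        return df


@dataclass(frozen=True)
class ClaimsConfig:
    """Knobs for turning a panel into claims-shaped tables.

    ``short_fill_prob`` is the chance that a non-adherent month receives a
    short fill (``short_fill_days`` < 24 days of supply) instead of no fill.
    ``violators`` maps cohort-filter names to counts of extra rule-breaking
    patients appended to the tables (ids prefixed ``viol_``).
    """

    fill_days: int = 30
    index_fill_days: int = 30
    short_fill_prob: float = 0.0
    short_fill_days: int = 10
    baseline_days: int = 360
    followup_days: int = 360
    violators: tuple = ()

    def __post_init__(self):
        if not 0 <= self.short_fill_prob <= 1:
            raise ValueError("short_fill_prob must lie in [0, 1]")
        if not 1 <= self.short_fill_days < 24:
            raise ValueError("short_fill_days must be in [1, 24)")
        if self.index_fill_days < 30:
            raise ValueError("index fill must carry >= 30 days of supply")


def _generate_covariates(scenario: Scenario, rng: np.random.Generator) -> pd.DataFrame:
    n = scenario.n_patients
    data = {"patient_id": [f"p{i:05d}" for i in range(1, n + 1)]}
    for name in scenario.covariate_spec:
        gen = DEFAULT_COVARIATE_SPEC.get(name)
        if gen is None:
            raise KeyError(f"unknown covariate generator: {name!r}")
        data[name] = gen(rng, n)
    return pd.DataFrame(data)


def simulate_panel(scenario: Scenario) -> SyntheticCohort:
    """Draw true groups and the monthly adherence panel.

    Groups come from ``group_probs`` (or the membership logit model when
    ``membership_coefs`` is set); monthly indicators are Bernoulli draws from
    each group's trajectory, independent across months unless
    ``persistence`` > 0, in which case each month copies the previous
    indicator with that probability instead of drawing fresh.
    """
    rng = np.random.default_rng(scenario.seed)
    covariates = _generate_covariates(scenario, rng)
    n, G, T = scenario.n_patients, scenario.n_groups, scenario.n_months

    if scenario.membership_coefs is None:
        labels = rng.choice(G, size=n, p=np.asarray(scenario.group_probs)) + 1
    else:
        mc = np.asarray(scenario.membership_coefs, dtype=float)
        X = covariates[list(scenario.membership_covariates)].to_numpy(dtype=float)
        base = np.log(np.asarray(scenario.group_probs))  # anchors means at group_probs
        eta = np.column_stack([np.zeros(n)] + [X @ mc[g] for g in range(G - 1)])
        eta += base - base[0]
        prob = np.exp(eta - eta.max(axis=1, keepdims=True))
        prob /= prob.sum(axis=1, keepdims=True)
        u = rng.random(n)
        labels = (prob.cumsum(axis=1) < u[:, None]).sum(axis=1) + 1

    traj = scenario.trajectory_probs()  # G x T
    p = traj[labels - 1]  # n x T
    panel = (rng.random((n, T)) < p).astype(int)
    if scenario.persistence > 0:
        copy = rng.random((n, T)) < scenario.persistence
        for t in range(1, T):
            panel[:, t] = np.where(copy[:, t], panel[:, t - 1], panel[:, t])
    return SyntheticCohort(covariates=covariates, labels=labels, panel=panel)


def _violator_rows(kind: str, pid: str, config: ClaimsConfig):
    """Tables for one patient breaking exactly one cohort rule."""
    cov = {
        "patient_id": pid, "age": 75, "female": 0, "nonwhite": 0,
        "region": "South", "deprivation_score": 50.0, "comorbidity_count": 2,
        "medication_count": 8, "any_hospitalization": 0,
        "lung_transplant": 0, "snf": 0, "ltc": 0, "hospice": 0,
        "dual_eligible": 0, "death_day": np.nan,
    }
    fills = [
        {"patient_id": pid, "day": 0, "days_supply": 30, "drug": "nintedanib"}
    ]
    enroll = [{"patient_id": pid, "start_day": -config.baseline_days,
               "end_day": config.followup_days, "part_a": 1, "part_b": 1, "part_d": 1}]
    dx = [
        {"patient_id": pid, "day": -200, "code": "IPF", "setting": "outpatient"},
        {"patient_id": pid, "day": -150, "code": "IPF", "setting": "outpatient"},
    ]
    if kind == "age":
        cov["age"] = 64
    elif kind == "enrollment":
        enroll = [{"patient_id": pid, "start_day": -100,
                   "end_day": config.followup_days, "part_a": 1, "part_b": 1, "part_d": 1}]
    elif kind == "diagnosis":
        dx = [
            {"patient_id": pid, "day": -60, "code": "IPF", "setting": "outpatient"},
            {"patient_id": pid, "day": -50, "code": "IPF", "setting": "outpatient"},
        ]
    elif kind == "baseline_antifibrotic":
        fills.append({"patient_id": pid, "day": -90, "days_supply": 30,
                      "drug": "pirfenidone"})
    elif kind == "excluded_care":
        cov["hospice"] = 1
    elif kind == "comorbid_exclusion":
        dx.append({"patient_id": pid, "day": -120, "code": "LUNG_CANCER",
                   "setting": "inpatient"})
    elif kind == "pirfenidone_overlap":
        fills.append({"patient_id": pid, "day": 10, "days_supply": 30,
                      "drug": "pirfenidone"})
    elif kind == "death":
        cov["death_day"] = 200.0
    else:
        raise KeyError(f"unknown violator kind: {kind!r}")
    return cov, fills, enroll, dx


def simulate_claims(
    scenario: Scenario,
    cohort: SyntheticCohort,
    config: ClaimsConfig = ClaimsConfig(),
) -> SyntheticCohort:
    """Emit fills/enrollment/diagnosis tables consistent with the panel.

    Every patient gets an index fill of ``index_fill_days`` (>= 30) at day 0.
    Each later adherent month receives a 30-day fill at that month's first
    day; non-adherent months get no fill, or a short (< 24 day) fill with
    probability ``short_fill_prob``. With no short fills the tables round-trip
    through the PDC engine to the panel, up to month 1 being structurally
    adherent because of the index fill.
    """
    if cohort.panel is None:
        raise ValueError("cohort must carry a panel")
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 7]))
    fills, enroll, dx = [], [], []
    cov = cohort.covariates.copy()
    for flag in ("lung_transplant", "snf", "ltc", "hospice", "dual_eligible"):
        if flag not in cov.columns:
            cov[flag] = 0
    if "death_day" not in cov.columns:
        cov["death_day"] = np.nan

    for i, pid in enumerate(cov["patient_id"]):
        fills.append({"patient_id": pid, "day": 0, "days_supply":
                      config.index_fill_days, "drug": "nintedanib"})
        for m in range(1, scenario.n_months):  # month m+1, starts day 30*m
            if cohort.panel[i, m] == 1:
                fills.append({"patient_id": pid, "day": 30 * m,
                              "days_supply": config.fill_days, "drug": "nintedanib"})
            elif config.short_fill_prob > 0 and rng.random() < config.short_fill_prob:
                fills.append({"patient_id": pid, "day": 30 * m,
                              "days_supply": config.short_fill_days,
                              "drug": "nintedanib"})
        enroll.append({"patient_id": pid, "start_day": -config.baseline_days,
                       "end_day": config.followup_days,
                       "part_a": 1, "part_b": 1, "part_d": 1})
        # two qualifying outpatient claims >= 14 days apart in baseline
        d1 = int(rng.integers(-config.baseline_days, -30))
        d2 = min(d1 + 14 + int(rng.integers(0, 60)), -1)
        dx.append({"patient_id": pid, "day": d1, "code": "IPF", "setting": "outpatient"})
        dx.append({"patient_id": pid, "day": d2, "code": "IPF", "setting": "outpatient"})

    extra_cov = []
    counter = 0
    for kind in config.violators:
        counter += 1
        vc, vf, ve, vd = _violator_rows(kind, f"viol_{counter:03d}_{kind}", config)
        extra_cov.append(vc)
        fills.extend(vf)
        enroll.extend(ve)
        dx.extend(vd)
    if extra_cov:
        cov = pd.concat([cov, pd.DataFrame(extra_cov)], ignore_index=True)
        cov["death_day"] = cov["death_day"].astype(float)
        labels = np.concatenate([cohort.labels, np.zeros(len(extra_cov), dtype=int)])
        panel = np.vstack([cohort.panel,
                           np.zeros((len(extra_cov), scenario.n_months), dtype=int)])
    else:
        labels, panel = cohort.labels, cohort.panel

    return SyntheticCohort(
        covariates=cov,
        labels=labels,
        panel=panel,
        fills=pd.DataFrame(fills),
        enrollment=pd.DataFrame(enroll),
        diagnoses=pd.DataFrame(dx),
    )


def simulate_cohort(
    scenario: Scenario, config: ClaimsConfig = ClaimsConfig()
) -> SyntheticCohort:
    """``simulate_panel`` followed by ``simulate_claims``."""
    return simulate_claims(scenario, simulate_panel(scenario), config)


# ---------------------------------------------------------------------------
# scenario registry
# ---------------------------------------------------------------------------

# Five-group default. Printed shares (43.1, 11.9, 10.4, 13.2, 21.5)% sum to
# 100.1% from rounding; renormalized to a proper simplex here. Trajectory
# coefficients are fixed configuration constants (standardized month basis,
# logit scale) chosen so the group mean curves have the qualitative shapes
# the labels describe; they are not estimates.
_PAPER5_SHARES = np.array([0.431, 0.119, 0.104, 0.132, 0.215])
_PAPER5 = dict(
    group_probs=tuple(_PAPER5_SHARES / _PAPER5_SHARES.sum()),
    group_trajectories=(
        (3.4,),                                      # high: ~0.97 throughout
        (-0.2205, 0.3008, 0.4789, -0.3623),          # moderate: ~0.5 from month 3
        (1.3253, -3.0046, -1.7988, 0.5072, 0.4712),  # high-then-poor: drop after month 7
        (-1.4732, -3.0281, 0.1565, 0.4784),          # delayed-poor: slide then sharp drop
        (-4.8946, -0.9524, 1.2613, -0.4379),         # early-poor: near 0 by month 4
    ),
    name="paper5",
)

_REGISTRY: dict[str, dict] = {
    "paper5": _PAPER5,
    "two_group_easy": dict(
        group_probs=(0.6, 0.4),
        group_trajectories=((3.0,), (-3.0,)),
        name="two_group_easy",
    ),
    "one_group_null": dict(
        group_probs=(1.0,),
        group_trajectories=((0.0,),),
        name="one_group_null",
    ),
}


def scenario_names() -> list[str]:
    return sorted(_REGISTRY)


def default_scenario(name: str, n_patients: int = 1798, seed: int = 0, **over) -> Scenario:
    """Look up a registered scenario, overriding any Scenario field via kwargs."""
    try:
        base = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known: {scenario_names()}"
        ) from None
    kw = dict(base)
    kw.update(over)
    return Scenario(n_patients=n_patients, seed=seed, **kw)


def save_scenario(scenario: Scenario, path) -> None:
    doc = dataclasses.asdict(scenario)
    doc["group_probs"] = [float(p) for p in scenario.group_probs]
    doc["group_trajectories"] = [list(map(float, b)) for b in scenario.group_trajectories]
    doc["covariate_spec"] = list(scenario.covariate_spec)
    if scenario.membership_coefs is not None:
        doc["membership_coefs"] = np.asarray(scenario.membership_coefs).tolist()
        doc["membership_covariates"] = list(scenario.membership_covariates)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    doc["group_probs"] = tuple(doc["group_probs"])
    doc["group_trajectories"] = tuple(tuple(b) for b in doc["group_trajectories"])
    doc["covariate_spec"] = tuple(doc.get("covariate_spec", tuple(DEFAULT_COVARIATE_SPEC)))
    if doc.get("membership_coefs") is not None:
        doc["membership_coefs"] = tuple(tuple(r) for r in doc["membership_coefs"])
        doc["membership_covariates"] = tuple(doc["membership_covariates"])
    return Scenario(**doc)
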