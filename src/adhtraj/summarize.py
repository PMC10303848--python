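"""Group-stratified descriptive statistics with ANOVA / chi-square tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["summarize_groups"]


def summarize_groups(covariates: pd.DataFrame, labels,
                     columns: list | None = None) -> pd.DataFrame:
    """Per-group means/SDs (continuous) or counts/percentages (categorical)
    plus one-way ANOVA or chi-square p-values.

    With a single group only descriptives are produced; constant columns are
    skipped for testing and flagged.
    """
    labels = np.asarray(labels)
    if len(labels) != len(covariates):
        raise ValueError("labels must align with covariates")
    if columns is None:
        columns = [c for c in covariates.columns if c != "patient_id"]
    groups = np.unique(labels)
    rows = []
    for col in columns:
        s = covariates[col]
        categorical = s.dtype == object or s.dropna().isin([0, 1]).all()
        row = {"covariate": col,
               "kind": "categorical" if categorical else "continuous"}
        skip = s.dropna().nunique() <= 1
        if categorical:
            for g in groups:
                sub = s[labels == g].dropna()
                if s.dtype == object:
                    row[f"g{g}"] = "; ".join(
                        f"{k}:{v}" for k, v in sub.value_counts().items())
                else:
                    n = int(sub.sum())
                    row[f"g{g}"] = f"{n} ({100 * n / max(len(sub), 1):.1f}%)"
            if len(groups) > 1 and not skip:
                tab = pd.crosstab(s, labels)
                row["p"] = stats.chi2_contingency(tab)[1]
        else:
            for g in groups:
                sub = s[labels == g].dropna().astype(float)
                row[f"g{g}"] = f"{sub.mean():.2f} ({sub.std(ddof=1):.2f})"
            if len(groups) > 1 and not skip:
                samples = [s[labels == g].dropna().astype(float) for g in groups]
                row["p"] = stats.f_oneway(*samples)[1]
        if skip:
            row["flag"] = "constant column; test skipped"
        elif len(groups) == 1:
            row["flag"] = "single group; test skipped"
        rows.append(row)
    counts = {"covariate": "n", "kind": "count"}
    for g in groups:
        counts[f"g{g}"] = str(int((labels == g).sum()))
    return pd.DataFrame([counts] + rows)
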