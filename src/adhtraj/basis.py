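"""Standardized month basis shared by the simulator and the trajectory model.

Months are 1-based. The design column is z = (month - mean) / sd where mean
and sd are the population moments of 1..n_months, so for 12 months
z = (month - 6.5) / 3.452... Polynomial designs use increasing powers of z.
"""

from __future__ import annotations

import numpy as np

__all__ = ["standardize_months", "month_design"]


def standardize_months(n_months: int) -> np.ndarray:
    """Return the standardized month values z_1..z_T (mean 0, unit variance)."""
    if n_months < 1:
        raise ValueError("n_months must be >= 1")
    if n_months == 1:  # degenerate: a single month sits at the basis origin
        return np.zeros(1)
    m = np.arange(1, n_months + 1, dtype=float)
    return (m - m.mean()) / m.std()


def month_design(n_months: int, order: int) -> np.ndarray:
    """T x (order+1) Vandermonde matrix of increasing powers of z."""
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    z = standardize_months(n_months)
    return np.vander(z, order + 1, increasing=True)
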