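"""Variant-discovery saturation: accumulation curves and power-law fits.

As samples are added in random orders, the cumulative number of distinct
variants (keyed by site + alternate allele, so a new allele at a known site
counts as a new variant) grows and eventually saturates.  The mean curve
over many random orders is summarized by a two-parameter power law
y = c·x^k fitted by nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["AccumulationCurve", "accumulation_curve", "PowerFit", "fit_power_series"]


@dataclass
class AccumulationCurve:
    """Cumulative distinct-variant counts over random sample orders."""

    n_samples: np.ndarray  # 1..N
    mean: np.ndarray  # mean cumulative count at each n
    sd: np.ndarray  # sd over orders
    per_order: np.ndarray  # (n_orders, N) cumulative counts
    new_mean: np.ndarray  # mean new variants contributed by the n-th sample

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_samples": self.n_samples,
                "cumulative_mean": self.mean,
                "cumulative_sd": self.sd,
                "new_per_sample_mean": self.new_mean,
            }
        )


def accumulation_curve(
    per_sample_variant_sets: Sequence[set],
    n_orders: int = 48,
    seed: int = 0,
) -> AccumulationCurve:
    """Accumulation curve over ``n_orders`` random sample-addition orders.

    For each random permutation of the samples, records the cumulative union
    size after each addition; reports mean and sd across permutations, and
    the first-difference series (new variants per added sample).
    """
    sets = [set(s) for s in per_sample_variant_sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    n = len(sets)
    per_order = np.zeros((n_orders, n), dtype=np.int64)
    for o in range(n_orders):
        perm = rng.permutation(n)
        seen: set = set()
        for idx, s in enumerate(perm):
            seen |= sets[s]
            per_order[o, idx] = len(seen)
    mean = per_order.mean(axis=0)
    sd = per_order.std(axis=0, ddof=0)
    new_mean = np.diff(mean, prepend=0.0)
    return AccumulationCurve(
        n_samples=np.arange(1, n + 1),
        mean=mean,
        sd=sd,
        per_order=per_order,
        new_mean=new_mean,
    )


@dataclass
class PowerFit:
    c: float
    k: float
    r_squared: float

    def predict(self, x) -> np.ndarray:
        return self.c * np.asarray(x, float) ** self.k


def fit_power_series(x, y) -> PowerFit:
    """Fit y = c·x^k by nonlinear least squares on the original scale.

    Initialized from the log–log linear regression; R² is computed on the
    original scale.  Requires ≥3 points, positive x and y.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("x and y must be positive")
    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    popt, _ = curve_fit(
        lambda xx, c, k: c * xx**k,
        x,
        y,
        p0=[float(np.exp(intercept)), float(slope)],
        maxfev=10_000,
    )
    c, k = float(popt[0]), float(popt[1])
    resid = y - c * x**k
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:  # constant y: perfect iff residuals vanish
        r2 = 1.0 if ss_res < 1e-12 else -np.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    return PowerFit(c=c, k=k, r_squared=r2)
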