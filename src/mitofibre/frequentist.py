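"""Pooled-control OLS classifier (the legacy frequentist pipeline).

All control fibres are combined into a single dataset, a simple linear
regression of log OXPHOS abundance on log mitochondrial mass is fitted, and a
patient fibre is called not-like-control (Z_j = 1) when its y value falls
outside the out-of-sample prediction interval of that line at its x value.
The per-subject fits produced by :func:`fit_ols` also feed prior elicitation
for the Bayesian model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import MitoDataset


class DegenerateFitError(ValueError):
    """x has no spread or the fit has zero residual variance."""


@dataclass(frozen=True)
class OlsFit:
    """Simple-regression fit summarised by its sufficient statistics.

    tau is the residual precision 1/s^2 with s^2 the unbiased residual
    variance (df = n - 2); x_bar and s_xx = sum (x - x_bar)^2 are retained so
    prediction intervals can be formed without the raw data.
    """

    m: float
    c: float
    tau: float
    n: int
    x_bar: float
    s_xx: float


@dataclass(frozen=True)
class PredictionInterval:
    lower: float
    upper: float
    level: float


def fit_ols(x, y) -> OlsFit:
    """Least-squares line y = m x + c with residual precision.

    Requires n >= 3 (one residual degree of freedom) and non-degenerate x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    x_bar = float(x.mean())
    s_xx = float(((x - x_bar) ** 2).sum())
    if s_xx <= 0:
        raise DegenerateFitError("x values are all equal (s_xx = 0)")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    c, m = res.params
    ssr = float(res.ssr)
    if ssr <= 1e-12 * max(1.0, float(y @ y)):
        raise DegenerateFitError("zero residual sum of squares (infinite precision)")
    tau = (n - 2) / ssr
    return OlsFit(m=float(m), c=float(c), tau=float(tau), n=n,
                  x_bar=x_bar, s_xx=s_xx)


def prediction_interval(fit: OlsFit, x0: float, level: float = 0.95) -> PredictionInterval:
    """t-based out-of-sample prediction interval at x0.

    Centered at m*x0 + c with half-width
    t_{n-2,(1+level)/2} * s * sqrt(1 + 1/n + (x0 - x_bar)^2 / s_xx).
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    s = 1.0 / np.sqrt(fit.tau)
    tq = stats.t.ppf((1 + level) / 2, df=fit.n - 2)
    centre = fit.m * x0 + fit.c
    half = tq * s * np.sqrt(1 + 1 / fit.n + (x0 - fit.x_bar) ** 2 / fit.s_xx)
    return PredictionInterval(lower=float(centre - half), upper=float(centre + half),
                              level=level)


def classify_frequentist(dataset: MitoDataset, level: float = 0.95):
    """Convenience wrapper: fit and classify in one call."""
    return FrequentistClassifier(dataset).fit(level=level)


class FrequentistClassifier:
    """Legacy classifier as a model object over one 2Dmito dataset."""

    def __init__(self, dataset: MitoDataset):
        if not dataset.logged:
            raise ValueError("dataset must be log-transformed before fitting")
        self.dataset = dataset

    def fit(self, level: float = 0.95) -> "FrequentistResults":
        x_pool = np.concatenate([s.x for s in self.dataset.controls])
        y_pool = np.concatenate([s.y for s in self.dataset.controls])
        pooled = fit_ols(x_pool, y_pool)

        pat = self.dataset.patient
        s = 1.0 / np.sqrt(pooled.tau)
        tq = stats.t.ppf((1 + level) / 2, df=pooled.n - 2)
        centre = pooled.m * pat.x + pooled.c
        half = tq * s * np.sqrt(
            1 + 1 / pooled.n + (pat.x - pooled.x_bar) ** 2 / pooled.s_xx
        )
        lower, upper = centre - half, centre + half
        z = ((pat.y < lower) | (pat.y > upper)).astype(int)
        side = np.where(pat.y > upper, "above", np.where(pat.y < lower, "below", "inside"))
        table = pd.DataFrame({
            "fibre_id": pat.fibre_ids,
            "x": pat.x,
            "y": pat.y,
            "lower": lower,
            "upper": upper,
            "z": z,
            "side": side,
        })
        return FrequentistResults(self, pooled, level, table)


class FrequentistResults:
    """Fitted pooled line plus per-fibre classifications for the patient."""

    def __init__(self, model: FrequentistClassifier, pooled_fit: OlsFit,
                 level: float, table: pd.DataFrame):
        self.model = model
        self.pooled_fit = pooled_fit
        self.level = level
        self.table = table

    @property
    def labels(self) -> np.ndarray:
        return self.table["z"].to_numpy()

    @property
    def proportion(self) -> float:
        """Fraction of patient fibres flagged not-like-control."""
        return float(self.labels.mean())

    def band(self, x_grid):
        """(lower, fitted, upper) of the prediction band on a grid."""
        x_grid = np.asarray(x_grid, dtype=float)
        f = self.pooled_fit
        s = 1.0 / np.sqrt(f.tau)
        tq = stats.t.ppf((1 + self.level) / 2, df=f.n - 2)
        centre = f.m * x_grid + f.c
        half = tq * s * np.sqrt(1 + 1 / f.n + (x_grid - f.x_bar) ** 2 / f.s_xx)
        return centre - half, centre, centre + half

    def summary(self) -> str:
        f = self.pooled_fit
        lines = [
            "Pooled-control OLS classifier",
            f"  controls pooled: n = {f.n}",
            f"  slope m = {f.m:.4f}, intercept c = {f.c:.4f}, "
            f"residual sd = {1 / np.sqrt(f.tau):.4f}",
            f"  prediction level = {self.level:.2f}",
            f"  patient fibres flagged not-like-control: "
            f"{int(self.labels.sum())} / {len(self.labels)} "
            f"({100 * self.proportion:.1f}%)",
        ]
        return "\n".join(lines)
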