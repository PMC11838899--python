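"""Posterior summaries: per-fibre classifications, HDIs, predictive bands,
and comparisons of the deficiency proportion against a reference estimate."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special


def hdi(samples, level: float, support=None):
    """Highest density interval: the shortest contiguous interval over the
    sorted samples containing ceil(level * n) points.

    If ``support`` (a (lower, upper) tuple for a parameter with bounded
    support) is given and the chosen window abuts an extreme order statistic,
    that endpoint is reported as the support bound: the sample extreme is a
    biased-inward estimate of an HDI endpoint that sits on the boundary
    (e.g. a posterior piling up at zero), and snapping to the bound is
    conservative.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    if not 0 < level <= 1:
        raise ValueError(f"level must be in (0, 1], got {level}")
    n_inc = min(int(math.ceil(level * n)), n)
    widths = x[n_inc - 1:] - x[:n - n_inc + 1]
    i = int(np.argmin(widths))
    lo, hi = float(x[i]), float(x[i + n_inc - 1])
    if support is not None:
        s_lo, s_hi = support
        if i == 0 and s_lo is not None and np.isfinite(s_lo):
            lo = float(s_lo)
        if i + n_inc == n and s_hi is not None and np.isfinite(s_hi):
            hi = float(s_hi)
    return lo, hi


@dataclass
class ClassificationResult:
    """Posterior-mean deficiency probabilities and binary labels.

    A fibre is like-control (label 0) when its expected marginal posterior
    probability of being not-like-control is below the threshold; a
    probability exactly at the threshold maps to label 1.
    """

    fibre_ids: np.ndarray
    probability: np.ndarray   # p_j, posterior mean membership per fibre
    label: np.ndarray         # 0 like-control, 1 not-like-control
    threshold: float
    pi_median: float
    pi_mean: float
    pi_hdi_95: tuple
    pi_hdi_99: tuple
    chain: int

    @property
    def proportion(self) -> float:
        return float(self.label.mean())

    def to_frame(self, x=None, y=None):
        import pandas as pd

        cols = {"fibre_id": self.fibre_ids}
        if x is not None:
            cols["x"] = x
        if y is not None:
            cols["y"] = y
        cols["probability"] = self.probability
        cols["label"] = self.label
        return pd.DataFrame(cols)

    def summary_json(self, **kw) -> str:
        return json.dumps({
            "threshold": self.threshold,
            "n_fibres": int(len(self.label)),
            "n_not_like_control": int(self.label.sum()),
            "proportion": self.proportion,
            "pi_median": self.pi_median,
            "pi_mean": self.pi_mean,
            "pi_hdi_95": list(self.pi_hdi_95),
            "pi_hdi_99": list(self.pi_hdi_99),
            "chain": self.chain,
        }, **kw)


def classify_bayes(results, threshold: float = 0.5) -> ClassificationResult:
    """Classify patient fibres from fitted results (selected chain).

    ``results`` is a HierarchicalMixtureResults (or anything exposing
    ``membership`` (draws x fibres), ``posterior['pi']`` and the patient
    ``fibre_ids`` via ``draws.fibre_ids``).
    """
    membership = np.asarray(results.membership, dtype=float)
    if membership.size == 0:
        raise ValueError("empty membership matrix")
    pi = np.asarray(results.posterior["pi"], dtype=float)
    prior = results.draws.prior
    support = (prior.pi_lower, prior.pi_upper)
    p_j = membership.mean(axis=0)
    labels = (p_j >= threshold).astype(int)
    fibre_ids = results.draws.fibre_ids
    if fibre_ids is None:
        fibre_ids = np.arange(membership.shape[1])
    return ClassificationResult(
        fibre_ids=np.asarray(fibre_ids),
        probability=p_j,
        label=labels,
        threshold=threshold,
        pi_median=float(np.median(pi)),
        pi_mean=float(pi.mean()),
        pi_hdi_95=hdi(pi, 0.95, support=support),
        pi_hdi_99=hdi(pi, 0.99, support=support),
        chain=getattr(results, "selected_chain", 0),
    )


def posterior_predictive_band(m_draws, c_draws, tau_draws, x_grid,
                              level: float = 0.95):
    """Posterior predictive band for a like-control fibre (component one).

    At each grid point the predictive distribution is the draw-mixture of
    N(m x + c, 1/tau); equal-tailed quantiles are found by root-finding on
    the mixture CDF, and the fitted value is the posterior mean of m x + c.
    Returns (lower, fitted, upper) arrays over the grid.
    """
    m = np.asarray(m_draws, dtype=float)
    c = np.asarray(c_draws, dtype=float)
    sd = 1.0 / np.sqrt(np.asarray(tau_draws, dtype=float))
    x_grid = np.atleast_1d(np.asarray(x_grid, dtype=float))
    alpha = (1 - level) / 2
    lower = np.empty_like(x_grid)
    upper = np.empty_like(x_grid)
    fitted = np.empty_like(x_grid)
    for gi, x0 in enumerate(x_grid):
        mu = m * x0 + c
        fitted[gi] = mu.mean()
        lo0 = float((mu - 10 * sd).min())
        hi0 = float((mu + 10 * sd).max())

        def cdf(yv):
            return float(special.ndtr((yv - mu) / sd).mean())

        lower[gi] = optimize.brentq(lambda yv: cdf(yv) - alpha, lo0, hi0,
                                    xtol=1e-10)
        upper[gi] = optimize.brentq(lambda yv: cdf(yv) - (1 - alpha), lo0, hi0,
                                    xtol=1e-10)
    return lower, fitted, upper


@dataclass
class PiComparison:
    """Posterior pi against a reference (frequentist or manual) proportion."""

    reference: float
    median: float
    hdi_95: tuple
    hdi_99: tuple
    difference_median: float
    difference_hdi_95: tuple
    difference_hdi_99: tuple
    tail_probability: float
    tail_is_upper_bound: bool  # True when no draw was as extreme (floor 1/n)
    n_draws: int

    def __str__(self):
        tp = (f"<= {self.tail_probability:.1e}" if self.tail_is_upper_bound
              else f"{self.tail_probability:.1e}")
        return (f"pi median {self.median:.4f}, 95% HDI "
                f"[{self.hdi_95[0]:.4f}, {self.hdi_95[1]:.4f}]; "
                f"difference vs reference {self.reference:.4f}: "
                f"median {self.difference_median:.4f}, "
                f"tail probability {tp}")


def summarize_pi(pi_draws, reference: float, support=(0.0, 0.5)) -> PiComparison:
    """Posterior summary of pi and its difference from a reference proportion.

    The tail probability is one-sided in the direction of the reference
    relative to the posterior median ("the reference value or more extreme");
    when no draw is as extreme it is reported as the resolution floor
    1/n_draws with ``tail_is_upper_bound`` set.
    """
    if not 0 <= reference <= 1:
        raise ValueError("reference proportion must be in [0, 1]")
    pi = np.asarray(pi_draws, dtype=float)
    n = len(pi)
    med = float(np.median(pi))
    diff = pi - reference
    diff_support = (None if support is None else
                    (support[0] - reference, support[1] - reference))
    if reference >= med:
        count = int((pi >= reference).sum())
    else:
        count = int((pi <= reference).sum())
    if count == 0:
        tail, is_bound = 1.0 / n, True
    else:
        tail, is_bound = count / n, False
    return PiComparison(
        reference=reference,
        median=med,
        hdi_95=hdi(pi, 0.95, support=support),
        hdi_99=hdi(pi, 0.99, support=support),
        difference_median=float(np.median(diff)),
        difference_hdi_95=hdi(diff, 0.95, support=diff_support),
        difference_hdi_99=hdi(diff, 0.99, support=diff_support),
        tail_probability=tail,
        tail_is_upper_bound=is_bound,
        n_draws=n,
    )
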