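"""Control-data-driven prior elicitation for the hierarchical mixture model.

The prior layer is

    mu_m ~ N(a_m, b_m)          b_m a VARIANCE (default 0.25^2)
    mu_c ~ N(a_c, b_c)
    tau   ~ Ga(g,  h)           shape/RATE parameterisation throughout
    tau_m ~ Ga(g_m, h_m)
    tau_c ~ Ga(g_c, h_c)
    pi    ~ Uniform(0, 0.5)
    m_i | mu_m, tau_m ~ TN(mu_m, 1/tau_m, slope_lower)   (left-truncated)
    c_i | mu_c, tau_c ~ N(mu_c, 1/tau_c)

a_m and a_c are the means of per-control-subject OLS slopes and intercepts;
(g, h) match the gamma prior MODE to the mean of the control residual
precisions with variance 10; (g_m, h_m) = (g_c, h_c) match mode 50,
variance 50, giving shape 51.981 and rate 1.020 to three decimals.  The
second mixture component's precision gamma is fixed, never inferred.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import special

from .frequentist import OlsFit


@dataclass(frozen=True)
class PriorSpec:
    """Every hyperparameter of the prior layer (gammas are shape/rate)."""

    am: float
    ac: float
    g: float
    h: float
    bm: float = 0.25 ** 2
    bc: float = 0.25 ** 2
    gm: float = 51.981
    hm: float = 1.020
    gc: float = 51.981
    hc: float = 1.020
    pi_lower: float = 0.0
    pi_upper: float = 0.5
    gamma_fixed: float = 1e-4
    slope_lower: float = 0.1

    def __post_init__(self):
        for name in ("bm", "bc", "g", "h", "gm", "hm", "gc", "hc", "gamma_fixed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.pi_lower < self.pi_upper <= 1:
            raise ValueError("need pi_lower < pi_upper <= 1")
        tau_mode = max(self.g - 1, 0.0) / self.h
        if tau_mode > 0 and self.gamma_fixed / tau_mode > 1e-2:
            warnings.warn(
                "gamma_fixed is not small relative to the tau prior mode; the "
                "outlier component may overlap the like-control component",
                stacklevel=2,
            )

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), **kw)

    @classmethod
    def from_json(cls, s: str) -> "PriorSpec":
        return cls(**json.loads(s))


def solve_gamma_mode_var(mode: float, variance: float):
    """Shape/rate of the gamma distribution with the given mode and variance.

    Solves (g - 1)/h = mode and g/h^2 = variance: h is the positive root of
    variance*h^2 - mode*h - 1 = 0 and g = mode*h + 1.
    """
    if mode <= 0 or variance <= 0:
        raise ValueError("mode and variance must be positive")
    h = (mode + math.sqrt(mode ** 2 + 4 * variance)) / (2 * variance)
    g = mode * h + 1
    return g, h


def build_priors(control_fits, *, bm: float | None = None, bc: float | None = None,
                 tau_variance: float = 10.0,
                 pop_precision_mode: float = 50.0,
                 pop_precision_variance: float = 50.0,
                 gamma_fixed: float = 1e-4,
                 slope_lower: float = 0.1,
                 pi_upper: float = 0.5) -> PriorSpec:
    """Elicit the full prior from per-control-subject OLS fits.

    The means of the control slopes, intercepts and residual precisions set
    the prior expectations of mu_m, mu_c and the mode of tau respectively.
    """
    fits = list(control_fits)
    if not fits:
        raise ValueError("need at least one control fit")
    if len(fits) == 1:
        warnings.warn("prior built from a single control fit", stacklevel=2)
    for f in fits:
        if not isinstance(f, OlsFit):
            raise TypeError("control_fits must be OlsFit instances")
    # fsum: exactly-rounded sums, so the result is permutation invariant
    am = math.fsum(f.m for f in fits) / len(fits)
    ac = math.fsum(f.c for f in fits) / len(fits)
    tau_mean = math.fsum(f.tau for f in fits) / len(fits)
    g, h = solve_gamma_mode_var(tau_mean, tau_variance)
    gm, hm = solve_gamma_mode_var(pop_precision_mode, pop_precision_variance)
    kw = {}
    if bm is not None:
        kw["bm"] = bm
    if bc is not None:
        kw["bc"] = bc
    return PriorSpec(am=am, ac=ac, g=g, h=h, gm=gm, hm=hm, gc=gm, hc=hm,
                     gamma_fixed=gamma_fixed, slope_lower=slope_lower,
                     pi_upper=pi_upper, **kw)


def scale_prior_variances(spec: PriorSpec, factor: float) -> PriorSpec:
    """Inflate (factor > 1) or deflate the prior variances, keeping every
    prior mean (normals) and mode (gammas) fixed — the sensitivity-analysis
    perturbation."""
    if factor <= 0:
        raise ValueError("factor must be positive")

    def rescale_gamma(g, h):
        mode = (g - 1) / h
        var = g / h ** 2
        return solve_gamma_mode_var(mode, var * factor)

    g, h = rescale_gamma(spec.g, spec.h)
    gm, hm = rescale_gamma(spec.gm, spec.hm)
    gc, hc = rescale_gamma(spec.gc, spec.hc)
    return replace(spec, bm=spec.bm * factor, bc=spec.bc * factor,
                   g=g, h=h, gm=gm, hm=hm, gc=gc, hc=hc)


def _truncnorm_rvs(mean, sd, lower, rng, size=None):
    """Left-truncated normal draws by inverse CDF (stable in both tails)."""
    alpha = (lower - np.asarray(mean)) / sd
    tail = special.ndtr(-alpha)  # P(X > lower)
    u = rng.uniform(size=size if size is not None else np.shape(alpha))
    u = np.clip(u, 1e-15, 1 - 1e-15)
    return mean - sd * special.ndtri((1 - u) * tail)


def sample_prior(spec: PriorSpec, n: int, seed: int, k: int = 2) -> dict:
    """n independent draws from the prior layer, including implied per-subject
    slopes/intercepts (k subjects), for prior-vs-posterior overlays and
    sensitivity runs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu_m = rng.normal(spec.am, math.sqrt(spec.bm), size=n)
    mu_c = rng.normal(spec.ac, math.sqrt(spec.bc), size=n)
    tau_m = rng.gamma(spec.gm, 1 / spec.hm, size=n)
    tau_c = rng.gamma(spec.gc, 1 / spec.hc, size=n)
    tau = rng.gamma(spec.g, 1 / spec.h, size=n)
    pi = rng.uniform(spec.pi_lower, spec.pi_upper, size=n)
    m = _truncnorm_rvs(mu_m[:, None], 1 / np.sqrt(tau_m)[:, None],
                       spec.slope_lower, rng, size=(n, k))
    c = rng.normal(mu_c[:, None], 1 / np.sqrt(tau_c)[:, None], size=(n, k))
    return {"mu_m": mu_m, "mu_c": mu_c, "tau_m": tau_m, "tau_c": tau_c,
            "tau": tau, "pi": pi, "m": m, "c": c}
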