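"""Bayesian hierarchical two-component mixture model for one 2Dmito plot.

Subjects i = 1..k-1 are controls, k is the patient.  Control fibres follow

    Y_ij | m_i, c_i, tau ~ N(m_i X_ij + c_i, 1/tau)

and patient fibres a two-component mixture sharing the patient's line,

    Y_kj ~ (1 - pi) N(m_k X_kj + c_k, 1/tau) + pi N(m_k X_kj + c_k, 1/gamma),

where gamma is a fixed, very small precision: the second component is a broad
catch-all for fibres inconsistent with the like-control relationship, and
fixing its precision removes label switching.  Slopes and intercepts get a
hierarchical prior (slopes left-truncated at a positive bound, since OXPHOS
abundance rises with mitochondrial mass).  The latent per-fibre membership
Z_j ~ Bern(pi) gives, per posterior draw, the probability that a patient
fibre is not-like-control.

Inference is by a Z-augmented Gibbs sampler.  All full conditionals are
conjugate; the mu_m and tau_m updates carry an exact Metropolis correction
for the truncated-normal slope prior's normalizing constant (the acceptance
ratio is the ratio of truncation constants, which is ~1 whenever the
truncation point is far in the prior's lower tail, so the sampler remains an
exact scheme at negligible cost).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .data import MitoDataset
from .frequentist import fit_ols
from .priors import PriorSpec, build_priors, _truncnorm_rvs

_LOG_2PI = math.log(2 * math.pi)


class InitializationError(RuntimeError):
    """The log posterior is non-finite at the initial state."""


class ConvergenceError(RuntimeError):
    """Every chain was flagged as non-convergent."""


@dataclass
class ModelParams:
    """One point in parameter space (m and c are length-k arrays)."""

    m: np.ndarray
    c: np.ndarray
    tau: float
    mu_m: float
    mu_c: float
    tau_m: float
    tau_c: float
    pi: float


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 3
    iterations: int = 22_000
    burn_in: int = 20_000
    seed: int = 0

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")


@dataclass
class ChainDraws:
    """Post-burn-in draws of one chain plus per-fibre membership probabilities."""

    params: dict  # name -> array (n_draws,) or (n_draws, k)
    membership: np.ndarray  # (n_draws, n_patient)
    seed: int
    accept_mu_m: float
    accept_tau_m: float

    @property
    def n_draws(self) -> int:
        return len(self.params["pi"])

    def scalar_params(self) -> dict:
        """Flatten vector parameters into named scalar series (m[0], c[0], ...)."""
        out = {}
        for name, arr in self.params.items():
            if arr.ndim == 1:
                out[name] = arr
            else:
                for j in range(arr.shape[1]):
                    out[f"{name}[{j}]"] = arr[:, j]
        return out


@dataclass
class PosteriorDraws:
    chains: list  # list[ChainDraws]
    config: McmcConfig
    prior: PriorSpec
    fibre_ids: np.ndarray = field(default=None)

    def to_frame(self):
        """Long table (chain, draw, parameter, value) for serialisation."""
        import pandas as pd

        frames = []
        for ci, ch in enumerate(self.chains):
            for name, arr in ch.scalar_params().items():
                frames.append(pd.DataFrame({
                    "chain": ci, "draw": np.arange(len(arr)),
                    "parameter": name, "value": arr,
                }))
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Density evaluation


def _norm_logpdf_prec(resid, tau):
    return 0.5 * (np.log(tau) - _LOG_2PI) - 0.5 * tau * resid ** 2


def _gamma_logpdf(x, shape, rate):
    if x <= 0:
        return -np.inf
    return (shape * math.log(rate) - special.gammaln(shape)
            + (shape - 1) * math.log(x) - rate * x)


def membership_probability(y, x, m_k, c_k, tau, gamma, pi):
    """P(Z_j = 1 | y, x, params): posterior probability that a patient fibre
    belongs to the broad (not-like-control) component.  Log-space throughout;
    exact 0/1 at the degenerate mixture weights."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if pi <= 0:
        return np.zeros_like(y) if y.ndim else 0.0
    if pi >= 1:
        return np.ones_like(y) if y.ndim else 1.0
    resid = y - (m_k * x + c_k)
    log1 = math.log(pi) + _norm_logpdf_prec(resid, gamma)
    log0 = math.log1p(-pi) + _norm_logpdf_prec(resid, tau)
    p = special.expit(log1 - log0)
    return p if y.ndim else float(p)


def log_unnormalized_posterior(params: ModelParams, data: MitoDataset,
                               prior: PriorSpec) -> float:
    """Log posterior kernel with the patient memberships Z marginalised.

    Returns -inf off the support (non-positive precisions, slopes below the
    truncation bound, pi outside its prior interval).  Includes the
    truncated-normal normalizing constants, so the value is exact up to the
    single data-independent constant dropped from the uniform pi prior's
    normalisation of the posterior itself.
    """
    p, k = params, data.k
    if (p.tau <= 0 or p.tau_m <= 0 or p.tau_c <= 0
            or not prior.pi_lower <= p.pi <= prior.pi_upper
            or np.any(p.m < prior.slope_lower)):
        return -np.inf

    total = 0.0
    for i, s in enumerate(data.controls):
        resid = s.y - (p.m[i] * s.x + p.c[i])
        total += _norm_logpdf_prec(resid, p.tau).sum()

    pat = data.patient
    resid = pat.y - (p.m[k - 1] * pat.x + p.c[k - 1])
    log0 = math.log1p(-p.pi) + _norm_logpdf_prec(resid, p.tau) if p.pi < 1 else None
    log1 = math.log(p.pi) + _norm_logpdf_prec(resid, prior.gamma_fixed) if p.pi > 0 else None
    if log0 is None:
        total += log1.sum()
    elif log1 is None:
        total += log0.sum()
    else:
        total += np.logaddexp(log0, log1).sum()

    # slope prior: left-truncated normal including its normalizing constant
    sd_m = 1.0 / math.sqrt(p.tau_m)
    log_z = special.log_ndtr((p.mu_m - prior.slope_lower) / sd_m)
    total += (_norm_logpdf_prec(p.m - p.mu_m, p.tau_m) - log_z).sum()
    total += _norm_logpdf_prec(p.c - p.mu_c, p.tau_c).sum()

    total += float(_norm_logpdf_prec(p.mu_m - prior.am, 1.0 / prior.bm))
    total += float(_norm_logpdf_prec(p.mu_c - prior.ac, 1.0 / prior.bc))
    total += _gamma_logpdf(p.tau, prior.g, prior.h)
    total += _gamma_logpdf(p.tau_m, prior.gm, prior.hm)
    total += _gamma_logpdf(p.tau_c, prior.gc, prior.hc)
    total += -math.log(prior.pi_upper - prior.pi_lower)
    return float(total)


# ---------------------------------------------------------------------------
# Gibbs sampler


def _subject_stats(s):
    return {
        "n": s.n, "sx": float(s.x.sum()), "sy": float(s.y.sum()),
        "sxx": float((s.x ** 2).sum()), "syy": float((s.y ** 2).sum()),
        "sxy": float((s.x * s.y).sum()),
    }


def _initial_state(data: MitoDataset, prior: PriorSpec) -> ModelParams:
    """OLS-anchored start: per-subject lines, pooled-control residual
    precision, hyperparameters at their prior centres.  tau is the
    within-subject like-control precision, so it starts at its prior mode —
    the mean of the per-control-subject OLS precisions under the elicitation
    pipeline.  (A pooled fit would start tau too low whenever subjects'
    lines differ, or whenever the patient has many deficient fibres, and a
    too-dispersed component one can absorb the whole mixture and trap the
    chain in a degenerate mode.)"""
    k = data.k
    m = np.empty(k)
    c = np.empty(k)
    x_all = np.concatenate([s.x for s in data.controls])
    y_all = np.concatenate([s.y for s in data.controls])
    pooled = fit_ols(x_all, y_all)
    tau0 = (prior.g - 1) / prior.h if prior.g > 1 else pooled.tau
    for i, s in enumerate(data.subjects):
        try:
            f = fit_ols(s.x, s.y)
            m[i], c[i] = f.m, f.c
        except ValueError:
            m[i], c[i] = pooled.m, pooled.c
    m = np.maximum(m, prior.slope_lower + 1e-6)
    return ModelParams(
        m=m, c=c, tau=tau0,
        mu_m=prior.am, mu_c=prior.ac,
        tau_m=max(prior.gm - 1, 0.5) / prior.hm,
        tau_c=max(prior.gc - 1, 0.5) / prior.hc,
        pi=0.1,
    )


def _truncated_beta_rvs(a, b, lower, upper, rng):
    f_lo = special.betainc(a, b, lower)
    f_hi = special.betainc(a, b, upper)
    u = rng.uniform(f_lo, f_hi)
    u = min(max(u, 1e-15), 1 - 1e-15)
    return float(special.betaincinv(a, b, u))


def _run_chain(data: MitoDataset, prior: PriorSpec, iterations: int,
               burn_in: int, seed: int):
    rng = np.random.default_rng(seed)
    k = data.k
    ctrl = [_subject_stats(s) for s in data.controls]
    pat = data.patient
    x_p, y_p, n_p = pat.x, pat.y, pat.n
    lower = prior.slope_lower
    gamma = prior.gamma_fixed
    n_ctrl_total = sum(st["n"] for st in ctrl)

    state = _initial_state(data, prior)
    if not np.isfinite(log_unnormalized_posterior(state, data, prior)):
        raise InitializationError(
            f"non-finite log posterior at initial state: {state}")
    m, c = state.m.copy(), state.c.copy()
    tau, mu_m, mu_c = state.tau, state.mu_m, state.mu_c
    tau_m, tau_c, pi = state.tau_m, state.tau_c, state.pi
    # initialise memberships from the starting parameters
    p_z = membership_probability(y_p, x_p, m[-1], c[-1], tau, gamma, pi)
    z = rng.uniform(size=n_p) < p_z

    n_keep = iterations - burn_in
    out = {
        "m": np.empty((n_keep, k)), "c": np.empty((n_keep, k)),
        "tau": np.empty(n_keep), "mu_m": np.empty(n_keep),
        "mu_c": np.empty(n_keep), "tau_m": np.empty(n_keep),
        "tau_c": np.empty(n_keep), "pi": np.empty(n_keep),
    }
    acc_mu = acc_tau = 0

    def log_trunc_const(mu, prec):
        return float(special.log_ndtr((mu - lower) * math.sqrt(prec)))

    def draw_line_block(swxx, swx, sw, swxy, swy):
        """Blocked (m, c) draw: the joint full conditional is bivariate
        normal truncated in m; sample m from its (truncated) marginal, then
        c | m.  Removes the slow one-at-a-time m-c random walk."""
        p00 = tau_m + swxx
        p11 = tau_c + sw
        p01 = swx
        b0 = tau_m * mu_m + swxy
        b1 = tau_c * mu_c + swy
        det = p00 * p11 - p01 * p01
        mean_m = (b0 * p11 - b1 * p01) / det
        var_m = p11 / det
        m_new = _truncnorm_rvs(mean_m, math.sqrt(var_m), lower, rng)
        mean_c = (b1 - p01 * m_new) / p11
        c_new = rng.normal(mean_c, 1 / math.sqrt(p11))
        return float(m_new), float(c_new)

    for it in range(iterations):
        # --- control slopes/intercepts
        for i, st in enumerate(ctrl):
            m[i], c[i] = draw_line_block(
                tau * st["sxx"], tau * st["sx"], tau * st["n"],
                tau * st["sxy"], tau * st["sy"])

        # --- patient line under per-fibre precisions lambda_j
        lam = np.where(z, gamma, tau)
        m[-1], c[-1] = draw_line_block(
            float((lam * x_p ** 2).sum()), float((lam * x_p).sum()),
            float(lam.sum()), float((lam * x_p * y_p).sum()),
            float((lam * y_p).sum()))

        # --- shared like-control precision tau
        ssr = 0.0
        for i, st in enumerate(ctrl):
            ssr += (st["syy"] + m[i] ** 2 * st["sxx"] + st["n"] * c[i] ** 2
                    - 2 * m[i] * st["sxy"] - 2 * c[i] * st["sy"]
                    + 2 * m[i] * c[i] * st["sx"])
        resid_p = y_p - (m[-1] * x_p + c[-1])
        like = ~z
        ssr += float((resid_p[like] ** 2).sum())
        n_eff = n_ctrl_total + int(like.sum())
        tau = rng.gamma(prior.g + 0.5 * n_eff, 1.0 / (prior.h + 0.5 * ssr))

        # --- mu_m: conjugate proposal + exact truncation-constant correction
        prec0 = 1.0 / prior.bm + k * tau_m
        mean0 = (prior.am / prior.bm + tau_m * m.sum()) / prec0
        prop = rng.normal(mean0, 1 / math.sqrt(prec0))
        log_a = k * (log_trunc_const(mu_m, tau_m) - log_trunc_const(prop, tau_m))
        if math.log(rng.uniform()) < log_a:
            mu_m = prop
            acc_mu += 1

        # --- tau_m: conjugate gamma proposal + same correction
        rate = prior.hm + 0.5 * float(((m - mu_m) ** 2).sum())
        prop = rng.gamma(prior.gm + 0.5 * k, 1.0 / rate)
        log_a = k * (log_trunc_const(mu_m, tau_m) - log_trunc_const(mu_m, prop))
        if math.log(rng.uniform()) < log_a:
            tau_m = prop
            acc_tau += 1

        # --- mu_c, tau_c (fully conjugate)
        prec0 = 1.0 / prior.bc + k * tau_c
        mean0 = (prior.ac / prior.bc + tau_c * c.sum()) / prec0
        mu_c = rng.normal(mean0, 1 / math.sqrt(prec0))
        rate = prior.hc + 0.5 * float(((c - mu_c) ** 2).sum())
        tau_c = rng.gamma(prior.gc + 0.5 * k, 1.0 / rate)

        # --- memberships and mixture weight
        p_z = membership_probability(y_p, x_p, m[-1], c[-1], tau, gamma, pi)
        z = rng.uniform(size=n_p) < p_z
        n1 = int(z.sum())
        pi = _truncated_beta_rvs(1 + n1, 1 + n_p - n1, prior.pi_lower,
                                 prior.pi_upper, rng)

        if it >= burn_in:
            j = it - burn_in
            out["m"][j] = m
            out["c"][j] = c
            out["tau"][j] = tau
            out["mu_m"][j] = mu_m
            out["mu_c"][j] = mu_c
            out["tau_m"][j] = tau_m
            out["tau_c"][j] = tau_c
            out["pi"][j] = pi

    # per-draw membership probabilities for every patient fibre (Bayes rule
    # at each retained draw, vectorised draws x fibres)
    resid = y_p[None, :] - (out["m"][:, -1][:, None] * x_p[None, :]
                            + out["c"][:, -1][:, None])
    log1 = (np.log(out["pi"])[:, None]
            + _norm_logpdf_prec(resid, gamma))
    log0 = (np.log1p(-out["pi"])[:, None]
            + 0.5 * (np.log(out["tau"])[:, None] - _LOG_2PI)
            - 0.5 * out["tau"][:, None] * resid ** 2)
    membership = special.expit(log1 - log0)

    return ChainDraws(params=out, membership=membership, seed=seed,
                      accept_mu_m=acc_mu / iterations,
                      accept_tau_m=acc_tau / iterations)


def fit_model(data: MitoDataset, prior: PriorSpec,
              mcmc: McmcConfig) -> PosteriorDraws:
    """Run the Gibbs sampler (one or more chains) on one 2Dmito dataset."""
    if data.patient.n < 5:
        warnings.warn("patient has fewer than 5 fibres; the mixture weight is "
                      "weakly identified", stacklevel=2)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)]
    chains = [_run_chain(data, prior, mcmc.iterations, mcmc.burn_in, s)
              for s in seeds]
    return PosteriorDraws(chains=chains, config=mcmc, prior=prior,
                          fibre_ids=data.patient.fibre_ids)


# ---------------------------------------------------------------------------
# Model / Results objects


class HierarchicalMixtureModel:
    """Hierarchical mixture classifier over one log-transformed 2Dmito dataset.

    If ``prior`` is omitted it is elicited from per-control-subject OLS fits
    (the control-data-driven pipeline).
    """

    def __init__(self, dataset: MitoDataset, prior: PriorSpec | None = None):
        if not dataset.logged:
            raise ValueError("dataset must be log-transformed before fitting")
        self.dataset = dataset
        if prior is None:
            fits = [fit_ols(s.x, s.y) for s in dataset.controls]
            prior = build_priors(fits)
        self.prior = prior

    @classmethod
    def from_dataframe(cls, df, mass_channel: str, oxphos_channel: str,
                       patient_id: str, prior: PriorSpec | None = None):
        """Build from a long-format DataFrame of raw intensities."""
        import io

        from .data import load_dataset, log_transform

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        raw, _ = load_dataset(buf, mass_channel, oxphos_channel, patient_id)
        logged, _ = log_transform(raw)
        return cls(logged, prior=prior)

    def fit(self, chains: int = 3, iterations: int = 22_000,
            burn_in: int = 20_000, seed: int = 0) -> "HierarchicalMixtureResults":
        cfg = McmcConfig(chains=chains, iterations=iterations,
                         burn_in=burn_in, seed=seed)
        draws = fit_model(self.dataset, self.prior, cfg)
        from .diagnostics import diagnose_chains

        diag = diagnose_chains(draws)
        return HierarchicalMixtureResults(self, draws, diag)


class HierarchicalMixtureResults:
    """Posterior draws, diagnostics, and the classification outputs.

    Inference is based on the selected chain: among chains not flagged by the
    convergence diagnostics, the one with the highest minimum per-parameter
    effective sample size.
    """

    def __init__(self, model, draws: PosteriorDraws, diagnostics):
        self.model = model
        self.draws = draws
        self.diagnostics = diagnostics
        self.selected_chain = diagnostics.selected_chain

    @property
    def chain(self) -> ChainDraws:
        return self.draws.chains[self.selected_chain]

    @property
    def posterior(self) -> dict:
        return self.chain.params

    @property
    def membership(self) -> np.ndarray:
        return self.chain.membership

    def classification(self, threshold: float = 0.5):
        from .posterior import classify_bayes

        return classify_bayes(self, threshold=threshold)

    def pi_summary(self, reference: float):
        from .posterior import summarize_pi

        prior = self.draws.prior
        return summarize_pi(self.posterior["pi"], reference,
                            support=(prior.pi_lower, prior.pi_upper))

    def predictive_band(self, x_grid, level: float = 0.95):
        from .posterior import posterior_predictive_band

        p = self.posterior
        return posterior_predictive_band(p["m"][:, -1], p["c"][:, -1],
                                         p["tau"], x_grid, level=level)

    def summary(self):
        """Posterior summary table (mean, sd, 95% HDI, ESS, split R-hat)."""
        import pandas as pd

        from .posterior import hdi

        rows = []
        diag = self.diagnostics
        for name, arr in self.chain.scalar_params().items():
            lo, hi = hdi(arr, 0.95)
            rows.append({
                "parameter": name,
                "mean": arr.mean(), "sd": arr.std(ddof=1),
                "hdi_2.5%": lo, "hdi_97.5%": hi,
                "ess": diag.ess[self.selected_chain].get(name, np.nan),
                "r_hat": diag.r_hat[self.selected_chain].get(name, np.nan),
            })
        return pd.DataFrame(rows).set_index("parameter")
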