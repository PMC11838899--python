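"""Ground-truth-labelled synthetic 2Dmito datasets.

The generator emulates the structure of the observed IMC data: a handful of
control subjects and one patient, each with per-subject linear relationships
between log OXPHOS abundance and log mitochondrial mass, plus a minority
patient subpopulation whose abundance sits below the like-control line
(negative intercept shift) with higher variance.  Mitochondrial mass is
log-normal, i.e. the log-mass covariate X is normal with a per-subject
location and scale.  The default deficient component sits two natural-log
units below the like-control line with residual sd 0.5 (vs 0.2 for
like-control fibres): a separate under-expressing population, as seen in
observed 2Dmito plots.  Ground-truth parameters are drawn from the model
prior or fixed explicitly; every dataset is bitwise reproducible from
(truth, sizes, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np

from .data import MitoDataset, SubjectBlock, CONTROL, PATIENT
from .priors import PriorSpec, _truncnorm_rvs

# observed per-section fibre counts: controls 154-363, patients 151-1,199
CONTROL_N_RANGE = (154, 363)
PATIENT_N_RANGE = (151, 1199)

_DEFAULTS = dict(mu_m=1.0, mu_c=0.0, tau_m=50.0, tau_c=50.0, tau=25.0,
                 pi=0.1, delta=-2.0, tau_def=4.0)


@dataclass(frozen=True)
class GroundTruth:
    """True parameters behind one synthetic 2Dmito dataset (patient last)."""

    k: int
    m: np.ndarray            # per-subject slopes, >= slope_lower
    c: np.ndarray            # per-subject intercepts
    tau: float               # shared like-control precision
    pi: float                # deficiency proportion in [0, 0.5]
    mu_m: float
    mu_c: float
    tau_m: float
    tau_c: float
    delta: float             # deficient-component intercept shift (< 0, log units)
    tau_def: float           # deficient-component precision (< tau)
    x_loc: np.ndarray        # per-subject log-mass location
    x_scale: np.ndarray      # per-subject log-mass scale
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "m", np.asarray(self.m, dtype=float))
        object.__setattr__(self, "c", np.asarray(self.c, dtype=float))
        object.__setattr__(self, "x_loc", np.asarray(self.x_loc, dtype=float))
        object.__setattr__(self, "x_scale", np.asarray(self.x_scale, dtype=float))
        if not (len(self.m) == len(self.c) == len(self.x_loc)
                == len(self.x_scale) == self.k):
            raise ValueError("per-subject arrays must have length k")
        if not 0 <= self.pi <= 0.5:
            raise ValueError("pi must be in [0, 0.5]")
        if self.delta >= 0:
            raise ValueError("deficient-component shift delta must be negative")
        if self.tau_def >= self.tau:
            raise ValueError("deficient component must have lower precision "
                             "(tau_def < tau)")

    def to_json(self, **kw) -> str:
        d = asdict(self)
        for key in ("m", "c", "x_loc", "x_scale"):
            d[key] = list(d[key])
        return json.dumps(d, **kw)

    @classmethod
    def from_json(cls, s: str) -> "GroundTruth":
        return cls(**json.loads(s))


def sample_ground_truth(prior=None, seed: int = 0, k: int = 5,
                        slope_lower: float = 0.1, **overrides) -> GroundTruth:
    """Draw (or fix) the true parameters for one synthetic dataset.

    ``prior`` may be a :class:`PriorSpec`, in which case the population
    parameters and pi are drawn from it and per-subject lines from the
    hierarchy, or ``None``, in which case realistic fixed defaults are used
    (slopes near 1, residual sd 0.2, deficient component one log-unit below
    with sd 1).  Keyword overrides are echoed into the truth verbatim, e.g.
    ``pi=0.25`` or explicit ``m=[...]`` arrays.
    """
    rng = np.random.default_rng(seed)
    vals = dict(_DEFAULTS)
    if isinstance(prior, PriorSpec):
        vals["mu_m"] = rng.normal(prior.am, np.sqrt(prior.bm))
        vals["mu_c"] = rng.normal(prior.ac, np.sqrt(prior.bc))
        vals["tau_m"] = rng.gamma(prior.gm, 1 / prior.hm)
        vals["tau_c"] = rng.gamma(prior.gc, 1 / prior.hc)
        vals["tau"] = rng.gamma(prior.g, 1 / prior.h)
        vals["pi"] = rng.uniform(prior.pi_lower, prior.pi_upper)
        slope_lower = prior.slope_lower
        if "tau_def" not in overrides:
            # keep the deficient component noisier than whatever tau was drawn
            vals["tau_def"] = vals["tau"] / 6.0
    for key in _DEFAULTS:
        if key in overrides:
            vals[key] = overrides.pop(key)
    x_loc = np.asarray(overrides.pop("x_loc", np.full(k, 2.0)), dtype=float)
    x_scale = np.asarray(overrides.pop("x_scale", np.full(k, 0.5)), dtype=float)
    if x_loc.ndim == 0:
        x_loc = np.full(k, float(x_loc))
    if x_scale.ndim == 0:
        x_scale = np.full(k, float(x_scale))
    if "m" in overrides:
        m = np.asarray(overrides.pop("m"), dtype=float)
    else:
        m = _truncnorm_rvs(np.full(k, vals["mu_m"]),
                           1 / np.sqrt(vals["tau_m"]), slope_lower, rng)
    if "c" in overrides:
        c = np.asarray(overrides.pop("c"), dtype=float)
    else:
        c = rng.normal(vals["mu_c"], 1 / np.sqrt(vals["tau_c"]), size=k)
    if overrides:
        raise TypeError(f"unknown ground-truth fields: {sorted(overrides)}")
    return GroundTruth(k=k, m=m, c=c, tau=vals["tau"], pi=vals["pi"],
                       mu_m=vals["mu_m"], mu_c=vals["mu_c"],
                       tau_m=vals["tau_m"], tau_c=vals["tau_c"],
                       delta=vals["delta"], tau_def=vals["tau_def"],
                       x_loc=x_loc, x_scale=x_scale, seed=seed)


def generate_dataset(truth: GroundTruth, n_per_subject=None, seed: int = 0,
                     mass_channel: str = "VDAC",
                     oxphos_channel: str = "NDUFB8"):
    """Simulate one log-scale 2Dmito dataset plus true patient labels.

    Control fibres come from the like-control line with precision tau;
    patient fibres are labelled Z_j ~ Bern(pi), like-control fibres sampled
    from component one, deficient fibres from the shifted, noisier line
    N(m_k x + c_k + delta, 1/tau_def).  When ``n_per_subject`` is omitted,
    per-subject sizes are drawn from the observed ranges (controls 154-363,
    patient 151-1,199).
    """
    rng = np.random.default_rng(seed)
    k = truth.k
    if n_per_subject is None:
        n_per_subject = np.r_[
            rng.integers(CONTROL_N_RANGE[0], CONTROL_N_RANGE[1] + 1, size=k - 1),
            rng.integers(PATIENT_N_RANGE[0], PATIENT_N_RANGE[1] + 1),
        ]
    n_per_subject = np.asarray(n_per_subject, dtype=int)
    if len(n_per_subject) != k:
        raise ValueError("n_per_subject must have length k")

    blocks = []
    labels = None
    for i in range(k):
        n = int(n_per_subject[i])
        is_patient = i == k - 1
        x = rng.normal(truth.x_loc[i], truth.x_scale[i], size=n)
        line = truth.m[i] * x + truth.c[i]
        if is_patient:
            z = rng.uniform(size=n) < truth.pi
            y = np.where(
                z,
                rng.normal(line + truth.delta, 1 / np.sqrt(truth.tau_def)),
                rng.normal(line, 1 / np.sqrt(truth.tau)),
            )
            labels = z.astype(int)
            sid, stype = "P01", PATIENT
        else:
            y = rng.normal(line, 1 / np.sqrt(truth.tau))
            sid, stype = f"C{i + 1:02d}", CONTROL
        fibre_ids = np.array([f"{sid}_F{j:04d}" for j in range(n)])
        blocks.append(SubjectBlock(sid, stype, fibre_ids, x, y))
    dataset = MitoDataset(mass_channel, oxphos_channel, blocks, logged=True)
    return dataset, labels


def make_d02_variant(truth: GroundTruth, scale: float = 1.0, shift: float = 0.0,
                     subject_sd_factor: float = 1.0,
                     seed: int | None = None) -> GroundTruth:
    """IF-like variant: linearly transform the log-mass distribution
    (x -> scale*x + shift, giving larger abundances) and widen inter-subject
    spread by ``subject_sd_factor`` (population precisions divided by its
    square, per-subject lines re-drawn).  The identity transform returns the
    truth unchanged."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if subject_sd_factor < 1:
        raise ValueError("subject_sd_factor must be >= 1")
    out = replace(truth,
                  x_loc=scale * truth.x_loc + shift,
                  x_scale=scale * truth.x_scale)
    if subject_sd_factor != 1.0:
        tau_m = truth.tau_m / subject_sd_factor ** 2
        tau_c = truth.tau_c / subject_sd_factor ** 2
        rng = np.random.default_rng(truth.seed if seed is None else seed)
        m = _truncnorm_rvs(np.full(truth.k, truth.mu_m),
                           1 / np.sqrt(tau_m), 0.1, rng)
        c = rng.normal(truth.mu_c, 1 / np.sqrt(tau_c), size=truth.k)
        out = replace(out, tau_m=tau_m, tau_c=tau_c, m=m, c=c)
    return out


def write_synthetic(dataset: MitoDataset, labels, truth: GroundTruth,
                    out_dir, stem: str = "synthetic") -> dict:
    """Write the raw-scale long CSV, the patient-label CSV and the truth JSON."""
    import pathlib

    import pandas as pd

    from .data import exp_transform

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "data": out_dir / f"{stem}_data.csv",
        "labels": out_dir / f"{stem}_labels.csv",
        "truth": out_dir / f"{stem}_truth.json",
    }
    exp_transform(dataset).save(paths["data"])
    pd.DataFrame({"fibre_id": dataset.patient.fibre_ids,
                  "label": labels}).to_csv(paths["labels"], index=False)
    paths["truth"].write_text(truth.to_json(indent=2))
    return paths
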