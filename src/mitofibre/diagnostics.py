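"""Convergence diagnostics and chain selection.

The original workflow inspected effective sample sizes, R-hat and trace
plots, discarded chains showing signs of non-convergence, and based
inference on the chain with the highest minimum per-parameter effective
sample size.  Here the visual check is replaced by a quantitative one: each
chain is split in half and the split R-hat of the two halves is computed
(a stationarity/drift statistic for a single chain); chains with any
per-parameter split R-hat above the threshold are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

RHAT_THRESHOLD = 1.05


class ConvergenceError(RuntimeError):
    """Every chain was flagged as non-convergent."""


@dataclass
class Diagnostics:
    ess: list          # per chain: dict parameter -> ESS (bulk)
    r_hat: list        # per chain: dict parameter -> split R-hat of its halves
    flagged: list      # per chain: bool
    selected_chain: int
    threshold: float = RHAT_THRESHOLD

    def min_ess(self, chain: int) -> float:
        return min(self.ess[chain].values())


def ess_1d(x) -> float:
    """Bulk effective sample size of a single series."""
    return float(az.ess(np.asarray(x, dtype=float)[None, :]))


def split_rhat_1d(x) -> float:
    """Split R-hat of one series: compare its two halves as pseudo-chains."""
    x = np.asarray(x, dtype=float)
    half = len(x) // 2
    return float(az.rhat(np.stack([x[:half], x[half:2 * half]])))


def diagnose_chains(draws, threshold: float = RHAT_THRESHOLD) -> Diagnostics:
    """Per-chain, per-parameter ESS and split R-hat; flag drifting chains;
    select the unflagged chain maximising the minimum per-parameter ESS."""
    ess, r_hat, flagged = [], [], []
    for ch in draws.chains:
        ce, cr = {}, {}
        for name, series in ch.scalar_params().items():
            ce[name] = ess_1d(series)
            cr[name] = split_rhat_1d(series)
        ess.append(ce)
        r_hat.append(cr)
        flagged.append(any(v > threshold for v in cr.values()))
    if all(flagged):
        raise ConvergenceError(
            "all chains flagged as non-convergent "
            f"(split R-hat > {threshold} for some parameter)")
    candidates = [i for i, f in enumerate(flagged) if not f]
    selected = max(candidates, key=lambda i: min(ess[i].values()))
    return Diagnostics(ess=ess, r_hat=r_hat, flagged=flagged,
                       selected_chain=selected, threshold=threshold)


def select_chain(draws, threshold: float = RHAT_THRESHOLD) -> int:
    return diagnose_chains(draws, threshold=threshold).selected_chain
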