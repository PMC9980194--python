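"""Convergence diagnostics: split-R-hat and effective sample size.

Split-R-hat halves each chain before computing the classic
between/within variance ratio, so within-chain drift registers as
lack of convergence even for a single chain.  ESS uses the FFT-based
autocorrelation estimate with Geyer's initial-monotone-positive
truncation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RHAT_WARN = 1.05


def _split(chains: np.ndarray) -> np.ndarray:
    """(m, n) chains -> (2m, n//2) half-chains."""
    n = chains.shape[1] // 2
    return np.vstack([chains[:, :n], chains[:, n : 2 * n]])


def split_rhat(draws: np.ndarray) -> float:
    """Split-R-hat for draws shaped (n,) for one chain or (m, n) for m chains."""
    chains = np.atleast_2d(np.asarray(draws, float))
    if chains.shape[1] < 4:
        raise ValueError("split-R-hat needs at least 4 draws per chain")
    sp = _split(chains)
    m, n = sp.shape
    chain_means = sp.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = sp.var(axis=1, ddof=1).mean()
    if w == 0:
        return np.inf if b > 0 else 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def ess(draws: np.ndarray) -> float:
    """Effective sample size via Geyer initial-monotone positive sequences."""
    chains = np.atleast_2d(np.asarray(draws, float))
    m, n = chains.shape
    if n < 4:
        raise ValueError("ESS needs at least 4 draws per chain")
    w = chains.var(axis=1, ddof=0).mean()
    if w == 0:
        return float(m)  # a constant chain carries (at most) one point of information
    # mean autocovariance across chains via FFT
    acov = np.zeros(n)
    for c in chains:
        x = c - c.mean()
        f = np.fft.rfft(x, 2 * n)
        ac = np.fft.irfft(f * np.conj(f))[:n] / n
        acov += ac
    acov /= m
    rho = acov / acov[0]
    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    pair = rho[1:-1:2] + rho[2::2]
    t = 0
    run_min = np.inf
    s = 0.0
    while t < len(pair) and pair[t] > 0:
        run_min = min(run_min, pair[t])
        s += run_min
        t += 1
    tau = max(1.0 + 2.0 * s, 1.0 / (m * n))
    return float(min(m * n / tau, m * n))


def diagnostics(samples) -> pd.DataFrame:
    """Split-R-hat and ESS for every scalar parameter of a posterior sample.

    Accepts any object exposing ``scalar_draws() -> dict[str, array]``
    (notably :class:`mrdjoint.sampler.PosteriorSamples`).  Raises on
    fewer than 4 draws.  The ``flagged`` column marks R-hat > 1.05.
    """
    rows = []
    for name, vals in samples.scalar_draws().items():
        r = split_rhat(vals)
        e = ess(vals)
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "rhat": r,
                "ess": e,
                "flagged": bool(r > RHAT_WARN),
            }
        )
    return pd.DataFrame(rows)
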