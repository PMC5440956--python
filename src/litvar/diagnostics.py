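"""Convergence and precision diagnostics for Gibbs chains.

Single-chain tools matching common practice in animal-breeding Bayesian
analyses: the Geweke Z criterion (first 10% vs last 50% of the chain, with
spectral-density-at-zero variance estimates), time-series Monte Carlo
standard errors by batch means, and highest-posterior-density intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError


@dataclass
class PosteriorChain:
    """Thinned samples of one scalar parameter plus chain metadata."""

    name: str
    samples: np.ndarray
    iterations: int = 0
    burn_in: int = 0
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.isfinite(self.samples).all():
            raise ValidationError(f"chain {self.name!r} contains non-finite values")


def _spectral_var_of_mean(x: np.ndarray) -> float:
    """Variance of the segment mean from the spectral density at zero.

    Autocovariances are combined with a Bartlett window over the first 4%
    of lags (at least one lag).
    """
    n = x.size
    x = x - x.mean()
    lags = max(1, int(0.04 * n))
    gamma0 = float(x @ x) / n
    s0 = gamma0
    for k in range(1, lags + 1):
        gk = float(x[:-k] @ x[k:]) / n
        s0 += 2.0 * (1.0 - k / (lags + 1)) * gk
    return max(s0, 0.0) / n


def geweke_z(chain, first_fraction: float = 0.1, last_fraction: float = 0.5) -> float:
    """Geweke convergence Z score comparing early and late segment means."""
    x = np.asarray(getattr(chain, "samples", chain), dtype=float)
    if x.size < 100:
        raise ValidationError("Geweke diagnostic needs a chain of length >= 100")
    a = x[: int(first_fraction * x.size)]
    b = x[-int(last_fraction * x.size):]
    va, vb = _spectral_var_of_mean(a), _spectral_var_of_mean(b)
    denom = np.sqrt(va + vb)
    if denom == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def mc_standard_error(chain) -> float:
    """Time-series Monte Carlo standard error of the chain mean (batch means)."""
    x = np.asarray(getattr(chain, "samples", chain), dtype=float)
    if x.size < 100:
        raise ValidationError("MC standard error needs a chain of length >= 100")
    n_batches = int(np.floor(np.sqrt(x.size)))
    batch = x.size // n_batches
    means = x[: n_batches * batch].reshape(n_batches, batch).mean(axis=1)
    if np.allclose(means, means[0]):
        return 0.0
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def hpd_interval(samples, probability: float = 0.95) -> tuple:
    """Shortest contiguous interval containing the requested posterior mass."""
    x = np.sort(np.asarray(getattr(samples, "samples", samples), dtype=float))
    if x.size == 0:
        raise ValidationError("no samples")
    if not 0.0 < probability < 1.0:
        raise ValidationError("probability must be in (0, 1)")
    m = max(1, int(np.ceil(probability * x.size)))
    if m >= x.size:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: x.size - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def summarize(chains) -> pd.DataFrame:
    """Diagnostics table for a mapping name -> samples (or PosteriorChain)."""
    rows = []
    for name, ch in chains.items():
        x = np.asarray(getattr(ch, "samples", ch), dtype=float)
        lo, hi = hpd_interval(x, 0.95)
        rows.append(
            {
                "parameter": name,
                "mean": float(x.mean()),
                "median": float(np.median(x)),
                "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
                "mcse": mc_standard_error(x) if x.size >= 100 else np.nan,
                "geweke_z": geweke_z(x) if x.size >= 100 else np.nan,
                "hpd_low": lo,
                "hpd_high": hi,
            }
        )
    return pd.DataFrame(rows)


def check_convergence(chains, z_threshold: float = 3.0) -> list:
    """Names of parameters whose |Geweke Z| exceeds the threshold."""
    flagged = []
    for name, ch in chains.items():
        if abs(geweke_z(ch)) > z_threshold:
            flagged.append(name)
    return flagged
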