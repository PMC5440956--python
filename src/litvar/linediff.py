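"""Bayesian weighted line-difference model for phenotypic response.

Phenotypic response to selection is the per-generation difference between
the High and Low lines in the doe-level variance records. The model is

    y = X b + e ,

with one record per doe (her intra-doe variance), ``b`` a line-generation
cell effect, and heteroscedastic residuals: the record of a doe with n
parities has variance ``c(n) * sigma_e^2`` with ``c(n) = 2(n-1)/(n+1)^2``.
Priors are bounded flat for all unknowns; the posterior is explored with a
Gibbs sampler whose two blocks are conjugate:

* ``b | sigma_e^2`` — the cells are orthogonal, so each cell effect is a
  weighted cell mean plus normal noise;
* ``sigma_e^2 | b`` — scaled inverse chi-square from the weighted residual
  sum of squares.

Summaries include, besides equal-tail intervals, the "guaranteed value"
k of a one-sided interval [k, +inf) holding a stated posterior probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ChainConfig, LINE_DIFF_CHAIN
from .exceptions import ModelError, ValidationError
from .variance import ve_record_weights

SIGMA2_FLOOR = 1e-8


@dataclass
class LineGenPosterior:
    """Thinned posterior samples of the line-generation cell means."""

    cells: list                    # (line, generation) labels, column order
    b_samples: np.ndarray          # (n_samples, n_cells)
    sigma2_samples: np.ndarray     # (n_samples,)
    chain: ChainConfig
    value_col: str = "ve"

    def cell_index(self, line, generation) -> int:
        try:
            return self.cells.index((line, int(generation)))
        except ValueError:
            raise ModelError(f"no cell for line={line!r}, generation={generation}")

    def difference_samples(self, generation: int) -> np.ndarray:
        """Samplewise High - Low difference for one generation."""
        hi = self.b_samples[:, self.cell_index("High", generation)]
        lo = self.b_samples[:, self.cell_index("Low", generation)]
        return hi - lo


def gls_closed_form(y, design, weights, sigma2):
    """Weighted least-squares mean and covariance of b at fixed sigma_e^2.

    ``weights`` are the per-record residual-variance coefficients c_i, i.e.
    Var(e_i) = c_i * sigma2.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(design, dtype=float)
    c = np.asarray(weights, dtype=float)
    w = 1.0 / c
    xtwx = x.T @ (w[:, None] * x)
    if np.linalg.matrix_rank(xtwx) < xtwx.shape[0]:
        raise ModelError("rank-deficient design in GLS")
    cov = np.linalg.inv(xtwx) * sigma2
    mean = np.linalg.solve(xtwx, x.T @ (w * y))
    return mean, cov


def fit_weighted_linegen_model(
    ve_records: pd.DataFrame,
    chain: ChainConfig = LINE_DIFF_CHAIN,
    value_col: str = "ve",
) -> LineGenPosterior:
    """Gibbs sampler for the weighted line-generation model.

    ``value_col`` selects the analyzed record: ``ve`` (pre-corrected
    variance), ``vr`` (uncorrected) or ``sde`` (square-root scale).
    """
    df = ve_records
    cells = sorted(
        {(l, int(g)) for l, g in zip(df["line"], df["generation"])},
        key=lambda c: (c[1], c[0]),
    )
    cell_of = {c: i for i, c in enumerate(cells)}
    idx = np.array(
        [cell_of[(l, int(g))] for l, g in zip(df["line"], df["generation"])]
    )
    y = df[value_col].to_numpy(dtype=float)
    c = ve_record_weights(df)
    w = 1.0 / c
    n_cells = len(cells)
    counts = np.bincount(idx, minlength=n_cells)
    if (counts == 0).any():
        empty = [cells[i] for i in np.flatnonzero(counts == 0)]
        raise ModelError(f"empty line-generation cells: {empty}")

    w_sum = np.bincount(idx, weights=w, minlength=n_cells)
    wy_sum = np.bincount(idx, weights=w * y, minlength=n_cells)
    ybar = wy_sum / w_sum
    n = len(y)

    rng = np.random.default_rng(chain.seed)
    b = ybar.copy()
    sigma2 = 1.0
    keep = chain.n_samples
    b_out = np.empty((keep, n_cells))
    s_out = np.empty(keep)
    k = 0
    for it in range(chain.iterations):
        b = ybar + rng.standard_normal(n_cells) * np.sqrt(sigma2 / w_sum)
        resid = y - b[idx]
        ssr = float((w * resid**2).sum())
        sigma2 = max(ssr / rng.chisquare(max(n - 2, 1)), SIGMA2_FLOOR)
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0 and k < keep:
            b_out[k] = b
            s_out[k] = sigma2
            k += 1
    return LineGenPosterior(cells, b_out[:k], s_out[:k], chain, value_col)


def guaranteed_value(samples, probability: float) -> float:
    """Bound k of the one-sided interval [k, +inf) with the stated probability.

    ``P(value > k) = probability`` under the posterior, i.e. k is the
    (1 - probability) quantile of the samples.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValidationError("no posterior samples")
    if not 0.0 < probability < 1.0:
        raise ValidationError("probability must be in (0, 1)")
    return float(np.quantile(samples, 1.0 - probability))


def line_contrasts(posterior: LineGenPosterior, probability: float = 0.80) -> pd.DataFrame:
    """Per-generation High - Low summaries (mean, SD, 95% CI, guaranteed value)."""
    gens = sorted({g for l, g in posterior.cells if l in ("High", "Low")})
    rows = []
    for g in gens:
        try:
            d = posterior.difference_samples(g)
        except ModelError:
            continue
        rows.append(
            {
                "generation": g,
                "mean_diff": float(d.mean()),
                "sd_diff": float(d.std(ddof=1)),
                "ci_low": float(np.quantile(d, 0.025)),
                "ci_high": float(np.quantile(d, 0.975)),
                f"guaranteed_{int(round(probability * 100))}": guaranteed_value(
                    d, probability
                ),
            }
        )
    if not rows:
        raise ModelError("no generation has both High and Low cells")
    return pd.DataFrame(rows)
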