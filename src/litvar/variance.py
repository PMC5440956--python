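"""Intra-doe variance records: pre-correction and the minimum-risk estimator.

The selection criterion is each doe's intra-doe variance of litter size,

    V_e = (1/(n+1)) * sum_i (x_i - xbar)^2 ,

computed on records pre-corrected for year-season and parity-lactation
status. The divisor n+1 gives the quadratic estimator with minimum risk
(smallest expected mean square error), not the unbiased sample variance.
Because a doe's variance is estimated from n = 2..9 parities, records are
heteroscedastic; downstream models weight record i by

    c(n_i) = 2 (n_i - 1) / (n_i + 1)^2 ,

the variance of V_e in units of the residual variance.

Litter-record tables are pandas DataFrames with columns
``doe, parity, year_season, lactation_class, litter_size``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ModelError, ValidationError

LITTER_COLUMNS = ["doe", "parity", "year_season", "lactation_class", "litter_size"]
VE_COLUMNS = ["doe", "line", "generation", "n_parities", "ve", "vr", "sde"]


def intra_doe_variance(values) -> float:
    """Minimum quadratic risk estimator of the within-doe variance.

    Parameters
    ----------
    values : array-like
        Pre-corrected litter sizes of one doe, length n >= 2.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("intra-doe variance requires at least 2 parities")
    return float(np.sum((x - x.mean()) ** 2) / (x.size + 1))


def record_weight(n: int) -> float:
    """Residual-variance coefficient c(n) = 2(n-1)/(n+1)^2 of a variance record."""
    n = int(n)
    if n < 2:
        raise ValidationError("record weight undefined for n < 2")
    return 2.0 * (n - 1) / (n + 1) ** 2


@dataclass(frozen=True)
class EffectEstimates:
    """Additive two-factor least-squares estimates used for pre-correction.

    Effects are expressed relative to a reference level fixed at 0
    (the lexicographically first level of each factor).
    """

    year_season: dict
    parity_lactation: dict
    reference: tuple

    def lookup(self, ys, pl) -> float:
        try:
            return self.year_season[ys] + self.parity_lactation[pl]
        except KeyError as exc:
            raise ValidationError(f"level {exc.args[0]!r} not covered by estimates")


def fit_precorrection(records: pd.DataFrame) -> EffectEstimates:
    """OLS fit of litter size on year-season and parity-lactation status.

    The two factors enter additively; all records are pooled (both lines,
    all generations). Reference levels are constrained to 0.
    """
    if len(records) == 0:
        raise ModelError("no records to fit pre-correction on")
    ys_levels = sorted(records["year_season"].astype(str).unique())
    pl_levels = sorted(records["lactation_class"].astype(str).unique())
    y = records["litter_size"].to_numpy(dtype=float)
    n = len(y)
    # intercept + non-reference dummies of each factor
    cols = [np.ones(n)]
    names = ["intercept"]
    ys = records["year_season"].astype(str).to_numpy()
    pl = records["lactation_class"].astype(str).to_numpy()
    for lev in ys_levels[1:]:
        cols.append((ys == lev).astype(float))
        names.append(("year_season", lev))
    for lev in pl_levels[1:]:
        cols.append((pl == lev).astype(float))
        names.append(("parity_lactation", lev))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ModelError(
            "confounded year-season / parity-lactation levels: design matrix is "
            f"rank deficient (rank {rank} < {X.shape[1]})"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ys_eff = {ys_levels[0]: 0.0}
    pl_eff = {pl_levels[0]: 0.0}
    for name, b in zip(names[1:], beta[1:]):
        factor, lev = name
        if factor == "year_season":
            ys_eff[lev] = float(b)
        else:
            pl_eff[lev] = float(b)
    return EffectEstimates(
        year_season=ys_eff,
        parity_lactation=pl_eff,
        reference=(ys_levels[0], pl_levels[0]),
    )


def precorrect(records: pd.DataFrame, effects: EffectEstimates) -> np.ndarray:
    """Litter sizes minus the estimated systematic effects.

    No grand-mean centering is applied: the intra-doe variance is invariant
    to any translation common to all of a doe's records.
    """
    corr = np.empty(len(records), dtype=float)
    ls = records["litter_size"].to_numpy(dtype=float)
    ys = records["year_season"].astype(str).to_numpy()
    pl = records["lactation_class"].astype(str).to_numpy()
    for i in range(len(records)):
        corr[i] = ls[i] - effects.lookup(ys[i], pl[i])
    return corr


def build_ve_records(
    records: pd.DataFrame,
    effects: EffectEstimates,
    min_parities: int = 2,
    doe_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One variance record per doe with at least ``min_parities`` parities.

    ``ve`` uses pre-corrected litter sizes, ``vr`` the raw ones, and
    ``sde = sqrt(ve)``. ``doe_meta``, if given, is indexed by doe id with
    columns ``line`` and ``generation``.
    """
    corrected = precorrect(records, effects)
    df = records.assign(_corr=corrected)
    rows = []
    n_excluded = 0
    for doe, grp in df.groupby("doe", sort=True):
        n = len(grp)
        if n < min_parities:
            n_excluded += 1
            continue
        ve = intra_doe_variance(grp["_corr"].to_numpy())
        vr = intra_doe_variance(grp["litter_size"].to_numpy(dtype=float))
        line, gen = "", -1
        if doe_meta is not None and doe in doe_meta.index:
            line = doe_meta.loc[doe, "line"]
            gen = int(doe_meta.loc[doe, "generation"])
        rows.append((doe, line, gen, n, ve, vr, float(np.sqrt(ve))))
    out = pd.DataFrame(rows, columns=VE_COLUMNS)
    out.attrs["n_excluded"] = n_excluded
    return out


def ve_record_weights(ve_records: pd.DataFrame) -> np.ndarray:
    """c(n) coefficients for a table of variance records."""
    return np.array([record_weight(n) for n in ve_records["n_parities"]])
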