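"""Bayesian animal models: genetic trends, repeatability model, bivariate fit.

Three Gibbs-sampled mixed models, all with bounded flat priors:

* :func:`fit_ve_animal_model` — the doe's variance record with generation as
  a fixed effect and an additive genetic effect with covariance
  ``A sigma_u^2``; optional heteroscedastic residual weights ``c(n)``.
  Produces variance components and the per-line-generation genetic trend
  (posterior of the mean breeding value of each generation's does).
* :func:`fit_ls_repeatability_model` — repeated litter-size records with
  line-generation, parity-lactation and year-season fixed effects and a
  permanent environmental effect per doe (additive genetic effect optional).
  Produces per-generation High - Low litter-size contrasts.
* :func:`fit_bivariate_model` — the two traits jointly, breeding values
  bivariate with covariance ``G (x) A`` and an inverse-Wishart conditional
  for G; residuals independent across traits (the traits live at different
  levels: one derived variance record vs repeated records).

Heritability on the variance-record scale uses the phenotypic variance at
the average record precision, ``sigma_u^2 + cbar * sigma_e^2`` with ``cbar``
the mean weight coefficient, so that weighted and unweighted fits report
comparable ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._gibbs import bivariate_chain, univariate_chain
from .config import ChainConfig, GENETIC_CHAIN
from .diagnostics import hpd_interval
from .exceptions import ModelError
from .linediff import guaranteed_value
from .pedigree import Pedigree, a_inverse
from .variance import ve_record_weights


@dataclass
class VarianceComponents:
    """Posterior summaries (mean and HPD95%) of the variance components."""

    summary: pd.DataFrame
    samples: dict


def heritability(sigma_u2_samples, sigma_e2_samples, *extra_variance_samples):
    """Samplewise h2 = sigma_u^2 / (sigma_u^2 + all other components)."""
    u = np.asarray(sigma_u2_samples, dtype=float)
    e = np.asarray(sigma_e2_samples, dtype=float)
    if u.shape != e.shape:
        raise ModelError("sample vectors must have equal length")
    total = u + e
    for x in extra_variance_samples:
        x = np.broadcast_to(np.asarray(x, dtype=float), u.shape)
        total = total + x
    return u / total


def _csr_from_codes(codes: np.ndarray, n_levels: int):
    codes = np.asarray(codes, dtype=np.int64)
    order = np.argsort(codes, kind="stable").astype(np.int64)
    indptr = np.searchsorted(codes[order], np.arange(n_levels + 1)).astype(np.int64)
    return indptr, order


def _multi_factor_csr(factor_codes: list, level_counts: list):
    """Stack several factors into one global level -> record CSR."""
    offsets = np.concatenate([[0], np.cumsum(level_counts)])
    all_codes = []
    all_recs = []
    for f, codes in enumerate(factor_codes):
        all_codes.append(np.asarray(codes, dtype=np.int64) + offsets[f])
        all_recs.append(np.arange(len(codes), dtype=np.int64))
    codes = np.concatenate(all_codes)
    recs = np.concatenate(all_recs)
    n_fix = int(offsets[-1])
    order = np.argsort(codes, kind="stable")
    indptr = np.searchsorted(codes[order], np.arange(n_fix + 1)).astype(np.int64)
    return indptr, recs[order].astype(np.int64), n_fix, offsets


def _ainv_arrays(pedigree: Pedigree):
    ai = a_inverse(pedigree).tocsr()
    diag = ai.diagonal().astype(float)
    return (
        ai.indptr.astype(np.int64),
        ai.indices.astype(np.int64),
        ai.data.astype(float),
        diag,
        len(pedigree),
    )


def _codes(values) -> tuple:
    levels = sorted(pd.unique(np.asarray(values).astype(str)).tolist())
    lookup = {v: i for i, v in enumerate(levels)}
    return np.array([lookup[str(v)] for v in values], dtype=np.int64), levels


def _summary_frame(samples: dict) -> pd.DataFrame:
    rows = []
    for name, x in samples.items():
        lo, hi = hpd_interval(x, 0.95)
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)),
                "hpd_low": lo,
                "hpd_high": hi,
            }
        )
    return pd.DataFrame(rows)


def fit_ve_animal_model(
    ve_records: pd.DataFrame,
    pedigree: Pedigree,
    chain: ChainConfig = GENETIC_CHAIN,
    weighted: bool = True,
):
    """Animal model for the variance record: generation fixed, breeding value random.

    Returns ``(VarianceComponents, trend)`` where ``trend`` is a DataFrame
    with the posterior mean and SD of the average breeding value of each
    line-generation group of does.
    """
    y = ve_records["ve"].to_numpy(dtype=float)
    c = ve_record_weights(ve_records)
    w = 1.0 / c if weighted else np.ones_like(y)
    cbar = float(np.mean(c)) if weighted else 1.0

    gen_codes, gen_levels = _codes(ve_records["generation"])
    lev_indptr, lev_recs, n_fix, _ = _multi_factor_csr([gen_codes], [len(gen_levels)])

    anim = pedigree.index_of(ve_records["doe"])
    ai_indptr, ai_indices, ai_data, ai_diag, q = _ainv_arrays(pedigree)
    arec_indptr, arec_recs = _csr_from_codes(anim, q)

    pf = pedigree.frame
    grp_labels = []
    grp_lookup = {}
    group_idx = np.full(q, -1, dtype=np.int64)
    for i, (sex, line, gen) in enumerate(zip(pf["sex"], pf["line"], pf["generation"])):
        if sex != "F":
            continue
        key = (line, int(gen))
        if key not in grp_lookup:
            grp_lookup[key] = len(grp_labels)
            grp_labels.append(key)
        group_idx[i] = grp_lookup[key]

    var_y = float(np.var(y))
    beta_out, var_out, grp_out = univariate_chain(
        y, w,
        lev_indptr, lev_recs, n_fix,
        np.zeros(1, dtype=np.int64), np.zeros(0, dtype=np.int64), 0, False,
        np.full(len(y), -1, dtype=np.int64),
        arec_indptr, arec_recs, anim,
        ai_indptr, ai_indices, ai_data, ai_diag, q, True,
        group_idx, max(1, len(grp_labels)),
        chain.iterations, chain.burn_in, chain.thin, chain.seed,
        0.1 * var_y, 1.0, var_y / cbar,
    )
    s2u = var_out[:, 0]
    s2e = var_out[:, 2]
    samples = {
        "sigma2_u": s2u,
        "sigma2_e": s2e,
        "h2": s2u / (s2u + cbar * s2e),
    }
    components = VarianceComponents(_summary_frame(samples), samples)
    trend = pd.DataFrame(
        {
            "line": [l for l, g in grp_labels],
            "generation": [g for l, g in grp_labels],
            "mean_bv": grp_out.mean(axis=0)[: len(grp_labels)],
            "sd_bv": grp_out.std(axis=0, ddof=1)[: len(grp_labels)],
        }
    ).sort_values(["generation", "line"]).reset_index(drop=True)
    return components, trend


def fit_ls_repeatability_model(
    litter_records: pd.DataFrame,
    pedigree: Pedigree,
    chain: ChainConfig = GENETIC_CHAIN,
    with_additive: bool = False,
    probability: float = 0.80,
):
    """Repeatability model for litter size; returns (components, contrasts).

    Fixed effects: line-generation cell, parity-lactation status,
    year-season. Random: permanent environmental effect per doe, plus an
    additive genetic effect when ``with_additive`` is set. ``contrasts``
    holds the per-generation High - Low posterior summaries with guaranteed
    values at ``probability`` and at 95%.
    """
    meta = pedigree.frame.set_index("id")[["line", "generation"]]
    doe_line = litter_records["doe"].map(meta["line"])
    doe_gen = litter_records["doe"].map(meta["generation"])
    if doe_line.isna().any():
        missing = litter_records["doe"][doe_line.isna()].iloc[0]
        raise ModelError(f"doe {missing!r} not in pedigree")
    cell = [f"{l}|{int(g)}" for l, g in zip(doe_line, doe_gen)]

    y = litter_records["litter_size"].to_numpy(dtype=float)
    w = np.ones_like(y)
    cell_codes, cell_levels = _codes(cell)
    pl_codes, pl_levels = _codes(litter_records["lactation_class"])
    ys_codes, ys_levels = _codes(litter_records["year_season"])
    lev_indptr, lev_recs, n_fix, offsets = _multi_factor_csr(
        [cell_codes, pl_codes, ys_codes],
        [len(cell_levels), len(pl_levels), len(ys_levels)],
    )

    doe_codes, doe_levels = _codes(litter_records["doe"])
    perm_indptr, perm_recs = _csr_from_codes(doe_codes, len(doe_levels))

    ai_indptr, ai_indices, ai_data, ai_diag, q = _ainv_arrays(pedigree)
    if with_additive:
        anim = pedigree.index_of(litter_records["doe"])
        arec_indptr, arec_recs = _csr_from_codes(anim, q)
    else:
        anim = np.full(len(y), -1, dtype=np.int64)
        arec_indptr = np.zeros(q + 1, dtype=np.int64)
        arec_recs = np.zeros(0, dtype=np.int64)

    var_y = float(np.var(y))
    beta_out, var_out, _ = univariate_chain(
        y, w,
        lev_indptr, lev_recs, n_fix,
        perm_indptr, perm_recs, len(doe_levels), True, doe_codes,
        arec_indptr, arec_recs, anim,
        ai_indptr, ai_indices, ai_data, ai_diag, q, with_additive,
        np.full(q, -1, dtype=np.int64), 1,
        chain.iterations, chain.burn_in, chain.thin, chain.seed,
        0.1 * var_y, 0.1 * var_y, 0.8 * var_y,
    )
    samples = {
        "sigma2_p": var_out[:, 1],
        "sigma2_e": var_out[:, 2],
    }
    if with_additive:
        samples["sigma2_u"] = var_out[:, 0]
        samples["h2"] = heritability(var_out[:, 0], var_out[:, 2], var_out[:, 1])
    components = VarianceComponents(_summary_frame(samples), samples)

    cell_cols = {lab: beta_out[:, offsets[0] + i] for i, lab in enumerate(cell_levels)}
    gens = sorted(
        {int(lab.split("|")[1]) for lab in cell_levels if lab.startswith(("High", "Low"))}
    )
    rows = []
    for g in gens:
        hi, lo = f"High|{g}", f"Low|{g}"
        if hi not in cell_cols or lo not in cell_cols:
            continue
        d = cell_cols[hi] - cell_cols[lo]
        rows.append(
            {
                "generation": g,
                "mean_diff": float(d.mean()),
                "sd_diff": float(d.std(ddof=1)),
                "ci_low": float(np.quantile(d, 0.025)),
                "ci_high": float(np.quantile(d, 0.975)),
                f"guaranteed_{int(round(probability * 100))}": guaranteed_value(d, probability),
                "guaranteed_95": guaranteed_value(d, 0.95),
            }
        )
    contrasts = pd.DataFrame(rows)
    return components, contrasts


def fit_bivariate_model(
    ve_records: pd.DataFrame,
    litter_records: pd.DataFrame,
    pedigree: Pedigree,
    chain: ChainConfig = GENETIC_CHAIN,
) -> VarianceComponents:
    """Bivariate animal model of (variance record, litter size).

    Reports posterior samples and HPD95% summaries of the genetic
    (co)variances, the per-trait heritabilities, the genetic correlation
    ``r_g = G12 / sqrt(G11 G22)`` and the doe-level phenotypic correlation
    ``r_p`` implied by the components (genetic covariance over the product
    of doe-level phenotypic SDs, litter size taken as a mean over the
    average number of parities).
    """
    y1 = ve_records["ve"].to_numpy(dtype=float)
    c = ve_record_weights(ve_records)
    w1 = 1.0 / c
    cbar = float(np.mean(c))
    gen_codes, gen_levels = _codes(ve_records["generation"])
    lev1_indptr, lev1_recs, n_fix1, _ = _multi_factor_csr([gen_codes], [len(gen_levels)])
    anim1 = pedigree.index_of(ve_records["doe"])

    meta = pedigree.frame.set_index("id")[["line", "generation"]]
    doe_line = litter_records["doe"].map(meta["line"])
    doe_gen = litter_records["doe"].map(meta["generation"])
    cell = [f"{l}|{int(g)}" for l, g in zip(doe_line, doe_gen)]
    y2 = litter_records["litter_size"].to_numpy(dtype=float)
    cell_codes, cell_levels = _codes(cell)
    pl_codes, pl_levels = _codes(litter_records["lactation_class"])
    ys_codes, ys_levels = _codes(litter_records["year_season"])
    lev2_indptr, lev2_recs, n_fix2, _ = _multi_factor_csr(
        [cell_codes, pl_codes, ys_codes],
        [len(cell_levels), len(pl_levels), len(ys_levels)],
    )
    doe_codes, doe_levels = _codes(litter_records["doe"])
    perm_indptr, perm_recs = _csr_from_codes(doe_codes, len(doe_levels))
    anim2 = pedigree.index_of(litter_records["doe"])

    ai_indptr, ai_indices, ai_data, ai_diag, q = _ainv_arrays(pedigree)
    a1rec_indptr, a1rec_recs = _csr_from_codes(anim1, q)
    a2rec_indptr, a2rec_recs = _csr_from_codes(anim2, q)

    var1, var2 = float(np.var(y1)), float(np.var(y2))
    out = bivariate_chain(
        y1, w1, lev1_indptr, lev1_recs, n_fix1, a1rec_indptr, a1rec_recs, anim1,
        y2, lev2_indptr, lev2_recs, n_fix2,
        perm_indptr, perm_recs, len(doe_levels), doe_codes,
        a2rec_indptr, a2rec_recs, anim2,
        ai_indptr, ai_indices, ai_data, ai_diag, q,
        chain.iterations, chain.burn_in, chain.thin, chain.seed,
        0.1 * var1, 0.1 * var2, var1 / cbar, 0.8 * var2, 0.1 * var2,
    )
    g11, g12, g22 = out[:, 0], out[:, 1], out[:, 2]
    s2e1, s2e2, s2p = out[:, 3], out[:, 4], out[:, 5]
    nbar = float(np.mean(ve_records["n_parities"]))
    p1 = g11 + cbar * s2e1
    p2 = g22 + s2p + s2e2 / nbar
    samples = {
        "g11": g11,
        "g12": g12,
        "g22": g22,
        "sigma2_e_ve": s2e1,
        "sigma2_e_ls": s2e2,
        "sigma2_p_ls": s2p,
        "h2_ve": g11 / (g11 + cbar * s2e1),
        "h2_ls": g22 / (g22 + s2p + s2e2),
        "rg": g12 / np.sqrt(g11 * g22),
        "rp": g12 / np.sqrt(p1 * p2),
    }
    return VarianceComponents(_summary_frame(samples), samples)
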