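"""Experiment configuration and trait calibration.

The defaults describe a ten-generation divergent selection experiment on the
environmental variance of litter size in rabbits: two lines of ~125 does and
25 sires each, bred in discrete generations from a common unselected base.
Selection is on the intra-doe variance of litter size (the minimum-risk
estimator with divisor n+1), dams needing at least four parities to be
candidates, with within-sire-family replacement of males.

Base-population phenotypic moments (litter size mean 8.71 kits, SD 3.01;
intra-doe variance mean 3.73 kits^2, SD 3.36) and genetic parameters
(h2 of the variance trait 0.08, h2 of litter size 0.10, genetic correlation
~0) follow the rabbit experiment this package models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import CalibrationError, ValidationError

PARITY_SUPPORT = np.arange(2, 10)

#: Default distribution of the number of litters per doe (support 2..9).
#: Mean 4.51, mode 4; 70% of does have four or five parities.
DEFAULT_PARITY_DISTRIBUTION = (0.04, 0.11, 0.44, 0.26, 0.07, 0.04, 0.02, 0.02)

#: Realized weighted dam selection differentials of the rabbit divergent
#: selection experiment, in kits^2, one entry per selection round
#: (round 0 = base generation, rounds 1..9 = generations 1..9).
#: Used by the ``differential_matched`` selection mode.
REALIZED_DAM_DIFFERENTIALS_HIGH = (3.0, 1.5, 1.7, 2.9, 1.8, 2.0, 2.4, 2.9, 1.7, 2.4)
REALIZED_DAM_DIFFERENTIALS_LOW = (1.5, 0.2, 0.3, 0.6, 0.2, 0.9, 1.0, 0.8, 0.2, 0.4)

PARITY_LACTATION_LEVELS = ("first", "later_lactating", "later_nonlactating")


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs-chain settings: total iterations, burn-in and thinning."""

    iterations: int = 60_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValidationError("burn_in must be in [0, iterations)")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")

    @property
    def n_samples(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


#: Chain used for line-difference (phenotypic response) models.
LINE_DIFF_CHAIN = ChainConfig(iterations=60_000, burn_in=10_000, thin=10)

#: Chain used for the genetic (animal) models.
GENETIC_CHAIN = ChainConfig(iterations=1_000_000, burn_in=500_000, thin=100)


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the breeding scheme and genetic model."""

    n_generations: int = 10
    does_per_line: int = 125
    sires_per_line: int = 25
    dams_per_sire: int = 5
    selected_fraction: float = 0.20
    min_parities_for_selection: int = 4
    parity_count_distribution: tuple = DEFAULT_PARITY_DISTRIBUTION
    ve_base_mean: float = 3.73
    ve_base_sd: float = 3.36
    h2_ve: float = 0.08
    ls_base_mean: float = 8.71
    ls_base_sd: float = 3.01
    h2_ls: float = 0.10
    repeatability_ls: float = 0.20
    rg_ve_ls: float = 0.0
    year_season_sd: float = 0.30
    parity_lactation_effects: tuple = (-0.7, 0.0, 0.3)
    mode: str = "trait_level"
    selection_mode: str = "truncation"
    target_differentials: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("selected_fraction", "h2_ve", "h2_ls", "repeatability_ls"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {val}")
        if not -1.0 <= self.rg_ve_ls <= 1.0:
            raise ValidationError("rg_ve_ls must be in [-1, 1]")
        if self.repeatability_ls < self.h2_ls:
            raise ValidationError("repeatability_ls must be >= h2_ls")
        p = np.asarray(self.parity_count_distribution, dtype=float)
        if p.size != PARITY_SUPPORT.size:
            raise ValidationError(
                "parity_count_distribution must have 8 entries (parities 2..9)"
            )
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise ValidationError("parity_count_distribution must be a probability vector")
        if self.does_per_line != self.sires_per_line * self.dams_per_sire:
            raise ValidationError(
                "does_per_line must equal sires_per_line * dams_per_sire"
            )
        if self.mode not in ("trait_level", "mechanistic"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.selection_mode not in ("truncation", "differential_matched"):
            raise ValidationError(f"unknown selection_mode {self.selection_mode!r}")
        if self.selection_mode == "differential_matched":
            t = self.resolved_target_differentials()
            for key in ("high", "low"):
                if len(t[key]) != self.n_generations:
                    raise ValidationError(
                        f"target_differentials[{key!r}] must have one entry per "
                        f"selection round ({self.n_generations})"
                    )

    # -- derived quantities ------------------------------------------------

    def resolved_target_differentials(self) -> dict:
        """Per-round dam differential targets (signed magnitudes, kits^2)."""
        if self.target_differentials is not None:
            return self.target_differentials
        n = self.n_generations
        return {
            "high": list(REALIZED_DAM_DIFFERENTIALS_HIGH[:n]),
            "low": list(REALIZED_DAM_DIFFERENTIALS_LOW[:n]),
        }

    @property
    def parity_probabilities(self) -> np.ndarray:
        return np.asarray(self.parity_count_distribution, dtype=float)

    @property
    def mean_parities(self) -> float:
        return float((self.parity_probabilities * PARITY_SUPPORT).sum())

    @property
    def sigma2_u_ls(self) -> float:
        """Additive variance of litter size (kits^2)."""
        return self.h2_ls * self.ls_base_sd**2

    @property
    def sigma2_perm_ls(self) -> float:
        """Permanent environmental variance of litter size (kits^2)."""
        return (self.repeatability_ls - self.h2_ls) * self.ls_base_sd**2

    @property
    def sigma2_e_ls(self) -> float:
        """Residual variance of a single litter-size record (kits^2)."""
        return (1.0 - self.repeatability_ls) * self.ls_base_sd**2

    def ve_trait_calibration(self) -> dict:
        """Calibrate the trait-level model of the observed intra-doe variance.

        The observed record is ``max(0, mu + v + eps) * W`` with ``v`` the
        additive value, ``eps`` a doe-level environmental deviate and
        ``W = chi2_{n-1}/(n-1)`` the estimator's sampling noise
        (``E[W] = 1``, ``Var[W] = 2/(n-1)``). Moment matching gives

        * additive variance ``sigma_v^2 = h2 * sd^2`` (so that twice the
          parent-offspring regression slope equals ``h2``),
        * total doe-level variance ``sigma_T^2 = (sd^2 - mu^2 k)/(1 + k)``
          with ``k = E[2/(n-1)]`` over the parity distribution,
        * ``sigma_eps^2 = sigma_T^2 - sigma_v^2``.

        Raises :class:`CalibrationError` when ``sigma_eps^2 < 0``, i.e. the
        requested heritability cannot coexist with the requested SD given the
        estimator noise implied by the parity distribution.
        """
        p = self.parity_probabilities
        kappa = float((p * 2.0 / (PARITY_SUPPORT - 1)).sum())
        mu = self.ve_base_mean
        var_target = self.ve_base_sd**2
        sigma2_v = self.h2_ve * var_target
        sigma2_t = (var_target - mu**2 * kappa) / (1.0 + kappa)
        sigma2_eps = sigma2_t - sigma2_v
        if sigma2_t <= 0 or sigma2_eps < 0:
            raise CalibrationError(
                f"infeasible trait-level calibration: h2_ve={self.h2_ve}, "
                f"sd={self.ve_base_sd}, estimator-noise factor kappa={kappa:.3f} "
                f"requires doe-level variance {sigma2_t:.3f} but additive variance "
                f"alone is {sigma2_v:.3f}"
            )
        return {"sigma2_v": sigma2_v, "sigma2_eps": sigma2_eps, "kappa": kappa}

    @property
    def sigma2_v_log(self) -> float:
        """Additive variance on the log residual-variance scale (mechanistic mode).

        Delta-method calibration so that the observed-scale additive variance
        of the intra-doe variance approximates ``h2_ve * ve_base_sd^2``.
        """
        return self.h2_ve * self.ve_base_sd**2 / self.ve_base_mean**2

    @property
    def eta0(self) -> float:
        """Baseline log residual variance of litter size (mechanistic mode).

        Chosen so the expected intra-doe variance estimate (which carries the
        (n-1)/(n+1) deflation of the divisor-(n+1) estimator) matches
        ``ve_base_mean``.
        """
        p = self.parity_probabilities
        deflation = float((p * (PARITY_SUPPORT - 1) / (PARITY_SUPPORT + 1)).sum())
        return float(
            np.log(self.ve_base_mean / deflation) - 0.5 * self.sigma2_v_log
        )

    def genetic_covariance(self) -> np.ndarray:
        """2x2 additive (co)variance matrix of (v_Ve, u_LS) on the simulated scale."""
        if self.mode == "trait_level":
            s2v = self.ve_trait_calibration()["sigma2_v"]
        else:
            s2v = self.sigma2_v_log
        s2u = self.sigma2_u_ls
        cov = self.rg_ve_ls * np.sqrt(s2v * s2u)
        return np.array([[s2v, cov], [cov, s2u]])

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
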