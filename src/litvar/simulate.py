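"""Synthetic divergent-selection experiments on litter-size environmental variance.

Two generative modes share the same breeding scheme (discrete generations,
125 does and 25 sires per line, top/bottom 20% dam selection among does with
four or more parities, within-sire-family male replacement):

``trait_level``
    The doe's observed intra-doe variance is simulated directly as
    ``max(0, mu + v + eps) * W`` where ``v`` is her additive value, ``eps``
    a doe-level environmental deviate and ``W = chi2_{n-1}/(n-1)`` the
    sampling noise of a variance estimated from ``n`` parities. The model is
    calibrated so the observed trait reproduces the base-population mean and
    SD and the requested regression heritability
    (:meth:`litvar.config.SimConfig.ve_trait_calibration`).
    Litter-size records are simulated alongside with a homoscedastic
    residual, so mean-trait analyses can run on the same experiment.

``mechanistic``
    Litter-size records are simulated with a genetically structured residual
    variance ``Var(e) = exp(eta0 + v)`` (the standard exponential model for
    heterogeneous residual variance), and the intra-doe variance is then
    *computed* from the records through the pre-correction pipeline, exactly
    as an analyst would.

Selection can be plain truncation or ``differential_matched``, where the
per-round realized dam differential is pinned to prescribed targets (the
default targets are the differentials realized in the rabbit experiment this
package models). In both modes each sire family's replacement son comes from
the family's best dam in the line's direction, and every selection decision
— dam ranking, differential matching, family-best choice — is made on the
record as it stood at selection time (the first ``min(n, 4)`` parities),
while the analysis pipeline sees the complete-career records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PARITY_SUPPORT, SimConfig
from .exceptions import SelectionError, ValidationError
from .pedigree import PEDIGREE_COLUMNS, Pedigree, _tabular
from .selection import (
    eligible_dams,
    match_differential,
    select_dams,
    weighted_selection_differential,
)
from .variance import (
    VE_COLUMNS,
    build_ve_records,
    fit_precorrection,
    intra_doe_variance,
)

LACTATING_PROB = 0.7  # later parities: does are usually re-mated while lactating


@dataclass
class ExperimentData:
    """Everything one simulated experiment produced."""

    pedigree: Pedigree
    litter_records: pd.DataFrame
    ve_records: pd.DataFrame
    selection_log: pd.DataFrame
    config: SimConfig

    def doe_meta(self) -> pd.DataFrame:
        f = self.pedigree.frame
        return f[f["sex"] == "F"].set_index("id")[["line", "generation"]]


# ---------------------------------------------------------------------------
# elementary operations


def sample_parity_counts(config: SimConfig, n_does: int, rng) -> np.ndarray:
    """Number of litters per doe, drawn from the configured distribution."""
    return rng.choice(PARITY_SUPPORT, size=n_does, p=config.parity_probabilities)


def simulate_observed_variances(
    v: np.ndarray, n_parities: np.ndarray, config: SimConfig, rng, selection_at=None
) -> np.ndarray:
    """Trait-level observed intra-doe variances for does with additive values v.

    With ``selection_at=m`` a second array is returned: the record as it
    stood when the doe had only her first ``min(n, m)`` parities (selection
    decisions are made on incomplete records). The two share the doe's level
    T and the chi-square components of the early parities.
    """
    cal = config.ve_trait_calibration()
    v = np.asarray(v, dtype=float)
    eps = rng.normal(0.0, np.sqrt(cal["sigma2_eps"]), size=v.shape)
    t = np.maximum(0.0, config.ve_base_mean + v + eps)
    n = np.asarray(n_parities)
    if selection_at is None:
        k = n - 1
        return t * rng.chisquare(k) / k
    m = np.minimum(n, selection_at)
    x1 = rng.chisquare(m - 1)
    x2 = np.where(n > m, rng.chisquare(np.maximum(n - m, 1)), 0.0)
    full = t * (x1 + x2) / (n - 1)
    early = t * x1 / (m - 1)
    return full, early


def simulate_observed_variance(doe_v: float, n_parities: int, config: SimConfig, rng) -> float:
    """Single-doe version of :func:`simulate_observed_variances`."""
    if config.mode != "trait_level":
        raise ValidationError("simulate_observed_variance requires trait_level mode")
    return float(simulate_observed_variances(np.array([doe_v]), np.array([n_parities]), config, rng)[0])


class _SeasonEffects:
    """Year-season effects drawn once per class label."""

    def __init__(self, sd: float, rng):
        self.sd = sd
        self.rng = rng
        self.effects: dict = {}

    def get(self, label: str) -> float:
        if label not in self.effects:
            self.effects[label] = float(self.rng.normal(0.0, self.sd))
        return self.effects[label]


def _ls_intercept(config: SimConfig) -> float:
    """Intercept making the expected litter size equal ls_base_mean."""
    p_first = 1.0 / config.mean_parities
    first, lact, nonlact = config.parity_lactation_effects
    e_pl = p_first * first + (1 - p_first) * (
        LACTATING_PROB * lact + (1 - LACTATING_PROB) * nonlact
    )
    return config.ls_base_mean - e_pl


def _doe_record_rows(
    doe, n_parities, config, effects, rng, u_ls, perm, v_ve, generation
) -> list:
    first, lact, nonlact = config.parity_lactation_effects
    intercept = _ls_intercept(config)
    if config.mode == "mechanistic":
        sd = float(np.exp(0.5 * (config.eta0 + v_ve)))
    else:
        sd = float(np.sqrt(config.sigma2_e_ls))
    rows = []
    for j in range(1, int(n_parities) + 1):
        ys = f"ys{2 * generation + (j - 1) // 3}"
        if j == 1:
            pl, pl_eff = "first", first
        elif rng.random() < LACTATING_PROB:
            pl, pl_eff = "later_lactating", lact
        else:
            pl, pl_eff = "later_nonlactating", nonlact
        mean = intercept + effects.get(ys) + pl_eff + u_ls + perm
        size = max(0, int(round(mean + rng.normal(0.0, sd))))
        rows.append((doe, j, ys, pl, size))
    return rows


def simulate_doe_records(
    doe: str,
    n_parities: int,
    config: SimConfig,
    effects: _SeasonEffects,
    rng,
    u_ls: float = 0.0,
    perm: float = 0.0,
    v_ve: float = 0.0,
    generation: int = 0,
) -> pd.DataFrame:
    """Litter records for one doe.

    Parity j of a doe in generation g falls in year-season class
    ``ys{2g + (j-1)//3}`` (two seasons per year, roughly three litters per
    season). The residual SD is ``exp((eta0 + v)/2)`` in mechanistic mode and
    the homoscedastic ``sqrt(sigma2_e_ls)`` in trait-level mode. Litter sizes
    are rounded to non-negative integers.
    """
    rows = _doe_record_rows(doe, n_parities, config, effects, rng, u_ls, perm, v_ve, generation)
    return pd.DataFrame(
        rows, columns=["doe", "parity", "year_season", "lactation_class", "litter_size"]
    )


# ---------------------------------------------------------------------------
# population bookkeeping


class _Population:
    """Growing pedigree with breeding values, held as parallel lists."""

    def __init__(self, g_matrix: np.ndarray):
        self.g = g_matrix
        self.ids: list = []
        self.sire: list = []
        self.dam: list = []
        self.sex: list = []
        self.line: list = []
        self.gen: list = []
        self.v: list = []
        self.u: list = []
        self.perm: list = []
        self.sire_idx: list = []
        self.dam_idx: list = []
        self._pos: dict = {}
        self.f = np.zeros(0)

    def add(self, id_, sire, dam, sex, line, gen, v, u, perm):
        self._pos[id_] = len(self.ids)
        self.ids.append(id_)
        self.sire.append(sire)
        self.dam.append(dam)
        self.sex.append(sex)
        self.line.append(line)
        self.gen.append(gen)
        self.v.append(v)
        self.u.append(u)
        self.perm.append(perm)
        self.sire_idx.append(self._pos.get(sire, -1))
        self.dam_idx.append(self._pos.get(dam, -1))

    def update_inbreeding(self):
        a = _tabular(
            np.array(self.sire_idx, dtype=np.int64),
            np.array(self.dam_idx, dtype=np.int64),
        )
        self.f = np.diag(a) - 1.0

    def bv(self, id_) -> tuple:
        i = self._pos[id_]
        return self.v[i], self.u[i]

    def inbreeding_of(self, id_) -> float:
        return float(self.f[self._pos[id_]])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [s or "0" for s in self.sire],
                "dam": [d or "0" for d in self.dam],
                "sex": self.sex,
                "line": self.line,
                "generation": self.gen,
                "v_ve": self.v,
                "u_ls": self.u,
                "perm": self.perm,
            }
        )


def simulate_base_population(config: SimConfig, rng) -> pd.DataFrame:
    """Unrelated, unselected base animals: 2x does_per_line females, 2x sires_per_line males."""
    g = config.genetic_covariance()
    n_f = 2 * config.does_per_line
    n_m = 2 * config.sires_per_line
    n = n_f + n_m
    bv = _mvn(np.zeros(2), g, n, rng)
    perm = rng.normal(0.0, np.sqrt(config.sigma2_perm_ls), n)
    ids = [f"B0F{i:04d}" for i in range(1, n_f + 1)] + [
        f"B0M{i:04d}" for i in range(1, n_m + 1)
    ]
    return pd.DataFrame(
        {
            "id": ids,
            "sire": "0",
            "dam": "0",
            "sex": ["F"] * n_f + ["M"] * n_m,
            "line": "Base",
            "generation": 0,
            "v_ve": bv[:, 0],
            "u_ls": bv[:, 1],
            "perm": perm,
        }
    )


def _mvn(mean, cov, n, rng):
    # explicit Cholesky keeps draws reproducible across platforms
    var = np.diag(cov).copy()
    if (var == 0).any():
        l = np.zeros_like(cov)
        nz = var > 0
        if nz.any():
            sub = np.linalg.cholesky(cov[np.ix_(nz, nz)])
            l[np.ix_(nz, nz)] = sub
    else:
        l = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, len(mean)))
    return mean + z @ l.T


def breed_next_generation(
    selected_dams: pd.DataFrame, selected_sires: pd.DataFrame, config: SimConfig, rng
) -> pd.DataFrame:
    """Offspring of a full mating table (each sire with ``dams_per_sire`` dams).

    Parent frames need columns ``id, v_ve, u_ls`` and optionally ``f``
    (inbreeding). Offspring breeding values are the parent average plus a
    bivariate Mendelian-sampling deviation with covariance
    ``0.5 * G * (1 - mean(F_parents))``.
    """
    n_s, n_d = len(selected_sires), len(selected_dams)
    if n_d != n_s * config.dams_per_sire:
        raise ValidationError(
            f"need {n_s * config.dams_per_sire} dams for {n_s} sires, got {n_d}"
        )
    if "f" not in selected_dams:
        selected_dams = selected_dams.assign(f=0.0)
    if "f" not in selected_sires:
        selected_sires = selected_sires.assign(f=0.0)
    g = config.genetic_covariance()
    rows = []
    slot = 0
    for _, sire in selected_sires.iterrows():
        for _ in range(config.dams_per_sire):
            dam = selected_dams.iloc[slot]
            fbar = 0.5 * (sire["f"] + dam["f"])
            ms = _mvn(np.zeros(2), 0.5 * g * (1.0 - fbar), 1, rng)[0]
            rows.append(
                {
                    "sire": sire["id"],
                    "dam": dam["id"],
                    "v_ve": 0.5 * (sire["v_ve"] + dam["v_ve"]) + ms[0],
                    "u_ls": 0.5 * (sire["u_ls"] + dam["u_ls"]) + ms[1],
                }
            )
            slot += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full experiment


def run_experiment(config: SimConfig) -> ExperimentData:
    """Simulate a complete divergent-selection experiment.

    Returns litter records and variance records for every generation
    (0 .. n_generations) of both lines, the full pedigree, and a per-round
    selection log with realized differentials.
    """
    rng = np.random.default_rng(config.seed)
    if config.mode == "trait_level":
        config.ve_trait_calibration()  # fail fast on infeasible settings
    g = config.genetic_covariance()
    pop = _Population(g)
    seasons = _SeasonEffects(config.year_season_sd, rng)
    targets = (
        config.resolved_target_differentials()
        if config.selection_mode == "differential_matched"
        else None
    )

    base = simulate_base_population(config, rng)
    for _, row in base.iterrows():
        pop.add(row["id"], None, None, row["sex"], "Base", 0, row["v_ve"], row["u_ls"], row["perm"])
    pop.update_inbreeding()

    litter_frames: list = []
    selection_rows: list = []
    ve_frames: list = []

    def make_records(doe_ids, gen):
        """Simulate parities + phenotypes for a list of does; returns ve table."""
        n_par = sample_parity_counts(config, len(doe_ids), rng)
        lit = _simulate_litters(pop, doe_ids, n_par, gen, config, seasons, rng)
        litter_frames.append(lit)
        m_sel = config.min_parities_for_selection
        if config.mode == "trait_level":
            v = np.array([pop.bv(d)[0] for d in doe_ids])
            ve, ve_sel = simulate_observed_variances(
                v, n_par, config, rng, selection_at=m_sel
            )
            tab = pd.DataFrame(
                {
                    "doe": doe_ids,
                    "line": [pop.line[pop._pos[d]] for d in doe_ids],
                    "generation": gen,
                    "n_parities": n_par,
                    "ve": ve,
                    "vr": ve,
                    "sde": np.sqrt(ve),
                    "ve_selection": ve_sel,
                }
            )
        else:
            pooled = pd.concat(litter_frames, ignore_index=True)
            effects = fit_precorrection(pooled)
            meta = pd.DataFrame(
                {
                    "line": [pop.line[pop._pos[d]] for d in doe_ids],
                    "generation": gen,
                },
                index=pd.Index(doe_ids, name="doe"),
            )
            tab = build_ve_records(lit, effects, min_parities=2, doe_meta=meta)
            # selection-time record: the variance of the first parities only
            early = build_ve_records(
                lit[lit["parity"] <= m_sel], effects, min_parities=2
            ).set_index("doe")["ve"]
            tab["ve_selection"] = tab["doe"].map(early).fillna(tab["ve"]).to_numpy()
        ve_frames.append(tab)
        return tab

    # --- base generation phenotypes
    base_does = [i for i, s in zip(pop.ids, pop.sex) if s == "F"]
    base_sires = [i for i, s in zip(pop.ids, pop.sex) if s == "M"]
    matings = _assign_matings(base_does, base_sires, config.dams_per_sire, rng)
    # all selection decisions are made on the record as it stood at selection
    # time (the first parities), not the complete-career record
    ve_tab = _selection_view(make_records(base_does, 0))

    # --- base selection round: joint pool, opposite directions; each line's
    # take is sized against its own half of the shared pool
    current = {"High": None, "Low": None}
    pool = ve_tab[ve_tab["n_parities"] >= config.min_parities_for_selection]
    if targets is None and config.selected_fraction >= 1.0:
        # no selection: random disjoint halves
        shuffled = pool["doe"].to_numpy()[rng.permutation(len(pool))]
        sel_high = sorted(shuffled[: len(pool) // 2])
        sel_low = sorted(shuffled[len(pool) // 2 :])
    elif targets is None:
        k = int(np.ceil(config.selected_fraction * len(pool) / 2))
        frac = k / len(pool)
        sel_high = select_dams(pool, frac, "up")
        remaining = pool[~pool["doe"].isin(sel_high)]
        sel_low = select_dams(remaining, k / len(remaining), "down")
    else:
        sel_high = _select(pool, config, "up", targets, 0, "high")
        remaining = pool[~pool["doe"].isin(sel_high)]
        sel_low = _select(remaining, config, "down", targets, 0, "low", full_pool=pool)
    fam_split = _split_families(base_sires, rng)
    for line, direction, selected, fams in (
        ("High", "up", sel_high, fam_split[0]),
        ("Low", "down", sel_low, fam_split[1]),
    ):
        current[line] = _breed_line(
            pop, config, rng, line, 1, selected, matings, fams, ve_tab, direction, targets
        )
        selection_rows.append(
            _log_row(line, 0, pool, selected, current[line])
        )

    # --- subsequent rounds
    for t in range(1, config.n_generations):
        gen_tabs = {}
        for line in ("High", "Low"):
            gen_tabs[line] = _selection_view(make_records(current[line]["does"], t))
        for line, direction, key in (("High", "up", "high"), ("Low", "down", "low")):
            tab = gen_tabs[line]
            pool = tab[tab["n_parities"] >= config.min_parities_for_selection]
            selected = _select(pool, config, direction, targets, t, key)
            nxt = _breed_line(
                pop,
                config,
                rng,
                line,
                t + 1,
                selected,
                current[line]["matings"],
                current[line]["sires"],
                tab,
                direction,
                targets,
            )
            selection_rows.append(_log_row(line, t, pool, selected, nxt))
            gen_tabs[line] = (tab, nxt)
        current = {line: gen_tabs[line][1] for line in ("High", "Low")}

    # --- final generation phenotypes (no further selection)
    for line in ("High", "Low"):
        make_records(current[line]["does"], config.n_generations)

    pedigree = Pedigree(pop.frame()[PEDIGREE_COLUMNS + ["v_ve", "u_ls", "perm"]])
    litter_records = pd.concat(litter_frames, ignore_index=True)
    if config.mode == "mechanistic":
        # recompute all variance records once, with effects fitted on the full data
        effects = fit_precorrection(litter_records)
        meta = pedigree.frame.set_index("id")[["line", "generation"]]
        ve_records = build_ve_records(litter_records, effects, min_parities=2, doe_meta=meta)
    else:
        ve_records = pd.concat(ve_frames, ignore_index=True)[VE_COLUMNS]
    selection_log = pd.DataFrame(selection_rows)
    return ExperimentData(pedigree, litter_records, ve_records, selection_log, config)


# ---------------------------------------------------------------------------
# internals of the breeding loop


def _selection_view(tab: pd.DataFrame) -> pd.DataFrame:
    return tab.assign(ve=tab["ve_selection"])


def _simulate_litters(pop, doe_ids, n_par, gen, config, seasons, rng) -> pd.DataFrame:
    rows = []
    for doe, n in zip(doe_ids, n_par):
        i = pop._pos[doe]
        rows.extend(
            _doe_record_rows(
                doe, n, config, seasons, rng, pop.u[i], pop.perm[i], pop.v[i], gen
            )
        )
    return pd.DataFrame(
        rows, columns=["doe", "parity", "year_season", "lactation_class", "litter_size"]
    )


def _assign_matings(does, sires, dams_per_sire, rng) -> pd.DataFrame:
    """Each doe mated to one sire, dams_per_sire does per sire."""
    does = list(does)
    order = rng.permutation(len(does))
    rows = []
    for k, sire in enumerate(sires):
        for j in range(dams_per_sire):
            rows.append({"sire": sire, "dam": does[order[k * dams_per_sire + j]]})
    return pd.DataFrame(rows)


def _select(pool, config, direction, targets, round_idx, key, full_pool=None):
    if len(pool) == 0:
        raise SelectionError(f"no eligible dams in round {round_idx} ({key})")
    if targets is None:
        return select_dams(pool, config.selected_fraction, direction)
    target = targets[key][round_idx]
    signed = target if direction == "up" else -abs(target)
    if full_pool is not None:
        # lifts measured against the full joint pool's mean; after the other
        # line's dams are removed the required lift may change sign, in which
        # case the matched set is truncated from the opposite end
        shift = full_pool["ve"].mean() - pool["ve"].mean()
        signed = signed + shift
    direction_eff = direction if signed == 0 else ("up" if signed > 0 else "down")
    return match_differential(pool, signed, direction_eff)


def _split_families(base_sires, rng):
    order = rng.permutation(len(base_sires))
    half = len(base_sires) // 2
    sires = np.array(base_sires)
    return sires[order[:half]].tolist(), sires[order[half:]].tolist()


def _breed_line(
    pop, config, rng, line, next_gen, selected, matings, line_sires, ve_tab, direction, targets
):
    """Create generation ``next_gen`` of one line; returns its roster."""
    mate_of = matings.set_index("dam")["sire"]
    ve = ve_tab.set_index("doe")["ve"]
    n_daughters = config.does_per_line
    selected = sorted(selected)
    # allocate daughters as evenly as possible over selected dams
    counts = np.zeros(len(selected), dtype=int)
    counts[:] = n_daughters // len(selected)
    extra = rng.permutation(len(selected))[: n_daughters % len(selected)]
    counts[extra] += 1

    prefix = line[0]
    daughters = []
    dam_counts = dict(zip(selected, counts.tolist()))
    slot = 1
    for dam, k in zip(selected, counts):
        sire = mate_of[dam]
        for _ in range(k):
            daughters.append((f"{prefix}{next_gen}F{slot:04d}", sire, dam))
            slot += 1

    # replacement sons: one per sire family, from the family's best dam
    # (selected_fraction = 1 means no selection at all, so the son's dam is
    # then drawn at random instead of ranked)
    no_selection = targets is None and config.selected_fraction >= 1.0
    sons = []
    slot = 1
    for sire in sorted(line_sires):
        fam = sorted(matings.loc[matings["sire"] == sire, "dam"])
        fam = [d for d in fam if d in ve.index]
        if not fam:
            raise SelectionError(f"sire family {sire!r} has no recorded mates")
        if no_selection:
            pick = fam[int(rng.integers(len(fam)))]
        else:
            vals = np.array([ve[d] for d in fam])
            pick = fam[int(np.argmax(vals)) if direction == "up" else int(np.argmin(vals))]
        sons.append((f"{prefix}{next_gen}M{slot:04d}", sire, pick))
        slot += 1

    g = pop.g
    s2p = config.sigma2_perm_ls
    for id_, sire, dam in daughters + sons:
        vs, us = pop.bv(sire)
        vd, ud = pop.bv(dam)
        fbar = 0.5 * (pop.inbreeding_of(sire) + pop.inbreeding_of(dam))
        ms = _mvn(np.zeros(2), 0.5 * g * (1.0 - fbar), 1, rng)[0]
        sex = "F" if "F" in id_[1:] else "M"
        pop.add(
            id_, sire, dam, sex, line, next_gen,
            0.5 * (vs + vd) + ms[0],
            0.5 * (us + ud) + ms[1],
            float(rng.normal(0.0, np.sqrt(s2p))),
        )
    pop.update_inbreeding()

    doe_ids = [d[0] for d in daughters]
    sire_ids = [s[0] for s in sons]
    new_matings = _assign_matings(doe_ids, sire_ids, config.dams_per_sire, rng)
    return {
        "does": doe_ids,
        "sires": sire_ids,
        "matings": new_matings,
        "dam_counts": dam_counts,
    }


def _log_row(line, round_idx, pool, selected, roster):
    eq = weighted_selection_differential(selected, pool)
    wt = weighted_selection_differential(selected, pool, weights=roster["dam_counts"])
    return {
        "line": line,
        "generation": round_idx,
        "n_eligible": len(pool),
        "n_selected": len(selected),
        "dam_differential": wt,
        "dam_differential_unweighted": eq,
        "sire_ids": ";".join(map(str, roster["sires"])),
        "selected_dams": ";".join(map(str, selected)),
    }
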