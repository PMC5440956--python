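"""Dam ranking, truncation and differential-matched selection.

Selection is purely phenotypic: dams are ranked on their own intra-doe
variance record, without any pedigree-based evaluation. Only dams with a
minimum number of parities (four in the experiment) are candidates. The
``match_differential`` routine is a calibration device: it returns a
truncation-style selected set whose realized weighted differential equals a
prescribed target, so that simulated experiments can reproduce the selection
pressure actually achieved in a real breeding program rather than the ideal
truncation value.

Tie-breaking everywhere is a stable sort on (criterion, doe id).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import SelectionError, ValidationError


def eligible_dams(ve_records: pd.DataFrame, min_parities: int = 4) -> list:
    """Ids of does with at least ``min_parities`` parities."""
    sel = ve_records[ve_records["n_parities"] >= min_parities]
    return sel["doe"].tolist()


def _ranked(pool: pd.DataFrame, direction: str) -> pd.DataFrame:
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    ascending = direction == "down"
    return pool.sort_values(["ve", "doe"], ascending=[ascending, True], kind="stable")


def select_dams(ve_records: pd.DataFrame, fraction: float, direction: str) -> list:
    """Top (up) or bottom (down) ``ceil(fraction * pool)`` does by variance record."""
    if len(ve_records) == 0:
        raise SelectionError("empty candidate pool")
    k = int(np.ceil(fraction * len(ve_records)))
    if k < 1:
        raise SelectionError("selected fraction yields no dams")
    return _ranked(ve_records, direction)["doe"].head(k).tolist()


def select_sires_within_family(
    matings: pd.DataFrame, ve_records: pd.DataFrame, direction: str
) -> list:
    """One young male per sire family, from the family's best dam.

    ``matings`` has columns ``sire, dam``; ``ve_records`` must contain the
    dams' records. For each sire family the dam with the most extreme
    variance record in the line's direction is taken; the returned list holds
    the chosen dams' ids (their sons are the replacement males), ordered by
    sire id. A son tie (several male progeny of the chosen dam) is resolved
    downstream by lowest id.
    """
    ve = ve_records.set_index("doe")["ve"]
    chosen = []
    for sire, fam in matings.groupby("sire", sort=True):
        dams = [d for d in fam["dam"] if d in ve.index]
        if not dams:
            raise SelectionError(f"sire family {sire!r} has no dam with a record")
        dams = sorted(dams)
        vals = np.array([ve[d] for d in dams])
        idx = int(np.argmax(vals)) if direction == "up" else int(np.argmin(vals))
        chosen.append(dams[idx])
    return chosen


def weighted_selection_differential(
    selected, pool: pd.DataFrame, weights=None
) -> float:
    """Weighted mean variance record of the selected dams minus the pool mean.

    ``weights`` maps doe id to its contribution (number of offspring bred
    from it); equal weights when omitted.
    """
    if len(selected) == 0:
        raise SelectionError("empty selection")
    pool_ve = pool.set_index("doe")["ve"]
    missing = [d for d in selected if d not in pool_ve.index]
    if missing:
        raise SelectionError(f"selected dams not in pool: {missing[:5]}")
    if weights is None:
        w = np.ones(len(selected))
    else:
        w = np.array([float(weights[d]) for d in selected])
    if w.sum() <= 0:
        raise SelectionError("selection weights sum to zero")
    vals = np.array([pool_ve[d] for d in selected])
    return float((w * vals).sum() / w.sum() - pool_ve.mean())


def match_differential(
    pool: pd.DataFrame,
    target_differential: float,
    direction: str,
    rel_tol: float = 0.05,
) -> list:
    """Selected set whose (equal-weight) differential matches a target.

    Starts from truncation at the pool's extreme in the line's direction and
    adjusts the selected count until the realized differential is as close as
    possible to the target; a final pass swaps boundary dams with just-outside
    candidates to fine-tune. The target is signed in the pool's own units
    (positive for upward selection). Raises :class:`SelectionError` with the
    achievable range when the target cannot be met within ``rel_tol``.
    """
    if len(pool) == 0:
        raise SelectionError("empty candidate pool")
    ranked = _ranked(pool, direction)
    ve = ranked["ve"].to_numpy(dtype=float)
    ids = ranked["doe"].to_numpy()
    mean = ve.mean()
    lifts = np.cumsum(ve) / np.arange(1, len(ve) + 1) - mean
    sign = 1.0 if direction == "up" else -1.0
    target = float(target_differential)
    if sign * target < 0:
        raise SelectionError(
            f"target differential {target} has the wrong sign for direction {direction}"
        )
    k0 = int(np.argmin(np.abs(lifts - target))) + 1
    # absolute floor at half the targets' printed precision: truncation lifts
    # are discrete, so a purely relative tolerance is unattainable for tiny
    # targets on finite pools
    tol = max(rel_tol * abs(target), 0.05)
    best_err, best_sel = abs(lifts[k0 - 1] - target), list(range(k0))
    if best_err > tol and abs(target) > 0:
        # fine-tune by swapping boundary dams: exchange a just-selected dam
        # with a just-outside one, keeping the set a truncation set
        n = len(ve)
        width = 12
        for k in sorted({min(n, max(1, kk)) for kk in range(k0 - 2, k0 + 3)}):
            chosen = list(range(k))
            achieved = lifts[k - 1]
            err = abs(achieved - target)
            for _ in range(10):
                inside = np.array(sorted(chosen))[-width:]
                outside = np.array(
                    [j for j in range(len(ve)) if j not in set(chosen)][:width]
                )
                if outside.size == 0:
                    break
                delta = (ve[outside][None, :] - ve[inside][:, None]) / k
                errs = np.abs(achieved + delta - target)
                j_in, j_out = np.unravel_index(int(np.argmin(errs)), errs.shape)
                if errs[j_in, j_out] >= err - 1e-15:
                    break
                achieved += delta[j_in, j_out]
                err = float(errs[j_in, j_out])
                chosen.remove(int(inside[j_in]))
                chosen.append(int(outside[j_out]))
                if err <= tol:
                    break
            if err < best_err:
                best_err, best_sel = err, chosen
            if best_err <= tol:
                break
        if best_err > tol:
            lo, hi = (lifts.min(), lifts.max())
            raise SelectionError(
                f"target differential {target} unachievable within {rel_tol:.0%}; "
                f"achievable truncation range is [{min(lo, 0):.3f}, {max(hi, 0):.3f}]"
            )
    return [ids[j] for j in best_sel]
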