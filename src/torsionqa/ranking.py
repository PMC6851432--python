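"""Adjusted z-scores and combined ranking schemes over per-model metrics.

The adjusted z-score follows the two-pass protocol used in recent CASP
rounds: z-scores from the full population, one-shot pruning of entries
below -2, recomputation of mean/SD on the pruned set, and clipping of
negative z-scores to zero.  Combined scores are fixed linear
combinations of per-metric z-scores; per-group rankings sum the
combined score of the designated model over targets.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HIGHER_IS_BETTER",
    "SCHEMES",
    "adjusted_z",
    "combine",
    "zscore_table",
    "rank_groups",
]

#: Default orientation of each metric column.  Torsion error means and
#: clashscore are "lower is better" and get negated before z-scoring so
#: that a larger z is always better.
HIGHER_IS_BETTER: dict[str, bool] = {
    "GDT_HA": True,
    "GDT_TS": True,
    "lDDT": True,
    "CADaa": True,
    "SG": True,
    "ASE": True,
    "clashscore": False,
    "mean_backbone": False,
    "mean_sidechain": False,
}

#: z-score column produced from each metric column.
Z_COLUMN: dict[str, str] = {
    "GDT_HA": "z_GDT_HA",
    "GDT_TS": "z_GDT_TS",
    "lDDT": "z_lDDT",
    "CADaa": "z_CADaa",
    "SG": "z_SG",
    "ASE": "z_ASE",
    "clashscore": "z_clash",
    "mean_backbone": "z_backbone",
    "mean_sidechain": "z_sidechain",
}

#: Combined ranking schemes: weights applied to z-score columns.
SCHEMES: dict[str, dict[str, float]] = {
    "S_CASP12": {
        "z_GDT_HA": 1 / 3, "z_lDDT": 1 / 9, "z_CADaa": 1 / 9,
        "z_SG": 1 / 9, "z_ASE": 1 / 3,
    },
    "S_CASP12-ASE": {
        "z_GDT_HA": 1 / 2, "z_lDDT": 1 / 6, "z_CADaa": 1 / 6, "z_SG": 1 / 6,
    },
    "S_torsion": {
        "z_backbone": 2 / 3, "z_sidechain": 1 / 3,
    },
    "S_geom": {
        "z_lDDT": 1 / 16, "z_CADaa": 1 / 16, "z_SG": 1 / 16,
        "z_sidechain": 1 / 16, "z_clash": 1 / 8, "z_backbone": 1 / 8,
        "z_GDT_HA": 1 / 4, "z_ASE": 1 / 4,
    },
}

PRUNE_THRESHOLD = -2.0


def _z_pass(values: np.ndarray, mask: np.ndarray, ddof: int) -> np.ndarray:
    """z-scores of all values from the mean/SD of the masked subset.

    A degenerate subset (SD zero, or too few points for the requested
    ddof) yields all-zero z-scores for the pass.
    """
    subset = values[mask]
    if subset.size <= ddof:
        return np.zeros_like(values)
    sd = float(np.std(subset, ddof=ddof))
    if sd == 0.0 or not np.isfinite(sd):
        return np.zeros_like(values)
    return (values - float(np.mean(subset))) / sd


def adjusted_z(values: Sequence[float], higher_is_better: bool = True,
               ddof: int = 1,
               prune_threshold: float = PRUNE_THRESHOLD) -> np.ndarray:
    """Two-pass adjusted z-scores (all >= 0) for one target's population.

    Values are first oriented so that higher is better.  Initial
    z-scores use the full population; entries strictly below
    ``prune_threshold`` are dropped once; final z-scores for *all*
    entries use the pruned mean/SD, with negatives clipped to zero.

    ``ddof=1`` (sample SD) is the default; ``ddof=0`` gives the
    population-SD convention.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("adjusted_z requires at least 2 values")
    oriented = values if higher_is_better else -values
    all_mask = np.ones(oriented.size, dtype=bool)
    z1 = _z_pass(oriented, all_mask, ddof)
    keep = z1 >= prune_threshold
    if not keep.any():
        keep = all_mask
    z2 = _z_pass(oriented, keep, ddof)
    return np.clip(z2, 0.0, None)


def combine(z_row: Mapping[str, Optional[float]], scheme: str) -> float:
    """Evaluate one combined ranking score from a row of z-scores.

    Missing (or NaN) z columns contribute zero, consistent with the
    negative-clip philosophy; the omission is logged.
    """
    if scheme not in SCHEMES:
        raise KeyError(f"unknown scheme {scheme!r}; options: {sorted(SCHEMES)}")
    total = 0.0
    for column, weight in SCHEMES[scheme].items():
        z = z_row.get(column)
        if z is None or (isinstance(z, float) and np.isnan(z)):
            logger.debug("scheme %s: missing %s treated as 0", scheme, column)
            continue
        total += weight * float(z)
    return total


def _metric_columns(table: pd.DataFrame,
                    metrics: Optional[Iterable[str]]) -> list[str]:
    if metrics is None:
        metrics = [c for c in table.columns if c in Z_COLUMN]
    return list(metrics)


def zscore_table(table: pd.DataFrame,
                 metrics: Optional[Iterable[str]] = None,
                 orientation: Optional[Mapping[str, bool]] = None,
                 population: Literal["all", "model_1"] = "all",
                 ddof: int = 1) -> pd.DataFrame:
    """Append per-target adjusted z-score columns to a metric table.

    The table needs ``group``, ``target`` and ``model_index`` columns
    plus any subset of the known metric columns.  The z population per
    target is either all submitted models or the model-1 subset
    (``population``); z-scores are computed for every row either way,
    using the population statistics.
    """
    required = {"group", "target", "model_index"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metric table lacks columns {sorted(missing)}")
    orient = dict(HIGHER_IS_BETTER)
    if orientation:
        orient.update(orientation)
    out = table.copy()
    for metric in _metric_columns(table, metrics):
        zcol = Z_COLUMN.get(metric, f"z_{metric}")
        hib = orient.get(metric, True)
        out[zcol] = np.nan
        for _, idx in out.groupby("target", sort=False).groups.items():
            sub = out.loc[idx]
            if population == "model_1":
                pop_mask = sub["model_index"] == 1
            else:
                pop_mask = pd.Series(True, index=sub.index)
            vals = sub[metric].to_numpy(dtype=float)
            valid = np.isfinite(vals)
            pop = valid & pop_mask.to_numpy()
            if pop.sum() < 2:
                out.loc[idx, zcol] = 0.0
                continue
            oriented = vals if hib else -vals
            filled = np.where(valid, oriented, np.nan)
            ref = filled[pop]
            keep = ref[_z_pass_with_ref(ref, ref, ddof) >= PRUNE_THRESHOLD]
            if keep.size == 0:
                keep = ref
            z2 = _z_pass_with_ref(filled, keep, ddof)
            z2 = np.clip(z2, 0.0, None)
            z2[~valid] = np.nan
            out.loc[idx, zcol] = z2
    return out


def _z_pass_with_ref(values: np.ndarray, ref: np.ndarray, ddof: int) -> np.ndarray:
    if ref.size <= ddof:
        return np.zeros_like(values)
    sd = float(np.std(ref, ddof=ddof))
    if sd == 0.0 or not np.isfinite(sd):
        return np.zeros_like(values)
    return (values - float(np.mean(ref))) / sd


def rank_groups(table: pd.DataFrame, scheme: str = "S_CASP12",
                model_selection: Literal["model_1", "best_of_5"] = "model_1",
                orientation: Optional[Mapping[str, bool]] = None,
                population: Literal["all", "model_1"] = "all",
                ddof: int = 1) -> pd.DataFrame:
    """Rank predictor groups by summed combined score over targets.

    Per target, adjusted z-scores are computed over the model
    population; the combined score of the selected model (model 1, or
    the best of the group's submissions) is summed over targets per
    group.  Ties are broken by group label for determinism.
    """
    ztable = zscore_table(table, orientation=orientation,
                          population=population, ddof=ddof)
    zcols = [c for c in ztable.columns if c.startswith("z_")]
    ztable["combined"] = [
        combine({c: row[c] for c in zcols}, scheme)
        for _, row in ztable.iterrows()
    ]
    if model_selection == "model_1":
        selected = ztable[ztable["model_index"] == 1]
    elif model_selection == "best_of_5":
        idx = (ztable.groupby(["group", "target"], sort=False)["combined"]
               .idxmax())
        selected = ztable.loc[idx]
    else:
        raise ValueError(f"unknown model_selection {model_selection!r}")
    if selected.empty:
        raise ValueError("model selection produced no rows")
    totals = (selected.groupby("group")["combined"].sum()
              .reset_index(name="total_score"))
    totals = totals.sort_values(["total_score", "group"],
                                ascending=[False, True],
                                kind="mergesort").reset_index(drop=True)
    totals["rank"] = np.arange(1, len(totals) + 1)
    return totals
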