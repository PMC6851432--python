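"""Preparation of predicted models for molecular replacement.

Predicted per-atom RMS coordinate-error estimates (submitted in the
B-factor column) are converted to inflated B-factors, smearing each
atom's density over its positional uncertainty.  Models that are too
inaccurate for stable likelihood calculations are filtered out and
assigned a log-likelihood-gain (LLG) of zero.  The LLG itself always
arrives as an external number — this module never computes it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .structure import StructureRecord

logger = logging.getLogger(__name__)

__all__ = [
    "B_PER_SQ_ERROR",
    "MRModelRecord",
    "FilterResult",
    "inflate_b",
    "median_error_from_b",
    "apply_b_mode",
    "mr_filter",
    "mr_success",
    "best_of_models",
]

#: B-factor added per squared Å of RMS coordinate error: 8 pi^2 / 3.
B_PER_SQ_ERROR = 8.0 * math.pi ** 2 / 3.0

#: Rejection thresholds for unstable MR calculations.
GDT_TS_MIN = 30.0
MEDIAN_ERROR_MAX = 3.0

#: LLG gain at or above which a full MR search almost always succeeds.
LLG_SUCCESS_THRESHOLD = 60.0

#: Default constant B-factor when discarding the submitted column.
DEFAULT_CONSTANT_B = 20.0

BMode = Literal["constant", "error_estimate", "b_factor"]


def inflate_b(error_estimate: Union[float, np.ndarray],
              baseline_b: float = 0.0) -> Union[float, np.ndarray]:
    """B-factor equivalent of an RMS coordinate-error estimate (Å).

    Returns ``baseline_b + (8 pi^2 / 3) * error^2`` (Å²).
    """
    err = np.asarray(error_estimate, dtype=float)
    if np.any(err < 0):
        raise ValueError("error estimates must be non-negative")
    out = baseline_b + B_PER_SQ_ERROR * err ** 2
    return float(out) if np.isscalar(error_estimate) else out


def median_error_from_b(structure: StructureRecord) -> float:
    """Median of the B-column values over heavy atoms, read as Å errors."""
    values = [a.b_factor for r in structure.residues()
              for a in r.heavy_atoms()]
    if not values:
        raise ValueError("structure has no heavy atoms with a B column")
    return float(np.median(values))


@dataclass
class MRModelRecord:
    """One candidate MR search model with its external scores."""

    structure: StructureRecord
    b_mode: BMode = "error_estimate"
    gdt_ts: Optional[float] = None       # external, 0-100
    llg_gain: Optional[float] = None     # external, from any MR engine
    group: str = ""
    target: str = ""
    model_index: int = 1
    _median_error: Optional[float] = None

    @property
    def median_error(self) -> Optional[float]:
        """Median coordinate-error estimate (Å) from the B column.

        Only meaningful when the column carries error estimates; under
        other B modes it is reported but not used for filtering.
        """
        if self._median_error is None:
            try:
                self._median_error = median_error_from_b(self.structure)
            except ValueError:
                return None
        return self._median_error


def apply_b_mode(structure: StructureRecord, mode: BMode,
                 constant_value: float = DEFAULT_CONSTANT_B,
                 baseline_b: float = 0.0) -> StructureRecord:
    """Rewrite the B column of a copy of *structure* per interpretation.

    constant: every atom gets ``constant_value``; error_estimate: the
    column is treated as RMS error (Å) and inflated to a B-factor;
    b_factor: the column is left untouched (control calculation).
    """
    if mode not in ("constant", "error_estimate", "b_factor"):
        raise ValueError(f"unknown B mode {mode!r}")
    out = structure.copy()
    if mode == "b_factor":
        return out
    n_clamped = 0
    for res in out.residues():
        for atom in res.atoms:
            if mode == "constant":
                atom.b_factor = constant_value
            else:
                atom.b_factor = inflate_b(atom.b_factor, baseline_b)
            if atom.b_factor > 999.99:
                n_clamped += 1
    if n_clamped:
        logger.warning("%d atoms exceed the PDB B column maximum; they will "
                       "be clamped to 999.99 on write", n_clamped)
    return out


@dataclass(frozen=True)
class FilterResult:
    accepted: bool
    assigned_llg: Optional[float]
    reason: str = ""


def mr_filter(record: MRModelRecord) -> FilterResult:
    """Reject models too poor for stable MR calculations.

    Rejection iff GDT_TS < 30 (strict) or median error estimate > 3 Å
    (strict); rejected models are assigned an LLG of zero.  Both
    boundaries are non-strict for acceptance.
    """
    if record.gdt_ts is None:
        raise ValueError("mr_filter requires a GDT_TS value")
    reasons = []
    if record.gdt_ts < GDT_TS_MIN:
        reasons.append(f"GDT_TS {record.gdt_ts:g} < {GDT_TS_MIN:g}")
    median_error = record.median_error
    if (record.b_mode == "error_estimate" and median_error is not None
            and median_error > MEDIAN_ERROR_MAX):
        reasons.append(
            f"median error {median_error:g} Å > {MEDIAN_ERROR_MAX:g} Å")
    if reasons:
        return FilterResult(False, 0.0, "; ".join(reasons))
    return FilterResult(True, record.llg_gain)


def mr_success(llg_gain: float) -> bool:
    """Would a full MR search almost certainly succeed with this gain?"""
    if not np.isfinite(llg_gain):
        raise ValueError("llg_gain must be finite")
    return llg_gain >= LLG_SUCCESS_THRESHOLD


def best_of_models(records: Sequence[MRModelRecord],
                   ) -> tuple[Optional[MRModelRecord], float]:
    """Best accepted model of a group's submissions for one target.

    Returns (record, llg_gain) of the accepted model with the largest
    LLG gain, ties resolved to the lowest model index.  With every
    model rejected (or none given an LLG) the group scores zero for the
    target and the record is None.
    """
    if not records:
        raise ValueError("no records supplied")
    best: Optional[MRModelRecord] = None
    best_llg = -np.inf
    for record in sorted(records, key=lambda r: r.model_index):
        result = mr_filter(record)
        if not result.accepted or result.assigned_llg is None:
            continue
        if result.assigned_llg > best_llg:
            best, best_llg = record, float(result.assigned_llg)
    if best is None:
        return None, 0.0
    return best, best_llg
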