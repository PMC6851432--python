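"""Stereochemical triage of experimental template structures.

Combines deposited validation statistics (clashscore, rotamer and
Ramachandran outlier percentages) into the standard log-scale composite
quality score, bands templates by resolution, and recommends the best
of several candidate templates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Literal, Optional, Sequence

__all__ = [
    "TemplateQualityRecord",
    "TriageTier",
    "TriageAdvice",
    "molprobity_score",
    "triage",
    "pick_better_template",
]

# Composite-score combination constants, as defined in the score's
# original publication.
_W_CLASH = 0.426
_W_ROTA = 0.33
_W_RAMA = 0.25
_OFFSET = 0.5
_ROTA_FLOOR = 1.0   # % below which rotamer outliers do not count
_RAMA_FLOOR = 2.0   # % below which non-favored Ramachandran does not count

#: Resolution band boundaries (Å), as recommended.
RES_EXTREME_CAUTION = 5.0
RES_CAUTION = 3.5
RES_TRUSTED = 2.5

#: Composite-score levels for escalation / endorsement.
MOLPROBITY_WARN = 3.0
MOLPROBITY_GOOD = 2.0


def molprobity_score(clashscore: float, rotamer_outlier_pct: float,
                     rama_pct: float,
                     rama_convention: Literal["not_favored", "outlier"] = "not_favored",
                     ) -> float:
    """Log-scale composite stereochemistry score (lower is better).

        0.426 ln(1 + clashscore)
      + 0.33  ln(1 + max(0, rotamer% - 1))
      + 0.25  ln(1 + max(0, rama% - 2)) + 0.5

    The third term is defined on the Ramachandran *not-favored*
    percentage; deposited validation tables often print the outlier
    percentage instead, so the convention of the supplied value is
    declared explicitly (the arithmetic is identical — the flag
    documents what the result means).  Perfect inputs floor at 0.5;
    fully pathological inputs (clashscore 1000, all residues outliers)
    approach 6.1.
    """
    if clashscore < 0 or rotamer_outlier_pct < 0 or rama_pct < 0:
        raise ValueError("validation statistics must be non-negative")
    if rama_convention not in ("not_favored", "outlier"):
        raise ValueError(f"unknown Ramachandran convention {rama_convention!r}")
    return (_W_CLASH * math.log(1.0 + clashscore)
            + _W_ROTA * math.log(1.0 + max(0.0, rotamer_outlier_pct - _ROTA_FLOOR))
            + _W_RAMA * math.log(1.0 + max(0.0, rama_pct - _RAMA_FLOOR))
            + _OFFSET)


@dataclass
class TemplateQualityRecord:
    """Validation summary of one candidate template chain."""

    pdb_id: str
    chain: str = ""
    resolution: Optional[float] = None
    clashscore: Optional[float] = None
    rama_outlier_pct: Optional[float] = None
    rotamer_outlier_pct: Optional[float] = None
    molprobity_score: Optional[float] = None
    sequence_identity_to_target: Optional[float] = None
    release_year: Optional[int] = None

    def __post_init__(self) -> None:
        for pct in (self.rama_outlier_pct, self.rotamer_outlier_pct,
                    self.sequence_identity_to_target):
            if pct is not None and not 0.0 <= pct <= 100.0:
                raise ValueError(f"percentage out of range: {pct}")
        if self.clashscore is not None and self.clashscore < 0:
            raise ValueError("clashscore must be non-negative")

    def effective_molprobity(self) -> Optional[float]:
        """Stored composite score, or one computed from the statistics."""
        if self.molprobity_score is not None:
            return self.molprobity_score
        if None in (self.clashscore, self.rotamer_outlier_pct,
                    self.rama_outlier_pct):
            return None
        return molprobity_score(self.clashscore, self.rotamer_outlier_pct,
                                self.rama_outlier_pct,
                                rama_convention="outlier")


class TriageTier(IntEnum):
    """Trust tiers, ordered from least to most trustworthy."""

    REJECT = 0       # use only with extreme caution, if at all
    CAUTION = 1
    TRANSITION = 2   # usually correct; loops often problematic
    TRUSTED = 3


@dataclass(frozen=True)
class TriageAdvice:
    tier: TriageTier
    notes: tuple[str, ...] = field(default_factory=tuple)


def _resolution_tier(resolution: float) -> TriageTier:
    if resolution > RES_EXTREME_CAUTION:
        return TriageTier.REJECT
    if resolution > RES_CAUTION:
        return TriageTier.CAUTION
    if resolution > RES_TRUSTED:
        return TriageTier.TRANSITION
    return TriageTier.TRUSTED


def triage(record: TemplateQualityRecord) -> TriageAdvice:
    """Band a template by resolution with composite-score escalation.

    Resolution bands: >5 Å reject-tier; 3.5-5 Å caution; 2.5-3.5 Å
    transition zone; <2.5 Å trusted.  A composite score above 3
    escalates the advice one tier toward rejection; a score below 2
    adds an endorsing note (the tier is never raised by a good score).
    Records without a resolution are banded on the score alone, noted.
    """
    notes: list[str] = []
    mp = record.effective_molprobity()
    if record.resolution is not None:
        tier = _resolution_tier(record.resolution)
        if record.resolution > RES_EXTREME_CAUTION:
            notes.append("resolution worse than 5 Å: use only with extreme "
                         "caution, and only if no other option exists")
        elif record.resolution > RES_CAUTION:
            notes.append("3.5-5 Å: register shifts of whole stretches are "
                         "common at this resolution")
    else:
        notes.append("no resolution available; advice from stereochemistry "
                     "score alone")
        if mp is None:
            return TriageAdvice(TriageTier.CAUTION, tuple(notes + [
                "no stereochemistry statistics either"]))
        if mp < MOLPROBITY_GOOD:
            tier = TriageTier.TRANSITION
        elif mp <= MOLPROBITY_WARN:
            tier = TriageTier.CAUTION
        else:
            tier = TriageTier.REJECT
    if mp is not None:
        if mp > MOLPROBITY_WARN:
            notes.append(f"stereochemistry score {mp:.2f} > 3: substantial "
                         "caution advised")
            # A poor score demotes trusting tiers one band; a template
            # already at (or below) the caution tier keeps its band and
            # carries the warning note instead.
            if record.resolution is not None and tier > TriageTier.CAUTION:
                tier = TriageTier(tier - 1)
        elif mp < MOLPROBITY_GOOD:
            notes.append(f"stereochemistry score {mp:.2f} < 2: good quality")
    return TriageAdvice(tier, tuple(notes))


def pick_better_template(candidates: Sequence[TemplateQualityRecord],
                         identity_floor_pct: float = 0.0,
                         ) -> Optional[TemplateQualityRecord]:
    """Recommend one template from candidates at/above an identity floor.

    Lexicographic preference: best (numerically lowest) resolution,
    then lowest composite stereochemistry score, then latest release
    year; final tie-break on PDB id for determinism.  Returns None if
    no candidate passes the identity floor.
    """
    def passes(record: TemplateQualityRecord) -> bool:
        ident = record.sequence_identity_to_target
        return ident is None or ident >= identity_floor_pct

    eligible = [r for r in candidates if passes(r)]
    if not eligible:
        return None

    def sort_key(record: TemplateQualityRecord):
        mp = record.effective_molprobity()
        return (
            record.resolution if record.resolution is not None else math.inf,
            mp if mp is not None else math.inf,
            -(record.release_year if record.release_year is not None else -math.inf),
            record.pdb_id,
            record.chain,
        )

    return min(eligible, key=sort_key)
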