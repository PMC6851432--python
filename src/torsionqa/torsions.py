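"""Backbone and sidechain dihedral computation and comparison.

All angles are degrees in the canonical range (-180, 180].  Deltas are
minimal angular distances on the circle, in [0, 180].  The omega
torsion of residue i describes the peptide bond between residues i-1
and i (CA(i-1)-C(i-1)-N(i)-CA(i)).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from ._geometry import CHI1_ATOM, CHI2_ATOMS, CHI2_SYMMETRIC, N_CHI
from .structure import ResiduePair, ResidueRecord

__all__ = [
    "GeometryError",
    "BackboneTorsions",
    "SidechainTorsions",
    "OmegaClass",
    "TorsionDelta",
    "dihedral",
    "backbone_torsions",
    "chi_torsions",
    "angular_delta",
    "classify_omega",
    "torsion_delta",
]

#: Peptides more than this far (degrees) from both planar configurations
#: are classified as twisted.  Exactly at the boundary counts as planar.
TWIST_CUTOFF = 30.0

_COLLINEAR_TOL = 1e-9


class GeometryError(ValueError):
    """Degenerate atom geometry (coincident or collinear points)."""


def canonical_angle(angle: float) -> float:
    """Map an angle in degrees to the canonical range (-180, 180]."""
    a = float(np.remainder(angle, 360.0))
    if a > 180.0:
        a -= 360.0
    return a


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points, IUPAC convention.

    Looking from p2 toward p3, the angle is positive when p4 is rotated
    clockwise relative to p1.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n2 = np.linalg.norm(b2)
    if n2 < _COLLINEAR_TOL:
        raise GeometryError("coincident central atoms")
    c12 = np.cross(b1, b2)
    c23 = np.cross(b2, b3)
    if np.linalg.norm(c12) < _COLLINEAR_TOL or np.linalg.norm(c23) < _COLLINEAR_TOL:
        raise GeometryError("collinear points in dihedral")
    x = float(np.dot(c12, c23))
    y = float(np.dot(np.cross(b2 / n2, c12), c23))
    return canonical_angle(np.degrees(np.arctan2(y, x)))


@dataclass(frozen=True)
class BackboneTorsions:
    phi: Optional[float] = None
    psi: Optional[float] = None
    omega: Optional[float] = None


@dataclass(frozen=True)
class SidechainTorsions:
    chi1: Optional[float] = None
    chi2: Optional[float] = None
    n_chi: int = 0


class OmegaClass(Enum):
    TRANS = "trans"
    CIS = "cis"
    TWISTED = "twisted"


@dataclass(frozen=True)
class TorsionDelta:
    """Per-torsion minimal angular deviations of a model from the target."""

    d_phi: Optional[float] = None
    d_psi: Optional[float] = None
    d_omega: Optional[float] = None
    d_chi1: Optional[float] = None
    d_chi2: Optional[float] = None
    omega_flip: bool = False
    omega_twist: bool = False


def _positions(residue: Optional[ResidueRecord], *names: str):
    if residue is None:
        return None
    out = []
    for name in names:
        atom = residue.get_atom(name)
        if atom is None:
            return None
        out.append(atom.position)
    return out


def _safe_dihedral(points) -> Optional[float]:
    if points is None:
        return None
    try:
        return dihedral(*points)
    except GeometryError:
        return None


def backbone_torsions(chain: Sequence[ResidueRecord], index: int) -> BackboneTorsions:
    """phi/psi/omega of chain[index]; absent at termini or missing atoms."""
    res = chain[index]
    prev = chain[index - 1] if index > 0 else None
    nxt = chain[index + 1] if index < len(chain) - 1 else None

    phi = psi = omega = None
    own = _positions(res, "N", "CA", "C")
    if own is not None:
        n, ca, c = own
        prev_c = _positions(prev, "C")
        if prev_c is not None:
            phi = _safe_dihedral([prev_c[0], n, ca, c])
        next_n = _positions(nxt, "N")
        if next_n is not None:
            psi = _safe_dihedral([n, ca, c, next_n[0]])
    n_ca = _positions(res, "N", "CA")
    prev_ca_c = _positions(prev, "CA", "C")
    if n_ca is not None and prev_ca_c is not None:
        omega = _safe_dihedral([prev_ca_c[0], prev_ca_c[1], n_ca[0], n_ca[1]])
    return BackboneTorsions(phi=phi, psi=psi, omega=omega)


def chi_torsions(residue: ResidueRecord) -> SidechainTorsions:
    """chi1/chi2 by the standard atom quadruples; absent if atoms missing."""
    res_type = residue.standard_type
    if res_type is None:
        return SidechainTorsions(n_chi=0)
    n_chi = N_CHI.get(res_type, 0)
    chi1 = chi2 = None
    if n_chi >= 1:
        chi1 = _safe_dihedral(
            _positions(residue, "N", "CA", "CB", CHI1_ATOM[res_type]))
    if n_chi >= 2:
        third, fourth = CHI2_ATOMS[res_type]
        chi2 = _safe_dihedral(_positions(residue, "CA", "CB", third, fourth))
    return SidechainTorsions(chi1=chi1, chi2=chi2, n_chi=n_chi)


def angular_delta(a: float, b: float, symmetry_order: int = 1) -> float:
    """Minimal distance between two angles on the circle, degrees.

    ``symmetry_order=2`` treats values 180 degrees apart as equivalent
    (chemically 2-fold symmetric terminal torsions), so the result is
    the minimum over the torsion and its 180-degree alternative.
    """
    if symmetry_order not in (1, 2):
        raise ValueError("symmetry_order must be 1 or 2")
    period = 360.0 / symmetry_order
    d = abs(float(np.remainder(a - b, period)))
    return min(d, period - d)


def classify_omega(omega: float, twist_cutoff: float = TWIST_CUTOFF) -> OmegaClass:
    """trans / cis / twisted classification of a peptide-bond torsion.

    Deviations of exactly ``twist_cutoff`` from a planar configuration
    are assigned to the planar (non-twisted) class.
    """
    omega = canonical_angle(omega)
    if abs(omega) <= twist_cutoff:
        return OmegaClass.CIS
    if 180.0 - abs(omega) <= twist_cutoff:
        return OmegaClass.TRANS
    return OmegaClass.TWISTED


def _delta_or_none(a: Optional[float], b: Optional[float],
                   symmetry_order: int = 1) -> Optional[float]:
    if a is None or b is None:
        return None
    return angular_delta(a, b, symmetry_order)


def torsion_delta(pair: ResiduePair,
                  target_bb: Optional[BackboneTorsions] = None,
                  model_bb: Optional[BackboneTorsions] = None,
                  chi_symmetry: bool = True,
                  twist_cutoff: float = TWIST_CUTOFF) -> TorsionDelta:
    """Torsion deltas for one matched residue pair.

    Backbone torsions require chain context, so callers that have it
    (``score_model``) pass precomputed :class:`BackboneTorsions`; with
    the default ``None`` the corresponding deltas are absent.

    Sidechain rules: a chi torsion present in the target but absent in
    the model (unmodeled atoms or a mutation) scores the maximal delta
    of 180 degrees; torsions present only in the model are ignored.
    With ``chi_symmetry``, chi2 of Asp/Phe/Tyr is compared modulo 180.
    """
    target = pair.target_residue
    model = pair.model_residue
    t_bb = target_bb or BackboneTorsions()
    m_bb = model_bb or BackboneTorsions()

    d_phi = _delta_or_none(t_bb.phi, m_bb.phi)
    d_psi = _delta_or_none(t_bb.psi, m_bb.psi)
    d_omega = _delta_or_none(t_bb.omega, m_bb.omega)

    omega_flip = omega_twist = False
    if m_bb.omega is not None:
        m_class = classify_omega(m_bb.omega, twist_cutoff)
        omega_twist = m_class is OmegaClass.TWISTED
        if t_bb.omega is not None:
            t_class = classify_omega(t_bb.omega, twist_cutoff)
            omega_flip = (
                {t_class, m_class} == {OmegaClass.CIS, OmegaClass.TRANS})

    t_chi = chi_torsions(target)
    m_chi = chi_torsions(model) if model is not None else SidechainTorsions()

    res_type = target.standard_type
    sym2 = 2 if (chi_symmetry and res_type in CHI2_SYMMETRIC) else 1

    d_chi1 = d_chi2 = None
    if t_chi.chi1 is not None:
        d_chi1 = 180.0 if m_chi.chi1 is None else angular_delta(t_chi.chi1, m_chi.chi1)
    if t_chi.chi2 is not None:
        # Missing model torsions take the literal maximum of 180 even for
        # symmetry-corrected torsions: unmodeled is worse than wrong.
        d_chi2 = (180.0 if m_chi.chi2 is None
                  else angular_delta(t_chi.chi2, m_chi.chi2, sym2))

    return TorsionDelta(d_phi=d_phi, d_psi=d_psi, d_omega=d_omega,
                        d_chi1=d_chi1, d_chi2=d_chi2,
                        omega_flip=omega_flip, omega_twist=omega_twist)
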