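"""Synthetic structures and metric tables with known ground truth.

``build_peptide`` constructs an all-atom polypeptide with ideal bond
lengths/angles and exactly prescribed torsions (natural-extension
placement, NeRF).  ``perturb`` rotates rigid bodies about torsion axes
so the true per-torsion deltas are known exactly, returning a ledger
for oracle comparisons.  ``synth_metric_table`` draws per-model metric
tables with a planted group-quality ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._geometry import (ANGLE_C_CA_CB, ANGLE_C_N_CA, ANGLE_CA_C_N,
                        ANGLE_CA_C_O, ANGLE_N_CA_C, BOND_C_N, BOND_C_O,
                        BOND_CA_C, BOND_CA_CB, BOND_N_CA, CHI1_ATOM,
                        CHI1_MOVERS, CHI2_ATOMS, CHI2_MOVERS, DEFAULT_CHI1,
                        DEFAULT_CHI2, IMPROPER_N_C_CA_CB, N_CHI, ONE_TO_THREE,
                        SIDECHAIN_ZMATRIX, element_of)
from .structure import AtomRecord, ResidueRecord, StructureRecord
from .torsions import canonical_angle

__all__ = [
    "PeptideSpec",
    "PerturbationSpec",
    "PerturbationLedger",
    "build_peptide",
    "perturb",
    "synth_metric_table",
    "METRIC_COLUMNS",
]

TorsionName = str  # "phi" | "psi" | "omega" | "chi1" | "chi2"
DeltaSpec = Union[float, tuple[str, float]]  # value, or ("gauss", sigma)


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    angle = np.radians(angle)
    torsion = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


@dataclass
class PeptideSpec:
    """Recipe for an ideal-geometry polypeptide.

    ``backbone_torsions`` holds one (phi, psi, omega) triple per
    residue; phi of the first and psi/omega entries at the ends that
    have no geometric meaning are simply ignored.  A single triple is
    broadcast over the chain.  ``chi_torsions`` likewise holds
    (chi1, chi2) per residue (entries beyond a residue's torsion count
    are ignored; None picks library defaults).
    """

    sequence: str
    backbone_torsions: Union[tuple, Sequence[tuple]] = (-120.0, 130.0, 180.0)
    chi_torsions: Optional[Sequence[Optional[tuple]]] = None
    chain_id: str = "A"
    identifier: str = "synthetic"
    first_seq_number: int = 1
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError("sequence must have at least 2 residues")
        for letter in self.sequence:
            if letter not in ONE_TO_THREE:
                raise ValueError(f"unsupported residue {letter!r}")

    def torsion_triple(self, i: int) -> tuple[float, float, float]:
        bb = self.backbone_torsions
        if bb and isinstance(bb[0], (int, float)):
            return tuple(bb)  # broadcast
        return tuple(bb[i])

    def chi_pair(self, i: int) -> tuple[float, float]:
        if self.chi_torsions is None or self.chi_torsions[i] is None:
            return (DEFAULT_CHI1, DEFAULT_CHI2)
        pair = self.chi_torsions[i]
        chi1 = pair[0] if pair[0] is not None else DEFAULT_CHI1
        chi2 = pair[1] if len(pair) > 1 and pair[1] is not None else DEFAULT_CHI2
        return (float(chi1), float(chi2))


def _build_sidechain(res_type: str, atoms: dict[str, np.ndarray],
                     chi1: float, chi2: float) -> list[tuple[str, np.ndarray]]:
    placed = []
    for entry in SIDECHAIN_ZMATRIX[res_type]:
        spec = entry.torsion
        if isinstance(spec, tuple):
            base = chi1 if spec[0] == "chi1" else chi2
            torsion = base + spec[1]
        else:
            torsion = spec
        pos = nerf(atoms[entry.refs[0]], atoms[entry.refs[1]],
                   atoms[entry.refs[2]], entry.bond, entry.angle, torsion)
        atoms[entry.name] = pos
        placed.append((entry.name, pos))
    return placed


def build_peptide(spec: PeptideSpec) -> StructureRecord:
    """Build an all-atom chain with exactly the prescribed torsions."""
    residues: list[ResidueRecord] = []
    prev: Optional[dict[str, np.ndarray]] = None

    for i, letter in enumerate(spec.sequence):
        res_type = ONE_TO_THREE[letter]
        phi_i, _, omega_i = spec.torsion_triple(i)
        atoms: dict[str, np.ndarray] = {}
        if prev is None:
            atoms["N"] = np.zeros(3)
            atoms["CA"] = np.array([BOND_N_CA, 0.0, 0.0])
            ang = np.radians(ANGLE_N_CA_C)
            atoms["C"] = atoms["CA"] + BOND_CA_C * np.array(
                [-np.cos(ang), np.sin(ang), 0.0])
        else:
            # N from psi of the previous residue, then omega and phi.
            _, psi_prev, _ = spec.torsion_triple(i - 1)
            atoms["N"] = nerf(prev["N"], prev["CA"], prev["C"],
                              BOND_C_N, ANGLE_CA_C_N, psi_prev)
            atoms["CA"] = nerf(prev["CA"], prev["C"], atoms["N"],
                               BOND_N_CA, ANGLE_C_N_CA, omega_i)
            atoms["C"] = nerf(prev["C"], atoms["N"], atoms["CA"],
                              BOND_CA_C, ANGLE_N_CA_C, phi_i)
        order = ["N", "CA", "C"]
        if res_type != "GLY":
            atoms["CB"] = nerf(atoms["N"], atoms["C"], atoms["CA"],
                               BOND_CA_CB, ANGLE_C_CA_CB, IMPROPER_N_C_CA_CB)
            order.append("CB")
        chi1, chi2 = spec.chi_pair(i)
        for name, _pos in _build_sidechain(res_type, atoms, chi1, chi2):
            order.append(name)
        residues.append(ResidueRecord(
            chain_id=spec.chain_id,
            seq_number=spec.first_seq_number + i,
            insertion_code="",
            res_type=res_type,
            atoms=[AtomRecord(name, element_of(name), atoms[name].copy(),
                              1.0, spec.b_factor, "") for name in order],
            is_polymer=True,
        ))
        prev = atoms

    # Carbonyl oxygens: trans to the next N (psi + 180), terminal O planar.
    for i, res in enumerate(residues):
        n, ca, c = (res.get_atom(x).position for x in ("N", "CA", "C"))
        _, psi_i, _ = spec.torsion_triple(i)
        o = nerf(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0)
        res.atoms.insert(3, AtomRecord("O", "O", o, 1.0, spec.b_factor, ""))

    return StructureRecord(spec.identifier, {spec.chain_id: residues},
                           source_format="memory")


@dataclass
class PerturbationSpec:
    """Torsion-space perturbation with an exact ground-truth ledger.

    ``deltas`` maps a torsion name (phi/psi/omega/chi1/chi2) to either a
    fixed signed delta in degrees or ("gauss", sigma) for seeded normal
    draws.  ``residues`` selects 0-based residue indices (None = all
    residues where the torsion exists).  ``flip_omega_at`` adds 180 to
    the omega of the listed residues; ``truncate_sidechains_at`` deletes
    all sidechain atoms beyond CB.
    """

    deltas: Mapping[TorsionName, DeltaSpec] = field(default_factory=dict)
    residues: Optional[Sequence[int]] = None
    flip_omega_at: Sequence[int] = ()
    truncate_sidechains_at: Sequence[int] = ()
    seed: int = 0


@dataclass
class PerturbationLedger:
    """Applied perturbations: (residue index -> torsion -> signed delta)."""

    applied: dict[int, dict[TorsionName, float]]
    flipped: tuple[int, ...]
    truncated: tuple[int, ...]

    def expected_delta(self, index: int, torsion: TorsionName) -> float:
        """Minimal angular distance implied by the applied signed delta."""
        raw = self.applied.get(index, {}).get(torsion, 0.0)
        if torsion == "omega" and index in self.flipped:
            raw += 180.0
        d = abs(canonical_angle(raw))
        return d


def _rotate(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
            angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    theta = np.radians(angle_deg)
    k = axis
    shifted = points - origin
    return (shifted * np.cos(theta)
            + np.cross(k, shifted) * np.sin(theta)
            + np.outer(shifted @ k, k) * (1 - np.cos(theta))) + origin


_VALID_TORSIONS = ("phi", "psi", "omega", "chi1", "chi2")


def _axis_and_movers(chain: list[ResidueRecord], i: int, torsion: TorsionName):
    """(axis_start, axis_end, moving atom list) for a torsion of residue i.

    Returns None when the torsion does not exist at this position.
    Moving atoms are chosen so that rotating them changes exactly the
    named torsion: downstream backbone for phi/psi/omega, distal
    sidechain atoms for chi1/chi2.
    """
    res = chain[i]
    res_type = res.res_type

    def atom(r, name):
        a = r.get_atom(name)
        return None if a is None else a.position

    downstream = [a for r in chain[i + 1:] for a in r.atoms]
    if torsion == "phi":
        if i == 0:
            return None
        n, ca = atom(res, "N"), atom(res, "CA")
        movers = [res.get_atom("C"), res.get_atom("O")] + downstream
        return n, ca, [m for m in movers if m is not None]
    if torsion == "psi":
        if i == len(chain) - 1:
            return None
        ca, c = atom(res, "CA"), atom(res, "C")
        movers = [res.get_atom("O")] + downstream
        return ca, c, [m for m in movers if m is not None]
    if torsion == "omega":
        if i == 0:
            return None
        c_prev, n = atom(chain[i - 1], "C"), atom(res, "N")
        # N(i) lies on the axis, so including it is harmless.
        movers = [a for r in chain[i:] for a in r.atoms]
        return c_prev, n, movers
    if torsion == "chi1":
        if N_CHI.get(res_type, 0) < 1 or res.get_atom(CHI1_ATOM.get(res_type, "")) is None:
            return None
        ca, cb = atom(res, "CA"), atom(res, "CB")
        names = CHI1_MOVERS[res_type]
        return ca, cb, [a for a in res.atoms if a.name in names]
    if torsion == "chi2":
        if N_CHI.get(res_type, 0) < 2:
            return None
        third, fourth = CHI2_ATOMS[res_type]
        if res.get_atom(third) is None or res.get_atom(fourth) is None:
            return None
        cb, g = atom(res, "CB"), atom(res, third)
        names = CHI2_MOVERS[res_type]
        return cb, g, [a for a in res.atoms if a.name in names]
    raise ValueError(f"unknown torsion {torsion!r}")


def _apply_rotation(chain: list[ResidueRecord], i: int,
                    torsion: TorsionName, delta: float) -> bool:
    """Rotate the moving set so the named torsion changes by +delta."""
    spec = _axis_and_movers(chain, i, torsion)
    if spec is None:
        return False
    start, end, movers = spec
    if not movers:
        return False
    points = np.array([a.position for a in movers])
    # Right-handed rotation about the axis increases the IUPAC dihedral.
    rotated = _rotate(points, start, end - start, delta)
    for a, p in zip(movers, rotated):
        a.position = p
    return True


def perturb(base: StructureRecord, pspec: PerturbationSpec,
            ) -> tuple[StructureRecord, PerturbationLedger]:
    """Apply a torsion-space perturbation, returning the exact ledger.

    Operates on single-chain structures from :func:`build_peptide`.
    """
    out = base.copy()
    chain_ids = list(out.chains)
    if len(chain_ids) != 1:
        raise ValueError("perturb expects a single-chain structure")
    chain = [r for r in out.chains[chain_ids[0]] if r.is_polymer]
    n = len(chain)
    rng = np.random.default_rng(pspec.seed)

    for idx in list(pspec.flip_omega_at) + list(pspec.truncate_sidechains_at):
        if not 0 <= idx < n:
            raise IndexError(f"residue index {idx} out of range")
    if pspec.residues is not None:
        for idx in pspec.residues:
            if not 0 <= idx < n:
                raise IndexError(f"residue index {idx} out of range")

    targets = (list(pspec.residues) if pspec.residues is not None
               else list(range(n)))
    applied: dict[int, dict[TorsionName, float]] = {}

    for torsion in _VALID_TORSIONS:
        if torsion not in pspec.deltas:
            continue
        dspec = pspec.deltas[torsion]
        for i in targets:
            if isinstance(dspec, tuple):
                if dspec[0] != "gauss":
                    raise ValueError(f"unknown delta distribution {dspec[0]!r}")
                delta = float(rng.normal(0.0, dspec[1]))
            else:
                delta = float(dspec)
            if _apply_rotation(chain, i, torsion, delta):
                applied.setdefault(i, {})[torsion] = delta

    for i in pspec.flip_omega_at:
        if not _apply_rotation(chain, i, "omega", 180.0):
            raise ValueError(f"cannot flip omega of residue {i}")

    for i in pspec.truncate_sidechains_at:
        res = chain[i]
        drop = CHI1_MOVERS.get(res.res_type, frozenset())
        res.atoms = [a for a in res.atoms if a.name not in drop]

    ledger = PerturbationLedger(applied=applied,
                                flipped=tuple(pspec.flip_omega_at),
                                truncated=tuple(pspec.truncate_sidechains_at))
    return out, ledger


METRIC_COLUMNS = ["GDT_HA", "GDT_TS", "lDDT", "CADaa", "SG", "ASE",
                  "clashscore", "mean_backbone", "mean_sidechain"]

_HIGHER_BETTER = {"GDT_HA": True, "GDT_TS": True, "lDDT": True,
                  "CADaa": True, "SG": True, "ASE": True,
                  "clashscore": False, "mean_backbone": False,
                  "mean_sidechain": False}

_BASE = {"GDT_HA": 50.0, "GDT_TS": 60.0, "lDDT": 60.0, "CADaa": 50.0,
         "SG": 60.0, "ASE": 70.0, "clashscore": 30.0,
         "mean_backbone": 0.25, "mean_sidechain": 0.3}

_NOISE_SD = {"GDT_HA": 10.0, "GDT_TS": 10.0, "lDDT": 8.0, "CADaa": 8.0,
             "SG": 10.0, "ASE": 8.0, "clashscore": 10.0,
             "mean_backbone": 0.05, "mean_sidechain": 0.05}


def synth_metric_table(n_groups: int, n_targets: int,
                       effect_sd: float = 3.0, seed: int = 0,
                       n_models: int = 5,
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Random metric table with a planted group-quality ordering.

    Group ``G01`` is planted best; adjacent groups are separated by
    ``effect_sd`` noise standard deviations on every metric (oriented
    appropriately).  Values are not clipped to physical ranges — only
    the rank structure matters.  Returns (table, planted order,
    best group first).
    """
    if n_groups < 2 or n_targets < 1:
        raise ValueError("need at least 2 groups and 1 target")
    rng = np.random.default_rng(seed)
    groups = [f"G{i + 1:02d}" for i in range(n_groups)]
    rows = []
    for t in range(n_targets):
        target = f"T{t + 1:04d}"
        for g, group in enumerate(groups):
            # quality decreases with group index
            shift = -effect_sd * g
            for m in range(1, n_models + 1):
                row = {"group": group, "target": target, "model_index": m}
                for col in METRIC_COLUMNS:
                    sd = _NOISE_SD[col]
                    signed = shift if _HIGHER_BETTER[col] else -shift
                    row[col] = _BASE[col] + signed * sd + rng.normal(0.0, sd)
                rows.append(row)
    return pd.DataFrame(rows), groups
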