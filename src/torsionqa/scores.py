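"""Per-residue and per-model torsion-space conformation scores.

The unit dihedral score is the normalized squared chord length on the
unit circle, gamma(delta) = (1 - cos delta) / 2, in [0, 1] with 0 for a
perfect match.  Backbone residues average gamma over phi/psi/omega;
sidechains combine chi1 and chi2 with a burial weight beta derived from
the target's packing so that fully exposed sidechains (for which there
is often no single correct answer) do not contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geometry import N_CHI, N_SC
from .structure import (PairingError, ResidueRecord, StructureRecord,
                        pair_residues)
from .torsions import (BackboneTorsions, TorsionDelta, backbone_torsions,
                       torsion_delta)

__all__ = [
    "ScoreParams",
    "ResidueScore",
    "ModelTorsionSummary",
    "gamma",
    "backbone_score",
    "burial",
    "BurialCalculator",
    "sidechain_score",
    "score_model",
    "compare_template_model",
    "superpose_ca",
]


@dataclass(frozen=True)
class ScoreParams:
    """Tunable constants of the torsion scores."""

    tau: float = 30.0                    # degrees; chi2 down-weight scale
    burial_contact_cutoff: float = 4.0   # Å; neighbor distance for beta
    twist_cutoff: float = 30.0           # degrees; omega twist threshold
    chi_symmetry: bool = True            # compare symmetric chi2 modulo 180
    include_hetero_neighbors: bool = True  # ligands/other chains count for beta

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.burial_contact_cutoff <= 0 or self.twist_cutoff <= 0:
            raise ValueError("ScoreParams values must be positive")


@dataclass
class ResidueScore:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_type: str
    s_backbone: Optional[float] = None
    s_sidechain: Optional[float] = None
    beta: Optional[float] = None
    n_close: int = 0
    n_sc: int = 0
    omega_flip: bool = False
    omega_twist: bool = False
    mutated: bool = False
    model_present: bool = False
    delta: Optional[TorsionDelta] = None


@dataclass
class ModelTorsionSummary:
    mean_backbone: Optional[float]
    mean_sidechain: Optional[float]
    n_flips: int
    n_twists: int
    n_residues_scored: int
    n_backbone_scored: int = 0
    n_sidechain_scored: int = 0


def gamma(delta: float) -> float:
    """Unit chord score (1 - cos delta)/2 for a delta in [0, 180] degrees."""
    if not 0.0 <= delta <= 180.0:
        raise ValueError(f"delta {delta} outside [0, 180]")
    return (1.0 - math.cos(math.radians(delta))) / 2.0


def backbone_score(delta: TorsionDelta) -> Optional[float]:
    """Mean gamma over the defined subset of (d_phi, d_psi, d_omega).

    At chain termini some torsions are undefined; the mean is then
    renormalized over the defined ones.  All three absent -> None.
    """
    terms = [gamma(d) for d in (delta.d_phi, delta.d_psi, delta.d_omega)
             if d is not None]
    if not terms:
        return None
    return float(sum(terms) / len(terms))


class BurialCalculator:
    """Counts, for each residue of a structure, the heavy atoms of other
    residues within a distance cutoff — the n_close of the burial score.

    Waters never count as neighbors; ligand atoms and other chains do by
    default (switchable via ``ScoreParams.include_hetero_neighbors``).
    """

    def __init__(self, structure: StructureRecord,
                 params: ScoreParams = ScoreParams()):
        self.params = params
        positions = []
        owners = []
        for idx, res in enumerate(structure.residues()):
            if res.res_type in ("HOH", "WAT", "DOD"):
                continue
            if not res.is_polymer and not params.include_hetero_neighbors:
                continue
            for atom in res.heavy_atoms():
                positions.append(atom.position)
                owners.append(idx)
        self._owners = np.asarray(owners, dtype=int)
        self._tree = cKDTree(np.asarray(positions)) if positions else None
        self._index_of = {res.key: idx
                          for idx, res in enumerate(structure.residues())}

    def n_close(self, residue: ResidueRecord) -> int:
        if self._tree is None:
            return 0
        own_idx = self._index_of.get(residue.key, -1)
        coords = [a.position for a in residue.heavy_atoms()]
        if not coords:
            return 0
        hits: set[int] = set()
        for group in self._tree.query_ball_point(
                np.asarray(coords), r=self.params.burial_contact_cutoff):
            hits.update(group)
        return sum(1 for h in hits if self._owners[h] != own_idx)


def burial(target_residue: ResidueRecord, target_structure: StructureRecord,
           params: ScoreParams = ScoreParams(),
           calculator: Optional[BurialCalculator] = None,
           ) -> tuple[Optional[float], int, int]:
    """(beta, n_close, n_sc) for one residue of the target structure.

    beta = min(n_close / (3 * n_sc), 1); undefined (None) when the
    residue type has no canonical sidechain heavy atoms (glycine).
    """
    if not target_residue.heavy_atoms():
        raise ValueError("residue has no heavy atoms")
    calc = calculator or BurialCalculator(target_structure, params)
    n_close = calc.n_close(target_residue)
    res_type = target_residue.standard_type
    n_sc = N_SC.get(res_type, 0) if res_type else 0
    if n_sc == 0:
        return None, n_close, 0
    beta = min(n_close / (3.0 * n_sc), 1.0)
    return beta, n_close, n_sc


def sidechain_score(delta: TorsionDelta, n_chi: int, beta: float,
                    params: ScoreParams = ScoreParams()) -> float:
    """Burial-weighted sidechain conformation score in [0, 1].

    For a single-torsion sidechain this is beta * gamma(d_chi1);
    otherwise chi2 contributes only while chi1 is approximately right:

        beta * [1 - (2/3)(1 - gamma(d_chi1))
                  - (1/3) exp(-(d_chi1/tau)^2) (1 - gamma(d_chi2))]
    """
    if n_chi < 1:
        raise ValueError("sidechain_score requires n_chi >= 1")
    if delta.d_chi1 is None:
        raise ValueError("d_chi1 undefined; missing chi handling is upstream")
    g1 = gamma(delta.d_chi1)
    if n_chi == 1:
        return beta * g1
    g2 = gamma(delta.d_chi2) if delta.d_chi2 is not None else 1.0
    damp = math.exp(-((delta.d_chi1 / params.tau) ** 2))
    return beta * (1.0 - (2.0 / 3.0) * (1.0 - g1)
                   - (1.0 / 3.0) * damp * (1.0 - g2))


def _residue_chain_index(structure: StructureRecord):
    """Map residue key -> (polymer chain residue list, index)."""
    out = {}
    for cid in structure.chains:
        chain = [r for r in structure.chains[cid] if r.is_polymer]
        for i, res in enumerate(chain):
            out[res.key] = (chain, i)
    return out


def score_model(target: StructureRecord, model: StructureRecord,
                params: ScoreParams = ScoreParams(),
                pairing_mode: Literal["numbering", "alignment"] = "numbering",
                ) -> tuple[list[ResidueScore], ModelTorsionSummary]:
    """Score every target polymer residue against the paired model residue.

    Returns one :class:`ResidueScore` per target polymer residue (scores
    absent where the model residue is missing or the target has no chi
    torsions) and the per-model aggregate summary, whose means run over
    scored residues only.
    """
    pairs = pair_residues(target, model, mode=pairing_mode)
    burial_calc = BurialCalculator(target, params)
    t_index = _residue_chain_index(target)
    m_index = _residue_chain_index(model)

    scores: list[ResidueScore] = []
    for pair in pairs:
        t_res = pair.target_residue
        chain_t, i_t = t_index[t_res.key]
        t_bb = backbone_torsions(chain_t, i_t)
        m_bb = BackboneTorsions()
        if pair.model_residue is not None:
            chain_m, i_m = m_index[pair.model_residue.key]
            m_bb = backbone_torsions(chain_m, i_m)

        rs = ResidueScore(
            chain_id=t_res.chain_id, seq_number=t_res.seq_number,
            insertion_code=t_res.insertion_code, res_type=t_res.res_type,
            mutated=pair.mutated, model_present=pair.model_residue is not None,
        )
        beta, n_close, n_sc = burial(t_res, target, params, burial_calc)
        rs.beta, rs.n_close, rs.n_sc = beta, n_close, n_sc

        if pair.model_residue is not None:
            delta = torsion_delta(pair, t_bb, m_bb,
                                  chi_symmetry=params.chi_symmetry,
                                  twist_cutoff=params.twist_cutoff)
            rs.delta = delta
            rs.omega_flip = delta.omega_flip
            rs.omega_twist = delta.omega_twist
            rs.s_backbone = backbone_score(delta)
            res_type = t_res.standard_type
            n_chi = N_CHI.get(res_type, 0) if res_type else 0
            # Gly/Ala and target-side truncations receive no sidechain score.
            if n_chi >= 1 and delta.d_chi1 is not None and beta is not None:
                rs.s_sidechain = sidechain_score(delta, n_chi, beta, params)
        scores.append(rs)

    bb = [s.s_backbone for s in scores if s.s_backbone is not None]
    sc = [s.s_sidechain for s in scores if s.s_sidechain is not None]
    summary = ModelTorsionSummary(
        mean_backbone=float(np.mean(bb)) if bb else None,
        mean_sidechain=float(np.mean(sc)) if sc else None,
        n_flips=sum(s.omega_flip for s in scores),
        n_twists=sum(s.omega_twist for s in scores),
        n_residues_scored=sum(s.model_present for s in scores),
        n_backbone_scored=len(bb),
        n_sidechain_scored=len(sc),
    )
    return scores, summary


def superpose_ca(target: StructureRecord, other: StructureRecord,
                 mode: Literal["numbering", "alignment"] = "numbering",
                 ) -> dict[tuple[str, int, str], float]:
    """Least-squares superpose *other* onto *target* on shared CA atoms.

    Returns per-target-residue CA residual distances (Å) after the
    rigid-body fit, keyed by target residue key.
    """
    pairs = pair_residues(target, other, mode=mode)
    t_pts, o_pts, keys = [], [], []
    for pair in pairs:
        if pair.model_residue is None:
            continue
        t_ca = pair.target_residue.get_atom("CA")
        o_ca = pair.model_residue.get_atom("CA")
        if t_ca is None or o_ca is None:
            continue
        t_pts.append(t_ca.position)
        o_pts.append(o_ca.position)
        keys.append(pair.target_residue.key)
    if len(t_pts) < 3:
        raise PairingError("fewer than 3 shared CA atoms for superposition")
    T = np.asarray(t_pts)
    O = np.asarray(o_pts)
    ct, co = T.mean(axis=0), O.mean(axis=0)
    H = (O - co).T @ (T - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    moved = (O - co) @ R.T + ct
    residuals = np.linalg.norm(moved - T, axis=1)
    return {key: float(r) for key, r in zip(keys, residuals)}


def compare_template_model(target: StructureRecord, model: StructureRecord,
                           template: StructureRecord,
                           params: ScoreParams = ScoreParams(),
                           model_pairing: Literal["numbering", "alignment"] = "numbering",
                           ) -> pd.DataFrame:
    """Per-residue comparison of model and template against the target.

    One row per target polymer residue with the backbone/sidechain
    scores of both comparisons, their (model - template) differences
    (negative = the model improved on the template), and CA residual
    distances after independent rigid-body superpositions.
    """
    model_scores, _ = score_model(target, model, params, model_pairing)
    template_scores, _ = score_model(target, template, params, "alignment")
    shared = any(m.model_present and t.model_present
                 for m, t in zip(model_scores, template_scores))
    if not shared:
        raise PairingError("model and template share no scored residues")

    ca_model = superpose_ca(target, model, model_pairing)
    ca_template = superpose_ca(target, template, "alignment")

    def diff(a: Optional[float], b: Optional[float]) -> Optional[float]:
        if a is None or b is None:
            return None
        return a - b

    rows = []
    for ms, ts in zip(model_scores, template_scores):
        key = (ms.chain_id, ms.seq_number, ms.insertion_code)
        rows.append({
            "chain": ms.chain_id,
            "seq": ms.seq_number,
            "icode": ms.insertion_code,
            "res_type": ms.res_type,
            "model_backbone": ms.s_backbone,
            "template_backbone": ts.s_backbone,
            "d_backbone": diff(ms.s_backbone, ts.s_backbone),
            "model_sidechain": ms.s_sidechain,
            "template_sidechain": ts.s_sidechain,
            "d_sidechain": diff(ms.s_sidechain, ts.s_sidechain),
            "model_ca_residual": ca_model.get(key),
            "template_ca_residual": ca_template.get(key),
            "model_omega_flip": ms.omega_flip,
            "model_omega_twist": ms.omega_twist,
            "template_omega_flip": ts.omega_flip,
            "template_omega_twist": ts.omega_twist,
        })
    return pd.DataFrame(rows)


def residue_scores_frame(scores: list[ResidueScore]) -> pd.DataFrame:
    """Tabulate per-residue scores (the per-residue CSV report)."""
    rows = []
    for s in scores:
        d = s.delta or TorsionDelta()
        rows.append({
            "chain": s.chain_id, "seq": s.seq_number, "icode": s.insertion_code,
            "res_type": s.res_type, "model_present": s.model_present,
            "mutated": s.mutated,
            "d_phi": d.d_phi, "d_psi": d.d_psi, "d_omega": d.d_omega,
            "d_chi1": d.d_chi1, "d_chi2": d.d_chi2,
            "beta": s.beta, "n_close": s.n_close, "n_sc": s.n_sc,
            "s_backbone": s.s_backbone, "s_sidechain": s.s_sidechain,
            "omega_flip": s.omega_flip, "omega_twist": s.omega_twist,
        })
    return pd.DataFrame(rows)
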