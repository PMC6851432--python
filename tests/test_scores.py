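import math

import numpy as np
import pytest

from torsionqa._geometry import N_CHI, N_SC
from torsionqa.scores import (ScoreParams, backbone_score, burial,
                              compare_template_model, gamma, score_model,
                              sidechain_score, superpose_ca)
from torsionqa.structure import AtomRecord, ResidueRecord, StructureRecord
from torsionqa.synth import (PeptideSpec, PerturbationSpec, build_peptide,
                             perturb)
from torsionqa.torsions import TorsionDelta


class TestGamma:
    @pytest.mark.parametrize("delta,expected", [
        (0.0, 0.0),
        (180.0, 1.0),
        (90.0, 0.5),
        (60.0, 0.25),
    ])
    def test_closed_form(self, delta, expected):
        assert gamma(delta) == pytest.approx(expected, abs=1e-12)

    def test_monotone_increasing(self):
        grid = np.linspace(0, 180, 361)
        vals = [gamma(d) for d in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            gamma(-1.0)
        with pytest.raises(ValueError):
            gamma(180.5)


class TestBackboneScore:
    def test_zero(self):
        assert backbone_score(TorsionDelta(0.0, 0.0, 0.0)) == 0.0

    def test_one(self):
        assert backbone_score(TorsionDelta(180.0, 180.0, 180.0)) == 1.0

    def test_half(self):
        assert backbone_score(TorsionDelta(90.0, 90.0, 90.0)) == pytest.approx(0.5)

    def test_terminus_renormalized(self):
        # two defined torsions at 90 -> mean of two gamma=0.5 terms
        assert backbone_score(TorsionDelta(90.0, 90.0, None)) == pytest.approx(0.5)

    def test_all_absent(self):
        assert backbone_score(TorsionDelta()) is None


def _lone_residue_structure(extra_positions=()):
    """A LEU residue plus an optional cloud of foreign heavy atoms."""
    leu = build_peptide(PeptideSpec("GLG")).polymer_residues()[1].copy()
    chains = {"A": [leu]}
    if extra_positions is not None:
        other = ResidueRecord("A", 99, "", "GLY", [
            AtomRecord(f"C{i}", "C", np.asarray(p, float))
            for i, p in enumerate(extra_positions)], is_polymer=False)
        if extra_positions:
            chains["A"] = [leu, other]
    return StructureRecord("lone", chains), chains["A"][0]


class TestBurial:
    def test_isolated_residue_beta_zero(self):
        structure, res = _lone_residue_structure(())
        beta, n_close, n_sc = burial(res, structure)
        assert n_close == 0
        assert beta == 0.0
        assert n_sc == 4  # LEU

    def test_saturation(self):
        # 13 foreign atoms right next to CA -> n_close >= 12 -> beta 1
        ca = None
        structure, res = _lone_residue_structure(None)
        ca = res.get_atom("CA").position
        cloud = [ca + [0.1 * i, 1.0, 0.0] for i in range(13)]
        structure, res = _lone_residue_structure(cloud)
        beta, n_close, n_sc = burial(res, structure)
        assert n_close == 13
        assert beta == 1.0

    def test_hand_computed_fraction(self):
        structure, res = _lone_residue_structure(None)
        ca = res.get_atom("CA").position
        cloud = [ca + [0.2 * i, 1.5, 0.0] for i in range(6)]
        structure, res = _lone_residue_structure(cloud)
        beta, n_close, n_sc = burial(res, structure)
        assert n_close == 6
        assert beta == pytest.approx(6 / (3 * 4))

    def test_glycine_beta_undefined(self):
        s = build_peptide(PeptideSpec("AGA"))
        gly = s.polymer_residues()[1]
        beta, n_close, n_sc = burial(gly, s)
        assert beta is None and n_sc == 0

    def test_waters_excluded(self):
        structure, res = _lone_residue_structure(None)
        ca = res.get_atom("CA").position
        structure, res = _lone_residue_structure([ca + [0.0, 1.5, 0.0]])
        structure.chains["A"][1].res_type = "HOH"
        beta, n_close, _ = burial(res, structure)
        assert n_close == 0 and beta == 0.0


class TestSidechainScore:
    def test_chi1_match_chi2_flip_is_one_third(self):
        delta = TorsionDelta(d_chi1=0.0, d_chi2=180.0)
        assert sidechain_score(delta, 2, 1.0) == pytest.approx(1 / 3, rel=1e-12)

    def test_perfect_is_zero(self):
        assert sidechain_score(TorsionDelta(d_chi1=0.0, d_chi2=0.0), 2, 1.0) \
            == pytest.approx(0.0, abs=1e-12)

    def test_chi1_flip_is_one(self):
        score = sidechain_score(TorsionDelta(d_chi1=180.0, d_chi2=0.0), 2, 1.0)
        assert score == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_interior_point(self):
        # gamma(30)=0.066987, e^-1=0.367879: 1 - 0.622008 - 0.122626
        delta = TorsionDelta(d_chi1=30.0, d_chi2=0.0)
        assert sidechain_score(delta, 2, 1.0) == pytest.approx(0.25536, abs=5e-5)

    def test_single_chi(self):
        delta = TorsionDelta(d_chi1=90.0)
        assert sidechain_score(delta, 1, 0.5) == pytest.approx(0.25)

    def test_beta_scales_linearly(self):
        delta = TorsionDelta(d_chi1=70.0, d_chi2=120.0)
        full = sidechain_score(delta, 2, 1.0)
        assert sidechain_score(delta, 2, 0.25) == pytest.approx(0.25 * full)

    def test_monotone_in_both_deltas(self):
        grid = np.linspace(0, 180, 37)
        for d2 in (0.0, 60.0, 120.0, 180.0):
            vals = [sidechain_score(TorsionDelta(d_chi1=d1, d_chi2=d2), 2, 1.0)
                    for d1 in grid]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        for d1 in (0.0, 20.0, 45.0, 90.0, 180.0):
            vals = [sidechain_score(TorsionDelta(d_chi1=d1, d_chi2=d2), 2, 1.0)
                    for d2 in grid]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_chi2_negligible_beyond_50(self):
        bound = math.exp(-((50.0 / 30.0) ** 2)) / 3.0
        assert bound == pytest.approx(0.0207, abs=5e-4)
        for d1 in np.linspace(50, 180, 27):
            lo = sidechain_score(TorsionDelta(d_chi1=d1, d_chi2=0.0), 2, 1.0)
            hi = sidechain_score(TorsionDelta(d_chi1=d1, d_chi2=180.0), 2, 1.0)
            assert hi - lo < bound + 1e-12

    def test_range(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            delta = TorsionDelta(d_chi1=rng.uniform(0, 180),
                                 d_chi2=rng.uniform(0, 180))
            s = sidechain_score(delta, 2, rng.uniform(0, 1))
            assert 0.0 <= s <= 1.0


class TestScoreModel:
    def test_identity_is_zero(self, mixed):
        scores, summary = score_model(mixed, mixed)
        assert summary.mean_backbone == pytest.approx(0.0, abs=1e-12)
        assert summary.mean_sidechain == pytest.approx(0.0, abs=1e-12)
        assert summary.n_flips == 0 and summary.n_twists == 0
        for s in scores:
            if s.s_backbone is not None:
                assert s.s_backbone == pytest.approx(0.0, abs=1e-12)

    def test_scores_in_unit_interval(self, mixed):
        model, _ = perturb(mixed, PerturbationSpec(
            deltas={"phi": ("gauss", 40.0), "chi1": ("gauss", 60.0)}, seed=3))
        scores, _ = score_model(mixed, model)
        for s in scores:
            for v in (s.s_backbone, s.s_sidechain):
                if v is not None:
                    assert 0.0 <= v <= 1.0

    def test_chi1_flip_closed_form(self, mixed):
        model, _ = perturb(mixed, PerturbationSpec(deltas={"chi1": 180.0}))
        scores, _ = score_model(mixed, model)
        for s in scores:
            res_type = s.res_type
            if N_CHI.get(res_type, 0) < 1 or s.s_sidechain is None:
                continue
            d = s.delta
            assert d.d_chi1 == pytest.approx(180.0, abs=1e-6)
            expected = sidechain_score(d, N_CHI[res_type], s.beta)
            assert s.s_sidechain == pytest.approx(expected, rel=1e-12)
            if N_CHI[res_type] == 1:
                # beta * gamma(180) = beta exactly
                assert s.s_sidechain == pytest.approx(s.beta, rel=1e-9)

    def test_missing_residues_bookkeeping(self, mixed):
        partial = mixed.copy()
        partial.chains["A"] = partial.chains["A"][:10]
        _, summary = score_model(mixed, partial)
        assert summary.n_residues_scored == 10

    def test_exposed_residues_contribute_zero(self):
        # a fully extended, exposed chain: every sidechain far from others
        s = build_peptide(PeptideSpec("GLLLLG", backbone_torsions=(-140.0, 140.0, 180.0)))
        model, _ = perturb(s, PerturbationSpec(deltas={"chi1": 120.0}))
        scores, _ = score_model(s, model)
        for sc in scores:
            if sc.s_sidechain is not None and sc.n_close == 0:
                assert sc.s_sidechain == 0.0

    def test_gly_ala_receive_no_sidechain_score(self, mixed):
        scores, _ = score_model(mixed, mixed)
        for s in scores:
            if s.res_type in ("GLY", "ALA"):
                assert s.s_sidechain is None


class TestCompareTemplateModel:
    def test_template_equals_model_zero_deltas(self, mixed):
        frame = compare_template_model(mixed, mixed, mixed)
        assert np.allclose(frame["d_backbone"].dropna(), 0.0)
        assert np.allclose(frame["d_sidechain"].dropna(), 0.0)

    def test_identical_ca_residuals_zero(self, mixed):
        residuals = superpose_ca(mixed, mixed)
        assert all(abs(v) < 1e-9 for v in residuals.values())

    def test_model_improving_one_residue(self, mixed):
        template, _ = perturb(mixed, PerturbationSpec(
            deltas={"phi": 60.0}, residues=[5]))
        frame = compare_template_model(mixed, mixed, template)
        deltas = frame["d_backbone"].to_numpy(dtype=float)
        assert deltas[5] < 0
        others = np.delete(deltas, 5)
        assert np.allclose(others[np.isfinite(others)], 0.0, atol=1e-9)

    def test_superposition_invariant_to_rigid_motion(self, mixed):
        from scipy.spatial.transform import Rotation
        moved = mixed.copy()
        R = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        for res in moved.residues():
            for atom in res.atoms:
                atom.position = R @ atom.position + np.array([5.0, -3.0, 8.0])
        residuals = superpose_ca(mixed, moved)
        assert all(abs(v) < 1e-6 for v in residuals.values())


class TestScoreParams:
    def test_positive_required(self):
        with pytest.raises(ValueError):
            ScoreParams(tau=-1.0)
        with pytest.raises(ValueError):
            ScoreParams(burial_contact_cutoff=0.0)

    def test_nsc_table_consistency(self):
        # every residue type with chi torsions has sidechain atoms
        for res_type, n in N_CHI.items():
            if n >= 1:
                assert N_SC[res_type] >= 2
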