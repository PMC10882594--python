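import math

import numpy as np
import pytest

from oildrop import (
    ResidueRecord,
    UnitSelection,
    build_profile,
    eliminate_residues,
    fit_gaussian_frame,
    fragment_profile,
    kl_divergence,
    levitt_weight,
    observed_profile,
    rd,
    theoretical_profile,
)
from oildrop.core import FrameError, HydroProfile

from .conftest import random_records, random_rotation


def brute_force_observed(records, cutoff=9.0, include_self=True):
    """Independent O(N^2) double loop over the Levitt pair sum."""
    n = len(records)
    raw = [0.0] * n
    for i in range(n):
        for j in range(n):
            if i == j and not include_self:
                continue
            r = math.dist(records[i].effective_xyz, records[j].effective_xyz)
            if r > cutoff:
                continue
            x = r / cutoff
            w = 1.0 - 0.5 * (7 * x**2 - 9 * x**4 + 5 * x**6 - x**8)
            raw[i] += (records[i].intrinsic_h + records[j].intrinsic_h) * w
    total = sum(raw)
    return np.array(raw), np.array(raw) / total


class TestGaussianFrame:
    def test_axis_aligned_box_gives_half_extents_over_three(self):
        corners = np.array(
            [[sx * 3.0, sy * 2.0, sz * 1.0]
             for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        frame = fit_gaussian_frame(corners, margin=0.0)
        np.testing.assert_allclose(frame.center, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(frame.sigma, [1.0, 2 / 3, 1 / 3], atol=1e-9)

    def test_margin_inflates_sigma(self):
        pts = np.array([[3, 0, 0], [-3, 0, 0], [0, 2, 0],
                        [0, -2, 0], [0, 0, 1], [0, 0, -1]], float)
        f0 = fit_gaussian_frame(pts, margin=0.0)
        f9 = fit_gaussian_frame(pts, margin=9.0)
        np.testing.assert_allclose(f9.sigma, f0.sigma + 3.0, atol=1e-9)

    def test_rotation_equivariance_of_sigma(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(50, 3)) * [4.0, 2.0, 1.0]
        frame = fit_gaussian_frame(pts)
        R = random_rotation(rng)
        t = np.array([5.0, -3.0, 2.0])
        frame_rt = fit_gaussian_frame(pts @ R.T + t)
        np.testing.assert_allclose(frame_rt.sigma, frame.sigma, atol=1e-9)
        np.testing.assert_allclose(frame_rt.center, frame.center @ R.T + t,
                                   atol=1e-9)

    def test_sigma_matches_brute_force_projection(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(50, 3)) * [3.0, 2.0, 0.7]
        frame = fit_gaussian_frame(pts, margin=0.5)
        centered = pts - pts.mean(axis=0)
        for k in range(3):
            max_proj = max(abs(float(centered[i] @ frame.axes[k]))
                           for i in range(len(pts)))
            assert frame.sigma[k] == pytest.approx((max_proj + 0.5) / 3.0,
                                                   rel=1e-12)

    def test_axes_are_proper_rotation(self):
        pts = np.random.default_rng(1).normal(size=(30, 3)) * [3, 2, 1]
        frame = fit_gaussian_frame(pts)
        assert np.linalg.det(frame.axes) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_cloud_rejected(self):
        pts = np.outer(np.arange(10.0), [1.0, 0.5, 0.0])
        with pytest.raises(FrameError):
            fit_gaussian_frame(pts)


class TestTheoreticalProfile:
    def test_center_residue_is_the_gaussian_peak(self):
        records = random_records(10, seed=0)
        frame = fit_gaussian_frame([r.effective_xyz for r in records])
        center_rec = ResidueRecord("A", 99, "", "ALA", tuple(frame.center), 0.5)
        raw, _ = theoretical_profile(records + [center_rec], frame)
        assert raw[-1] == pytest.approx(1.0, abs=1e-12)
        assert raw[-1] == raw.max()

    def test_symmetric_pair_has_equal_t(self):
        frame = fit_gaussian_frame(
            np.array([[3, 0, 0], [-3, 0, 0], [0, 2, 0],
                      [0, -2, 0], [0, 0, 1], [0, 0, -1]], float)
        )
        pair = [
            ResidueRecord("A", 1, "", "ALA", (2.0, 0.0, 0.0), 0.5),
            ResidueRecord("A", 2, "", "ALA", (-2.0, 0.0, 0.0), 0.5),
        ]
        _, T = theoretical_profile(pair, frame)
        assert T[0] == pytest.approx(T[1], rel=1e-12)

    def test_pointwise_scalar_oracle_on_toy_helix(self):
        records = []
        for i in range(10):
            theta = math.radians(100.0) * i
            records.append(
                ResidueRecord("A", i + 1, "", "ALA",
                              (1.5 * i, 2.3 * math.cos(theta),
                               2.3 * math.sin(theta)), 0.5)
            )
        frame = fit_gaussian_frame([r.effective_xyz for r in records])
        raw, T = theoretical_profile(records, frame)
        expected = []
        for rec in records:
            local = frame.axes @ (np.array(rec.effective_xyz) - frame.center)
            expected.append(
                math.exp(-local[0] ** 2 / (2 * frame.sigma[0] ** 2))
                * math.exp(-local[1] ** 2 / (2 * frame.sigma[1] ** 2))
                * math.exp(-local[2] ** 2 / (2 * frame.sigma[2] ** 2))
            )
        np.testing.assert_allclose(raw, expected, rtol=1e-12)
        assert T.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(T > 0)


class TestObservedProfile:
    def test_levitt_weight_endpoints(self):
        assert levitt_weight(np.array([0.0]))[0] == 1.0
        assert levitt_weight(np.array([9.0]))[0] == pytest.approx(0.0, abs=1e-15)
        assert levitt_weight(np.array([9.0001]))[0] == 0.0
        r = np.linspace(0, 9, 50)
        w = levitt_weight(r)
        assert np.all(np.diff(w) <= 1e-12)  # monotone decay

    def test_distant_pair_reduces_to_self_terms(self):
        pair = [
            ResidueRecord("A", 1, "", "ALA", (0.0, 0.0, 0.0), 0.3),
            ResidueRecord("A", 2, "", "ALA", (25.0, 0.0, 0.0), 0.9),
        ]
        raw, O = observed_profile(pair)
        np.testing.assert_allclose(raw, [0.6, 1.8], rtol=1e-12)  # 2*Hir
        with pytest.raises(ValueError):  # no self term, no neighbours
            observed_profile(pair, include_self=False)

    def test_identical_close_residues_are_symmetric(self):
        pair = [
            ResidueRecord("A", 1, "", "ALA", (0.0, 0.0, 0.0), 0.7),
            ResidueRecord("A", 2, "", "ALA", (0.1, 0.0, 0.0), 0.7),
        ]
        _, O = observed_profile(pair)
        assert O[0] == pytest.approx(O[1], rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("include_self", [True, False])
    def test_matches_brute_force_double_loop(self, seed, include_self):
        records = random_records(12, seed=seed, box=18.0)
        raw, O = observed_profile(records, include_self=include_self)
        raw_bf, O_bf = brute_force_observed(records, include_self=include_self)
        np.testing.assert_allclose(raw, raw_bf, rtol=1e-12)
        np.testing.assert_allclose(O, O_bf, rtol=1e-12)

    def test_missing_hydrophobicity_rejected(self):
        recs = [ResidueRecord("A", 1, "", "ALA", (0, 0, 0)),
                ResidueRecord("A", 2, "", "ALA", (1, 0, 0))]
        with pytest.raises(ValueError):
            observed_profile(recs)


class TestKLDivergence:
    def test_identity_is_zero(self):
        P = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(P, P) == 0.0

    def test_closed_form_one_bit(self):
        assert kl_divergence(np.array([1.0, 0.0]),
                             np.array([0.5, 0.5])) == pytest.approx(1.0)

    def test_random_bins_match_hand_summation(self):
        rng = np.random.default_rng(3)
        P = rng.uniform(size=20); P /= P.sum()
        Q = rng.uniform(size=20); Q /= Q.sum()
        hand = sum(p * math.log2(p / q) for p, q in zip(P, Q))
        assert kl_divergence(P, Q) == pytest.approx(hand, rel=1e-12)
        assert kl_divergence(P, Q) >= 0.0

    def test_zero_q_under_positive_p_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            kl_divergence(np.array([0.5, 0.5]), np.array([1.0, 0.0]))

    def test_unnormalized_inputs_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(np.array([0.5, 0.6]), np.array([0.5, 0.5]))


def _profile_with_O(profile, O):
    return HydroProfile(
        unit=profile.unit, residues=profile.residues,
        raw_T=profile.raw_T, raw_O=np.asarray(O, float),
        frame=profile.frame, records=profile.records,
    )


class TestRD:
    def test_o_equal_t_gives_zero(self, micelle_profile):
        res = rd(_profile_with_O(micelle_profile, micelle_profile.T))
        assert res.rd == pytest.approx(0.0, abs=1e-12)

    def test_o_equal_r_gives_one(self, micelle_profile):
        res = rd(_profile_with_O(micelle_profile, micelle_profile.R))
        assert res.rd == pytest.approx(1.0, abs=1e-12)

    def test_rd_bounded_and_consistent(self, micelle_profile):
        res = rd(micelle_profile)
        assert 0.0 <= res.rd <= 1.0
        assert res.rd == pytest.approx(
            res.dkl_OT / (res.dkl_OT + res.dkl_OR), rel=1e-12
        )
        assert res.n_residues == micelle_profile.n


class TestFragmentAndElimination:
    def test_whole_parent_fragment_is_identity(self, micelle_profile):
        sel = UnitSelection(name="whole", mode="part_of_parent")
        frag = fragment_profile(micelle_profile, sel)
        np.testing.assert_array_equal(frag.raw_T, micelle_profile.raw_T)
        assert rd(frag).rd == pytest.approx(rd(micelle_profile).rd, rel=1e-12)

    def test_disjoint_fragments_partition_raw_arrays(self, micelle_profile):
        n = micelle_profile.n
        first = UnitSelection(name="a", ranges=(("A", 1, n // 2),),
                              mode="part_of_parent")
        second = UnitSelection(name="b", ranges=(("A", n // 2 + 1, n),),
                               mode="part_of_parent")
        fa = fragment_profile(micelle_profile, first)
        fb = fragment_profile(micelle_profile, second)
        np.testing.assert_array_equal(
            np.concatenate([fa.raw_T, fb.raw_T]), micelle_profile.raw_T
        )
        np.testing.assert_array_equal(
            np.concatenate([fa.raw_O, fb.raw_O]), micelle_profile.raw_O
        )
        assert fa.R[0] == pytest.approx(1.0 / fa.n)

    def test_fragment_requires_part_mode(self, micelle_profile):
        with pytest.raises(ValueError):
            fragment_profile(micelle_profile, UnitSelection(name="x"))

    def test_empty_elimination_is_identity(self, micelle_profile):
        out = eliminate_residues(micelle_profile, [])
        assert rd(out).rd == rd(micelle_profile).rd

    def test_elimination_keeps_parent_field(self, micelle_profile):
        dropped = micelle_profile.residues[0]
        out = eliminate_residues(micelle_profile, [dropped])
        assert out.n == micelle_profile.n - 1
        assert out.frame is micelle_profile.frame
        np.testing.assert_array_equal(out.raw_T, micelle_profile.raw_T[1:])
        assert out.R[0] == pytest.approx(1.0 / out.n)

    def test_unknown_residue_rejected(self, micelle_profile):
        with pytest.raises(KeyError):
            eliminate_residues(micelle_profile, [("Z", 999, "")])

    def test_elimination_cannot_empty_unit(self, micelle_profile):
        with pytest.raises(ValueError):
            eliminate_residues(micelle_profile,
                               list(micelle_profile.residues[:-1]))


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("seed", range(3))
    def test_profiles_and_rd_invariant(self, seed):
        records = random_records(30, seed=seed)
        profile = build_profile(records)
        base = rd(profile)
        rng = np.random.default_rng(seed + 100)
        R = random_rotation(rng)
        t = rng.uniform(-50, 50, size=3)
        moved = [
            ResidueRecord(r.chain_id, r.auth_seq_id, r.insertion_code, r.aa3,
                          tuple(np.asarray(r.effective_xyz) @ R.T + t),
                          r.intrinsic_h)
            for r in records
        ]
        prof2 = build_profile(moved)
        np.testing.assert_allclose(prof2.T, profile.T, atol=1e-9)
        np.testing.assert_allclose(prof2.O, profile.O, atol=1e-9)
        assert rd(prof2).rd == pytest.approx(base.rd, abs=1e-9)
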