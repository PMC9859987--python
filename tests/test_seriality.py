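"""Relative seriality model: analytic identities, limits, and invariances."""

import math

import numpy as np
import pytest

from seridose import SerialityParams, beud_from_ntcp, ntcp, ntcp_for_volume_fraction, voxel_response
from seridose.seriality import ntcp_from_bins, ntcp_result

from conftest import make_ddvh


def random_ddvh(rng, n_bins=50, dmax=80.0):
    doses = np.sort(rng.uniform(0.0, dmax, n_bins))
    dv = rng.dirichlet(np.ones(n_bins))
    return make_ddvh(doses, dv)


class TestVoxelResponse:
    def test_half_response_at_d50(self, bladder, rectum):
        assert voxel_response(80.9, bladder) == pytest.approx(0.5, abs=1e-12)
        assert voxel_response(67.0, rectum) == pytest.approx(0.5, abs=1e-12)

    def test_zero_dose_rectum_negligible(self, rectum):
        # closed form: exp(-ln2 * e^(e*gamma)) with gamma = 2.5
        assert voxel_response(0.0, rectum) < 1e-100

    def test_strictly_increasing_and_saturating(self, rectum):
        doses = np.linspace(0.0, 300.0, 400)
        p = voxel_response(doses, rectum)
        assert np.all(np.diff(p) > 0)
        assert voxel_response(1e4, rectum) == pytest.approx(1.0)

    @pytest.mark.parametrize("organ", ["bladder", "rectum"])
    def test_normalized_gradient_at_d50(self, organ, organ_params):
        """D * dP/dD at D50 equals (e ln2 / 2) * gamma (central difference)."""
        p = organ_params[organ]
        eps = 1e-5 * p.d50
        grad = (voxel_response(p.d50 + eps, p) - voxel_response(p.d50 - eps, p)) / (2 * eps)
        assert p.d50 * grad == pytest.approx(math.e * math.log(2) / 2 * p.gamma, rel=1e-6)

    def test_negative_dose_rejected(self, rectum):
        with pytest.raises(ValueError):
            voxel_response(-1.0, rectum)


class TestNTCP:
    @pytest.mark.parametrize("s", [1e-4, 0.1, 1.0, 4.0])
    def test_uniform_whole_organ_independent_of_s(self, rectum, s):
        p = ntcp_from_bins([55.0], [1.0], rectum, s=s)
        assert p == pytest.approx(voxel_response(55.0, rectum), abs=1e-12)

    def test_serial_limit_matches_product_formula(self, rng, rectum):
        """s = 1 reduces to 1 - prod (1 - P(D_i))^dv_i."""
        ddvh = random_ddvh(rng)
        p_model = ntcp(ddvh, rectum)
        p_vox = voxel_response(ddvh.bin_dose, rectum)
        oracle = 1.0 - np.prod((1.0 - p_vox) ** ddvh.frac_volume)
        assert p_model == pytest.approx(oracle, abs=1e-12)

    def test_parallel_limit_small_s(self, rng, bladder):
        """s = 1e-4 matches the s -> 0 closed form within 1e-4."""
        ddvh = random_ddvh(rng)
        p_model = ntcp(ddvh, bladder)
        y = -np.log(voxel_response(ddvh.bin_dose, bladder))
        limit = np.exp(-np.exp(np.sum(ddvh.frac_volume * np.log(y))))
        assert p_model == pytest.approx(limit, abs=1e-4)

    def test_permutation_and_split_invariance(self, rng, rectum):
        ddvh = random_ddvh(rng, n_bins=12)
        base = ntcp(ddvh, rectum)
        order = rng.permutation(12)
        doses, dv = ddvh.bin_dose[order], ddvh.frac_volume[order]
        resort = np.argsort(doses)
        permuted = make_ddvh(doses[resort], dv[resort])
        assert ntcp(permuted, rectum) == pytest.approx(base, abs=1e-12)
        # split the largest bin into two equal halves at the same dose
        k = int(np.argmax(dv))
        doses2 = np.append(ddvh.bin_dose, ddvh.bin_dose[k] + 1e-9)
        dv2 = np.append(ddvh.frac_volume, ddvh.frac_volume[k] / 2)
        dv2[k] /= 2
        assert ntcp_from_bins(doses2, dv2, rectum) == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize("organ", ["bladder", "rectum"])
    def test_monotone_in_dose(self, rng, organ, organ_params):
        """Adding dose to any bin never decreases NTCP."""
        params = organ_params[organ]
        ddvh = random_ddvh(rng, n_bins=8)
        base = ntcp(ddvh, params)
        for k in range(8):
            doses = ddvh.bin_dose.copy()
            doses[k] += 5.0
            resort = np.argsort(doses)
            bumped = ntcp_from_bins(doses[resort], ddvh.frac_volume[resort], params)
            assert bumped >= base - 1e-12

    def test_unnormalized_volumes_rejected(self, rectum):
        with pytest.raises(ValueError, match="sum to 1"):
            ntcp_from_bins([10.0, 20.0], [0.4, 0.5], rectum)

    def test_zero_dose_bins_matter_for_parallel_organ(self, bladder):
        """For small s, dropping 0 Gy bins changes the result."""
        ddvh = make_ddvh([0.0, 60.0], [0.3, 0.7])
        kept = ntcp(ddvh, bladder)
        dropped = ntcp(ddvh, bladder, drop_zero_dose_bins=True)
        assert dropped == pytest.approx(voxel_response(60.0, bladder), abs=1e-6)
        assert kept < dropped  # cold volume protects a parallel organ


class TestBEUD:
    def test_inversion_returns_d50_at_half(self, bladder, rectum):
        assert beud_from_ntcp(0.5, rectum) == pytest.approx(67.0, abs=1e-10)
        assert beud_from_ntcp(0.5, bladder) == pytest.approx(80.9, abs=1e-10)

    def test_round_trip_through_heterogeneous_dvh(self, rng, rectum):
        ddvh = random_ddvh(rng)
        p = ntcp(ddvh, rectum)
        beud = beud_from_ntcp(p, rectum)
        assert ntcp_from_bins([beud], [1.0], rectum) == pytest.approx(p, abs=1e-10)

    def test_identity_on_uniform_doses(self, rectum):
        for dose in (30.0, 55.0, 67.0, 75.0, 90.0):
            p = voxel_response(dose, rectum)
            assert beud_from_ntcp(p, rectum) == pytest.approx(dose, abs=1e-8)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_probability_rejected(self, rectum, p):
        with pytest.raises(ValueError):
            beud_from_ntcp(p, rectum)

    def test_probability_below_zero_dose_floor_rejected(self, bladder):
        # bladder P(0) ~ 0.1; smaller NTCP values have no non-negative BEUD
        with pytest.raises(ValueError, match="zero-dose"):
            beud_from_ntcp(1e-6, bladder)

    def test_ntcp_result_is_consistent(self, rng, rectum):
        ddvh = random_ddvh(rng)
        res = ntcp_result(ddvh, rectum)
        assert voxel_response(res.beud_gy, rectum) == pytest.approx(res.ntcp, abs=1e-10)


class TestPartialVolume:
    def test_full_volume_equals_voxel_response(self, rectum):
        assert ntcp_for_volume_fraction(60.0, 1.0, rectum) == pytest.approx(
            voxel_response(60.0, rectum), abs=1e-12
        )

    def test_hand_evaluation_half_volume(self, rectum):
        """v = 0.5, s = 1, P(D) = 0.4 -> 1 - (1 - 0.4)^0.5 = 0.2254."""
        from scipy.optimize import brentq

        d = brentq(lambda x: voxel_response(x, rectum) - 0.4, 1.0, 200.0, xtol=1e-12)
        assert ntcp_for_volume_fraction(d, 0.5, rectum) == pytest.approx(
            1.0 - 0.6**0.5, abs=1e-9
        )

    def test_monotone_in_volume_fraction(self, rectum):
        vols = np.linspace(0.05, 1.0, 20)
        probs = [ntcp_for_volume_fraction(70.0, v, rectum) for v in vols]
        assert np.all(np.diff(probs) > 0)

    @pytest.mark.parametrize("v", [0.0, 1.5, -0.2])
    def test_volume_fraction_out_of_range_rejected(self, rectum, v):
        with pytest.raises(ValueError):
            ntcp_for_volume_fraction(50.0, v, rectum)


class TestParams:
    def test_ci_must_bracket_point(self):
        with pytest.raises(ValueError, match="bracket"):
            SerialityParams(d50=50.0, gamma=1.0, s=1.0, ci_d50=(60.0, 70.0))

    @pytest.mark.parametrize("kw", [{"d50": -1.0}, {"gamma": 0.0}, {"s": -0.5}])
    def test_nonpositive_parameters_rejected(self, kw):
        base = {"d50": 60.0, "gamma": 1.0, "s": 1.0}
        with pytest.raises(ValueError):
            SerialityParams(**{**base, **kw})

    def test_packaged_parameter_sets(self, organ_params):
        b, r = organ_params["bladder"], organ_params["rectum"]
        assert (b.d50, b.gamma, b.s) == (80.9, 0.44, 0.0001)
        assert (r.d50, r.gamma, r.s) == (67.0, 2.5, 1.0)
        assert b.ci_d50 == (65.7, 108.2) and r.ci_d50 == (64.5, 72.0)
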